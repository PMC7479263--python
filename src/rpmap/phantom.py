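"""Synthetic rad-path phantom: pre-aligned MRI feature stacks, epithelium
density truth, lesions, and multi-observer annotations.

The phantom emulates the statistical structure a radio-pathomic mapping
analysis assumes, so the whole pipeline is testable without patient data:

* per-slide prostate mask with elliptical lesions of graded severity
  (benign atrophy < HGPIN < Gleason 3 < Gleason 4 fused/cribriform < Gleason 5),
* a voxel-wise epithelium-density field whose class means increase with
  severity,
* six MRI-derived feature maps that are noisy affine functions of density
  (ADC-like features decrease with density, as denser tumor restricts
  diffusion),
* simulated annotators that miss lesions, confuse neighbouring grades and
  jitter lesion boundaries, reproducing the kind of inter-observer
  disagreement seen when several pathologists annotate the same slide.

All randomness flows from one master seed through fixed-key substreams:
slide content uses key ``(0, slide_index)`` and each annotator uses key
``(1, slide_index, seed_offset)``, so adding an annotator never perturbs
slide content or other annotators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

logger = logging.getLogger(__name__)

# 7-label annotation vocabulary shared by the whole package.
UNLABELED = 0
ATROPHY = 1
HGPIN = 2
G3 = 3
G4FG = 4
G4CG = 5
G5 = 6

LABEL_NAMES: dict[int, str] = {
    UNLABELED: "unlabeled",
    ATROPHY: "atrophy",
    HGPIN: "HGPIN",
    G3: "G3",
    G4FG: "G4FG",
    G4CG: "G4CG",
    G5: "G5",
}
NAME_TO_LABEL: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

# Lesion classes the phantom can place (everything except "unlabeled").
LESION_CLASSES: tuple[int, ...] = (ATROPHY, HGPIN, G3, G4FG, G4CG, G5)

FEATURE_NAMES: tuple[str, ...] = (
    "T2_norm",
    "ADC_0_1000",
    "ADC_1000_2000",
    "ADC_500_2000",
    "B0",
    "T1_sub",
)


class PhantomError(ValueError):
    """Invalid phantom configuration or impossible lesion placement."""


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for ``key`` under one master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_density_means() -> dict[str, float]:
    # Epithelium density (area fraction) rises with disease severity; the
    # background stroma sits below every lesion class.
    return {
        "stroma": 0.20,
        "atrophy": 0.26,
        "HGPIN": 0.33,
        "G3": 0.43,
        "G4FG": 0.53,
        "G4CG": 0.59,
        "G5": 0.68,
    }


def _default_feature_coeffs() -> np.ndarray:
    # (slope, intercept) per feature mapping density -> feature mean.
    # Diffusion-derived features (three ADC maps) fall with epithelium
    # density; T2 signal also drops in dense tumor; b=0 and the T1
    # subtraction map rise with cellularity/enhancement.
    return np.array(
        [
            [-0.80, 1.00],  # T2_norm
            [-1.00, 1.20],  # ADC_0_1000
            [-0.90, 1.10],  # ADC_1000_2000
            [-0.95, 1.15],  # ADC_500_2000
            [0.40, 0.50],   # B0
            [0.60, 0.30],   # T1_sub
        ]
    )


def _default_class_mix() -> dict[str, float]:
    return {
        "atrophy": 0.20,
        "HGPIN": 0.10,
        "G3": 0.30,
        "G4FG": 0.20,
        "G4CG": 0.12,
        "G5": 0.08,
    }


@dataclass
class PhantomConfig:
    """Study-condition knobs for the synthetic cohort.

    Parameters
    ----------
    n_patients, slides_per_patient
        Cohort size; slides are independent 2D sections (the analysis is
        in-plane, with no 3D continuity modelled).
    grid_shape
        Raster size in voxels; at least 16 per axis.
    voxel_area_mm2
        In-plane voxel area. Default 0.5 mm^2, so the lesion-size filter
        (specified in voxels downstream) remains exercisable at desk scale.
    lesion_count_mean
        Poisson mean of lesions per slide.
    lesion_radius_range
        (min, max) semi-axis range, in voxels, of the elliptical lesions.
    class_mix
        Sampling probabilities over the six lesion classes; must sum to 1.
    density_means
        Mean epithelium density per tissue class (incl. ``stroma``
        background), each in [0, 1]; validated monotone in severity when
        ``enforce_monotone`` is set.
    density_sd
        SD of the spatially smoothed Gaussian texture added to class means.
    lesion_density_jitter
        SD of a per-lesion offset on the class-mean density: lesion-level
        biological variability that does not average away in ROI medians,
        so lesion-wise discrimination stays imperfect as in real cohorts.
    feature_coeffs, feature_noise_sd
        Per-feature affine map density -> feature mean, and voxel-wise
        (white) additive noise SD.
    feature_noise_corr_sd, feature_noise_corr_len
        Amplitude and Gaussian correlation length (voxels) of a smooth
        per-feature noise field emulating coil shading, registration
        residue and other spatially structured MRI artefacts; unlike white
        noise this survives ROI medians.
    """

    n_patients: int = 4
    slides_per_patient: int = 2
    grid_shape: tuple[int, int] = (96, 96)
    voxel_area_mm2: float = 0.5
    lesion_count_mean: float = 4.0
    lesion_count_max: int = 5
    lesion_radius_range: tuple[float, float] = (6.0, 13.0)
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    density_means: dict[str, float] = field(default_factory=_default_density_means)
    density_sd: float = 0.05
    lesion_density_jitter: float = 0.08
    feature_coeffs: np.ndarray = field(default_factory=_default_feature_coeffs)
    feature_noise_sd: np.ndarray = field(default_factory=lambda: np.full(6, 0.05))
    feature_noise_corr_sd: np.ndarray = field(default_factory=lambda: np.full(6, 0.15))
    feature_noise_corr_len: float = 8.0
    enforce_monotone: bool = True
    max_placement_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        self.feature_coeffs = np.asarray(self.feature_coeffs, dtype=float)
        self.feature_noise_sd = np.asarray(self.feature_noise_sd, dtype=float)
        if self.feature_coeffs.shape != (6, 2):
            raise PhantomError("feature_coeffs must be a 6x2 (slope, intercept) matrix")
        self.feature_noise_corr_sd = np.asarray(self.feature_noise_corr_sd, dtype=float)
        if self.feature_noise_sd.shape != (6,) or self.feature_noise_corr_sd.shape != (6,):
            raise PhantomError("feature noise SDs must be 6-vectors")
        if (np.any(self.feature_noise_sd < 0) or np.any(self.feature_noise_corr_sd < 0)
                or self.density_sd < 0 or self.lesion_density_jitter < 0):
            raise PhantomError("noise standard deviations must be >= 0")
        if min(self.grid_shape) < 16:
            raise PhantomError("grid dimensions must be >= 16 voxels")
        if self.voxel_area_mm2 <= 0:
            raise PhantomError("voxel_area_mm2 must be positive")
        mix = np.array([self.class_mix[LABEL_NAMES[c]] for c in LESION_CLASSES])
        if abs(mix.sum() - 1.0) > 1e-12:
            raise PhantomError(f"class_mix must sum to 1, got {mix.sum()!r}")
        if np.any(mix < 0):
            raise PhantomError("class_mix probabilities must be >= 0")
        for name, mu in self.density_means.items():
            if not 0.0 <= mu <= 1.0:
                raise PhantomError(f"density mean for {name!r} outside [0, 1]")
        if self.enforce_monotone:
            order = ["stroma", "atrophy", "HGPIN", "G3", "G4FG", "G4CG", "G5"]
            vals = [self.density_means[n] for n in order]
            if not all(a < b for a, b in zip(vals, vals[1:])):
                raise PhantomError(
                    "density_means must increase strictly with severity "
                    f"({' < '.join(order)}); got {vals}"
                )

    @property
    def n_slides(self) -> int:
        return self.n_patients * self.slides_per_patient


@dataclass
class AnnotatorProfile:
    """Generative model of one observer's annotation behaviour.

    ``boundary_jitter_vox`` is the SD of a half-normal dilation/erosion
    radius applied per lesion (a fair coin picks grow vs shrink);
    ``detection_prob`` maps each class to the probability the observer marks
    a true lesion at all; ``confusion`` is a row-stochastic 6x6 matrix over
    the non-unlabeled classes giving the label the observer assigns;
    observers who never outline benign atrophy set ``annotates_atrophy``
    False, mirroring the real stylistic split between pathologists.
    """

    boundary_jitter_vox: float = 0.0
    detection_prob: Mapping[int, float] | float = 1.0
    confusion: np.ndarray | None = None
    annotates_atrophy: bool = True
    seed_offset: int = 0
    name: str = "observer"

    def __post_init__(self) -> None:
        if self.boundary_jitter_vox < 0:
            raise PhantomError("boundary_jitter_vox must be >= 0")
        if self.confusion is None:
            self.confusion = np.eye(6)
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (6, 6):
            raise PhantomError("confusion must be 6x6 over the lesion classes")
        if np.any(np.abs(self.confusion.sum(axis=1) - 1.0) > 1e-12):
            raise PhantomError("confusion rows must each sum to 1")
        if np.any(self.confusion < 0):
            raise PhantomError("confusion entries must be >= 0")

    def p_detect(self, class_label: int) -> float:
        if isinstance(self.detection_prob, Mapping):
            p = float(self.detection_prob.get(class_label, 1.0))
        else:
            p = float(self.detection_prob)
        if not 0.0 <= p <= 1.0:
            raise PhantomError(f"detection probability {p} outside [0, 1]")
        return p


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureVolume:
    """Per-slide stack of six named MRI-derived feature maps plus mask."""

    data: np.ndarray  # rows x cols x 6
    prostate_mask: np.ndarray  # rows x cols bool
    voxel_area_mm2: float
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.prostate_mask = np.asarray(self.prostate_mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.feature_names):
            raise ValueError("feature data must be rows x cols x n_features")
        if self.data.shape[:2] != self.prostate_mask.shape:
            raise ValueError("feature grid and prostate mask shapes differ")
        if not self.prostate_mask.any():
            raise ValueError("prostate mask is empty")
        if not np.all(np.isfinite(self.data[self.prostate_mask])):
            raise ValueError("non-finite feature values inside prostate mask")

    def feature(self, name: str) -> np.ndarray:
        return self.data[:, :, self.feature_names.index(name)]


@dataclass
class DensityMap:
    """Voxel-wise epithelium density in [0, 1]; NaN outside the mask."""

    data: np.ndarray
    role: str = "truth"  # truth | predicted

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("density values must lie in [0, 1]")


class AnnotationSet:
    """Per-observer integer label maps over one slide grid (labels 0..6)."""

    def __init__(self, labels: Mapping[str, np.ndarray]):
        self.labels: dict[str, np.ndarray] = {}
        shape = None
        for obs, arr in labels.items():
            arr = np.asarray(arr)
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"labels for {obs!r} must be integer")
            if arr.min() < 0 or arr.max() > 6:
                raise ValueError(f"labels for {obs!r} outside vocabulary 0..6")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all observers must share one grid shape")
            self.labels[obs] = arr
        if shape is None:
            raise ValueError("AnnotationSet needs at least one observer")
        self.shape = shape

    def __getitem__(self, obs: str) -> np.ndarray:
        return self.labels[obs]

    @property
    def observers(self) -> list[str]:
        return list(self.labels)


@dataclass
class PhantomLesion:
    """Ground-truth lesion placed by the generator."""

    lesion_id: int
    class_label: int
    center: tuple[float, float]
    rows: np.ndarray
    cols: np.ndarray

    @property
    def area_vox(self) -> int:
        return int(self.rows.size)


@dataclass
class Slide:
    slide_id: str
    patient_id: str
    features: FeatureVolume
    truth_density: DensityMap
    truth_labels: np.ndarray
    lesions: list[PhantomLesion]
    annotations: AnnotationSet | None = None

    @property
    def prostate_mask(self) -> np.ndarray:
        return self.features.prostate_mask


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def prostate_mask(grid_shape: tuple[int, int]) -> np.ndarray:
    """Elliptical gland outline occupying most of the grid."""
    rows, cols = grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    a, b = 0.40 * rows, 0.44 * cols
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _place_lesions(config: PhantomConfig, mask: np.ndarray,
                   rng: np.random.Generator, slide_id: str) -> list[PhantomLesion]:
    rows, cols = mask.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    # truncated Poisson: whole-mount slides carry at most a handful of
    # lesions large enough to matter, and the gland must fit them all
    n_lesions = min(int(rng.poisson(config.lesion_count_mean)),
                    config.lesion_count_max)
    occupied = np.zeros_like(mask)
    mix = np.array([config.class_mix[LABEL_NAMES[c]] for c in LESION_CLASSES])
    lesions: list[PhantomLesion] = []
    # draw classes and sizes up front and place the largest first, which
    # packs the gland far more reliably than arrival order
    draws = []
    for i in range(n_lesions):
        cls = int(rng.choice(LESION_CLASSES, p=mix))
        a = rng.uniform(*config.lesion_radius_range)
        b = rng.uniform(*config.lesion_radius_range)
        draws.append((i, cls, a, b))
    for i, cls, a, b in sorted(draws, key=lambda d: -d[2] * d[3]):
        placed = False
        for _ in range(config.max_placement_tries):
            r0 = rng.uniform(0, rows - 1)
            c0 = rng.uniform(0, cols - 1)
            inside = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
            if not inside.any():
                continue
            if not mask[inside].all():          # lesion must sit inside the gland
                continue
            if occupied[inside].any():          # lesions do not overlap
                continue
            occupied |= inside
            ys, xs = np.nonzero(inside)
            lesions.append(PhantomLesion(i, cls, (r0, c0), ys, xs))
            placed = True
            break
        if not placed:
            raise PhantomError(
                f"slide {slide_id}: could not place lesion {i} "
                f"(class {LABEL_NAMES[cls]}) after "
                f"{config.max_placement_tries} tries; "
                "shrink lesion_radius_range or lesion_count_mean"
            )
    lesions.sort(key=lambda les: les.lesion_id)
    return lesions


def _truth_density(config: PhantomConfig, mask: np.ndarray,
                   lesions: Sequence[PhantomLesion],
                   rng: np.random.Generator) -> np.ndarray:
    means = np.full(mask.shape, config.density_means["stroma"])
    for les in lesions:
        mu = config.density_means[LABEL_NAMES[les.class_label]]
        mu += rng.normal(0.0, config.lesion_density_jitter) if \
            config.lesion_density_jitter > 0 else 0.0
        means[les.rows, les.cols] = np.clip(mu, 0.0, 1.0)
    # Smoothed texture keeps lesion medians stable while giving within-class
    # spread; boxcar width 3.
    noise = rng.normal(0.0, config.density_sd, size=mask.shape)
    if config.density_sd > 0:
        noise = ndimage.uniform_filter(noise, size=3, mode="nearest")
    density = np.clip(means + noise, 0.0, 1.0)
    density[~mask] = np.nan
    return density


@lru_cache(maxsize=8)
def _gaussian_kernel_l2(sigma: float) -> float:
    """Pointwise SD of a Gaussian-filtered unit-variance white field."""
    impulse = np.zeros((int(8 * sigma) + 9,) * 2)
    impulse[impulse.shape[0] // 2, impulse.shape[1] // 2] = 1.0
    return float(np.sqrt((ndimage.gaussian_filter(impulse, sigma) ** 2).sum()))


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       sigma: float) -> np.ndarray:
    """Gaussian-correlated random field with pointwise SD 1."""
    white = rng.normal(0.0, 1.0, size=shape)
    field = ndimage.gaussian_filter(white, sigma, mode="nearest")
    return field / _gaussian_kernel_l2(sigma)


def render_features(truth_density: DensityMap, config: PhantomConfig,
                    mask: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> FeatureVolume:
    """Render the six feature maps as noisy affine functions of density.

    ``feature_j = slope_j * density + intercept_j + N(0, noise_sd_j)``
    plus a spatially correlated noise field of SD ``feature_noise_corr_sd``
    (Gaussian correlation length ``feature_noise_corr_len`` voxels).
    """
    dens = truth_density.data
    if mask is None:
        mask = np.isfinite(dens)
    if rng is None:
        rng = substream(config.seed, 2)
    if not np.all(np.isfinite(dens[mask])):
        raise PhantomError("truth density undefined inside the mask")
    data = np.empty(dens.shape + (6,), dtype=float)
    filled = np.where(mask, dens, 0.0)
    for j in range(6):
        slope, intercept = config.feature_coeffs[j]
        layer = slope * filled + intercept
        sd = config.feature_noise_sd[j]
        if sd > 0:
            layer = layer + rng.normal(0.0, sd, size=dens.shape)
        corr_sd = config.feature_noise_corr_sd[j]
        if corr_sd > 0:
            layer = layer + corr_sd * _smooth_unit_field(
                rng, dens.shape, config.feature_noise_corr_len)
        data[:, :, j] = layer
    data[~mask] = np.nan
    return FeatureVolume(data=data, prostate_mask=mask,
                         voxel_area_mm2=config.voxel_area_mm2)


def generate_slide(config: PhantomConfig, slide_index: int,
                   patient_id: str, slide_id: str) -> Slide:
    rng = substream(config.seed, 0, slide_index)
    mask = prostate_mask(config.grid_shape)
    lesions = _place_lesions(config, mask, rng, slide_id)
    density = DensityMap(_truth_density(config, mask, lesions, rng), role="truth")
    features = render_features(density, config, mask=mask, rng=rng)
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    for les in lesions:
        labels[les.rows, les.cols] = les.class_label
    return Slide(slide_id=slide_id, patient_id=patient_id, features=features,
                 truth_density=density, truth_labels=labels, lesions=lesions)


def generate_cohort(config: PhantomConfig) -> list[Slide]:
    """Generate ``n_patients * slides_per_patient`` independent slides.

    Deterministic given ``config.seed``; each slide's content comes from its
    own substream so cohort size changes do not reshuffle existing slides.
    """
    slides = []
    idx = 0
    for p in range(config.n_patients):
        for s in range(config.slides_per_patient):
            slides.append(
                generate_slide(config, idx, patient_id=f"P{p:03d}",
                               slide_id=f"P{p:03d}S{s}")
            )
            idx += 1
    return slides


def lesion_ledger(slides: Sequence[Slide]):
    """Ground-truth lesion table (one row per placed lesion)."""
    import pandas as pd

    rows = []
    for slide in slides:
        for les in slide.lesions:
            rows.append({
                "lesion_id": les.lesion_id,
                "slide_id": slide.slide_id,
                "class": LABEL_NAMES[les.class_label],
                "center_row": les.center[0],
                "center_col": les.center[1],
                "area_vox": les.area_vox,
            })
    return pd.DataFrame(rows, columns=["lesion_id", "slide_id", "class",
                                       "center_row", "center_col", "area_vox"])


# ---------------------------------------------------------------------------
# annotator simulation
# ---------------------------------------------------------------------------

def simulate_annotator(slide: Slide, profile: AnnotatorProfile,
                       slide_index: int, seed: int) -> np.ndarray:
    """One observer's label map for ``slide``.

    Per true lesion: drop it with probability ``1 - detection_prob[class]``;
    otherwise draw the assigned class from the profile's confusion row and
    grow or shrink the outline by a half-normal radius. Atrophy lesions are
    emitted only by observers who annotate atrophy. When jittered outlines
    collide, the later lesion overwrites the earlier one (logged).
    """
    rng = substream(seed, 1, slide_index, profile.seed_offset)
    out = np.zeros(slide.truth_labels.shape, dtype=np.int16)
    mask = slide.prostate_mask
    for les in slide.lesions:
        # Draws happen for every lesion, detected or not, so one observer's
        # stream stays aligned regardless of which lesions survive.
        u_detect = rng.uniform()
        new_cls = int(rng.choice(6, p=profile.confusion[les.class_label - 1]) + 1)
        radius = abs(rng.normal(0.0, profile.boundary_jitter_vox))
        grow = rng.uniform() < 0.5
        if les.class_label == ATROPHY and not profile.annotates_atrophy:
            continue
        if u_detect >= profile.p_detect(les.class_label):
            continue
        blob = np.zeros_like(mask)
        blob[les.rows, les.cols] = True
        r = int(round(radius))
        if r > 0:
            fp = disk(r)
            blob = (ndimage.binary_dilation(blob, fp) if grow
                    else ndimage.binary_erosion(blob, fp))
            blob &= mask
        if not blob.any():
            logger.debug("slide %s lesion %d eroded away by observer %s",
                         slide.slide_id, les.lesion_id, profile.name)
            continue
        if out[blob].any():
            logger.debug("slide %s lesion %d overlaps an earlier annotation; "
                         "later lesion wins", slide.slide_id, les.lesion_id)
        out[blob] = new_cls
    return out


def annotate_cohort(slides: Sequence[Slide], profiles: Sequence[AnnotatorProfile],
                    seed: int) -> None:
    """Attach an AnnotationSet from ``profiles`` to every slide, in place."""
    for idx, slide in enumerate(slides):
        labels = {
            prof.name: simulate_annotator(slide, prof, idx, seed)
            for prof in profiles
        }
        slide.annotations = AnnotationSet(labels)


def default_annotator_profiles(n: int = 5) -> list[AnnotatorProfile]:
    """Five observers spanning the annotation styles seen in practice:
    varying boundary precision, lesion-detection appetite, grade confusion
    concentrated on the G3/G4 boundary, and whether atrophy is outlined."""
    # Adjacent-grade confusion: each class mostly keeps its label, with the
    # residual mass on ordinal neighbours (G3<->G4FG etc.).
    def conf(keep: float) -> np.ndarray:
        m = np.zeros((6, 6))
        for i in range(6):
            m[i, i] = keep
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < 6]
            for j in nbrs:
                m[i, j] = (1 - keep) / len(nbrs)
        return m

    base = [
        AnnotatorProfile(boundary_jitter_vox=1.0, detection_prob=0.95,
                         confusion=conf(0.85), annotates_atrophy=True,
                         seed_offset=0, name="obs1"),
        AnnotatorProfile(boundary_jitter_vox=1.5, detection_prob=0.90,
                         confusion=conf(0.75), annotates_atrophy=False,
                         seed_offset=1, name="obs2"),
        AnnotatorProfile(boundary_jitter_vox=0.5, detection_prob=0.85,
                         confusion=conf(0.90), annotates_atrophy=True,
                         seed_offset=2, name="obs3"),
        AnnotatorProfile(boundary_jitter_vox=2.0, detection_prob=0.95,
                         confusion=conf(0.80), annotates_atrophy=False,
                         seed_offset=3, name="obs4"),
        AnnotatorProfile(boundary_jitter_vox=1.0, detection_prob=0.90,
                         confusion=conf(0.85), annotates_atrophy=True,
                         seed_offset=4, name="obs5"),
    ]
    return base[:n] if n <= 5 else base + [
        AnnotatorProfile(seed_offset=5 + i, name=f"obs{6 + i}")
        for i in range(n - 5)
    ]
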