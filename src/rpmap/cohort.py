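"""Lesion-wise training and evaluation tables.

Each pathologist-drawn region of interest becomes one row: the per-feature
medians over the lesion's voxels are the predictors and the median
epithelium density is the target. Lesions are 4-connected components of one
label value, kept only when strictly larger than 200 voxels in plane.
Control rows come either from benign-atrophy annotations (single-annotator
datasets) or from an unlabeled consensus: every voxel any observer called
Gleason pattern 3 or higher is subtracted from the prostate mask and the
remainder is split into four equally sized regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .phantom import (ATROPHY, LABEL_NAMES, AnnotationSet, DensityMap,
                      FeatureVolume)

logger = logging.getLogger(__name__)

#: labels considered cancerous for the consensus subtraction (G3 and up)
G3_PLUS = (3, 4, 5, 6)

#: lesion class -> coarse group used for evaluation; HGPIN's placement is
#: configurable via ``build_training_table(hgpin_group=...)``
CLASS_GROUPS: dict[str, str] = {
    "G3": "low",
    "G4FG": "high",
    "G4CG": "high",
    "G5": "high",
    "atrophy": "benign",
    "HGPIN": "benign",
    "atrophy_control": "benign",
    "unlabeled_consensus": "benign",
}


@dataclass
class Lesion:
    """A contiguous annotated region (or constructed control ROI)."""

    lesion_id: str
    slide_id: str
    observer: str
    class_label: str
    rows: np.ndarray
    cols: np.ndarray
    voxel_area_mm2: float

    @property
    def area_vox(self) -> int:
        return int(self.rows.size)

    @property
    def area_cm2(self) -> float:
        return self.area_vox * self.voxel_area_mm2 / 100.0


def extract_lesions(labels: np.ndarray, mask: np.ndarray, *,
                    slide_id: str = "slide", observer: str = "obs",
                    voxel_area_mm2: float = 0.5, min_area_vox: int = 201,
                    include_labels: tuple[int, ...] | None = None) -> list[Lesion]:
    """4-connected components per label value, kept iff area >= min_area_vox.

    The default ``min_area_vox=201`` realises the strict ">200 voxels"
    inclusion rule. Components are ordered by (label value, top-left voxel)
    for determinism. Voxels outside the prostate mask are ignored.
    """
    labels = np.where(mask, labels, 0)
    out: list[Lesion] = []
    values = include_labels if include_labels is not None else range(1, 7)
    for val in values:
        binary = labels == val
        if not binary.any():
            continue
        comp = measure.label(binary, connectivity=1)
        regions = []
        for region_id in range(1, comp.max() + 1):
            ys, xs = np.nonzero(comp == region_id)
            if ys.size >= min_area_vox:
                # top-left voxel = row-major first voxel of the component
                regions.append((ys[0], xs[0], ys, xs))
        regions.sort(key=lambda r: (r[0], r[1]))
        for k, (_, _, ys, xs) in enumerate(regions):
            out.append(Lesion(
                lesion_id=f"{slide_id}:{observer}:{LABEL_NAMES[val]}:{k}",
                slide_id=slide_id, observer=observer,
                class_label=LABEL_NAMES[val], rows=ys, cols=xs,
                voxel_area_mm2=voxel_area_mm2,
            ))
    return out


def consensus_unlabeled_rois(annotations: AnnotationSet, mask: np.ndarray, *,
                             k: int = 4, slide_id: str = "slide",
                             voxel_area_mm2: float = 0.5,
                             compact: bool = False,
                             seed: int = 0) -> list[Lesion]:
    """k equally sized control ROIs from the never-G3+ part of the mask.

    Every voxel any observer labeled G3 or higher is removed from the
    prostate mask; the remaining voxels are sorted row-major and chunked
    into k equal parts (remainder voxels dropped and logged). With
    ``compact=True`` the partition instead comes from k-means on voxel
    coordinates, trimmed to equal sizes.
    """
    excluded = np.zeros_like(mask)
    for arr in annotations.labels.values():
        excluded |= np.isin(arr, G3_PLUS)
    unl = mask & ~excluded
    coords = np.argwhere(unl)  # row-major order
    if coords.shape[0] < k:
        raise ValueError(
            f"slide {slide_id}: only {coords.shape[0]} unlabeled-consensus "
            f"voxels, cannot build {k} ROIs"
        )
    size = coords.shape[0] // k
    dropped = coords.shape[0] - size * k
    if dropped:
        logger.debug("slide %s: dropping %d remainder voxels from consensus ROIs",
                     slide_id, dropped)
    if compact:
        from scipy.cluster.vq import kmeans2
        _, assign = kmeans2(coords.astype(float), k, seed=seed, minit="++")
        order = np.lexsort((np.arange(coords.shape[0]), assign))
        coords = coords[order]
    rois = []
    for i in range(k):
        chunk = coords[i * size:(i + 1) * size]
        rois.append(Lesion(
            lesion_id=f"{slide_id}:consensus:{i}", slide_id=slide_id,
            observer="consensus", class_label="unlabeled_consensus",
            rows=chunk[:, 0], cols=chunk[:, 1],
            voxel_area_mm2=voxel_area_mm2,
        ))
    return rois


def select_controls(mode: str, annotations: AnnotationSet, mask: np.ndarray, *,
                    observer: str = "obs", slide_id: str = "slide",
                    voxel_area_mm2: float = 0.5, min_area_vox: int = 201,
                    k: int = 4, seed: int = 0) -> list[Lesion]:
    """Benign control ROIs in single-annotator or multi-annotator style.

    ``mode='atrophy'`` returns the observer's benign-atrophy lesions
    (relabeled ``atrophy_control``); ``mode='unlabeled_consensus'``
    delegates to :func:`consensus_unlabeled_rois`.
    """
    if mode == "atrophy":
        lesions = extract_lesions(annotations[observer], mask, slide_id=slide_id,
                                  observer=observer, voxel_area_mm2=voxel_area_mm2,
                                  min_area_vox=min_area_vox,
                                  include_labels=(ATROPHY,))
        for les in lesions:
            les.class_label = "atrophy_control"
        if not lesions:
            warnings.warn(f"slide {slide_id}: no atrophy controls found",
                          stacklevel=2)
        return lesions
    if mode == "unlabeled_consensus":
        return consensus_unlabeled_rois(annotations, mask, k=k, slide_id=slide_id,
                                        voxel_area_mm2=voxel_area_mm2, seed=seed)
    raise ValueError(f"unknown control mode {mode!r}")


def lesion_group(class_label: str, hgpin_group: str = "benign") -> str:
    group = CLASS_GROUPS[class_label]
    if class_label == "HGPIN":
        group = hgpin_group
    return group


def build_training_table(lesions: list[Lesion], features: FeatureVolume,
                         density: DensityMap | None = None, *,
                         hgpin_group: str = "benign") -> pd.DataFrame:
    """One row per lesion: median feature vector, median density, group.

    Columns: lesion_id, slide_id, observer, class, area_vox, group,
    x_<feature> for each of the six features, and y (median epithelium
    density; absent if ``density`` is None, as for pure evaluation ROIs).
    """
    rows = []
    for les in lesions:
        vals = features.data[les.rows, les.cols, :]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"lesion {les.lesion_id}: non-finite feature voxels")
        rec = {
            "lesion_id": les.lesion_id,
            "slide_id": les.slide_id,
            "observer": les.observer,
            "class": les.class_label,
            "area_vox": les.area_vox,
            "group": lesion_group(les.class_label, hgpin_group),
        }
        med = np.median(vals, axis=0)
        for j, name in enumerate(features.feature_names):
            rec[f"x_{name}"] = med[j]
        if density is not None:
            dvals = density.data[les.rows, les.cols]
            if not np.all(np.isfinite(dvals)):
                raise ValueError(f"lesion {les.lesion_id}: non-finite density voxels")
            rec["y"] = float(np.median(dvals))
        rows.append(rec)
    cols = ["lesion_id", "slide_id", "observer", "class", "area_vox", "group"]
    cols += [f"x_{n}" for n in features.feature_names]
    if density is not None:
        cols.append("y")
    return pd.DataFrame(rows, columns=cols)
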