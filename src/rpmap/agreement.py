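"""Inter-observer annotation agreement via Krippendorff's alpha.

Annotations are first recoded to three ordinal categories — 0 unlabeled,
1 low grade, 2 high grade — and agreement is computed voxel-wise. Because
agreement statistics presume shared unit boundaries while observers draw
their own, the analysis is repeated once per observer: the unit set
("footprint") is the voxels that observer annotated, and every observer's
recoded label at those voxels (including 0 = left unlabeled) enters the
ratings matrix.

Alpha uses the coincidence-matrix formulation. For a units-by-observers
matrix, each unit u with m_u >= 2 ratings contributes ordered pairs with
weight 1/(m_u - 1) to the coincidence matrix o_ck; with marginals
n_c = sum_k o_ck and n = sum_c n_c,

    D_o = (1/n)           * sum_{c<k} o_ck    * delta2(c, k)
    D_e = (1/(n (n - 1))) * sum_{c<k} n_c n_k * delta2(c, k)
    alpha = 1 - D_o / D_e

with the ordinal distance
``delta2(c, k) = (sum_{g=c..k} n_g - (n_c + n_k)/2)^2`` and the nominal
distance 0/1. Confidence intervals are percentile bootstrap over slides
(not voxels), which respects the strong spatial correlation of labels
within a slide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .phantom import AnnotationSet

#: default 7-label -> 3-category ordinal recoding: benign atrophy joins the
#: unlabeled/benign background category, HGPIN is treated as low grade,
#: Gleason pattern 4 (fused or cribriform) and 5 are high grade.
DEFAULT_RECODING: dict[int, int] = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}

CATEGORY_NAMES = {0: "unlabeled", 1: "low_grade", 2: "high_grade"}


class UndefinedAlphaError(ValueError):
    """Alpha has no value (no rating variance, or no pairable units)."""


@dataclass
class AgreementResult:
    alpha: float
    D_o: float
    D_e: float
    n_units: int
    ci95: tuple[float, float] | None = None
    footprint_observer: str | None = None


def recode(annotations: AnnotationSet,
           recoding: Mapping[int, int] = DEFAULT_RECODING) -> dict[str, np.ndarray]:
    """Apply the ordinal recoding voxel-wise to every observer's map."""
    lut = np.full(7, -1, dtype=np.int16)
    for src, dst in recoding.items():
        lut[src] = dst
    out = {}
    for obs, arr in annotations.labels.items():
        bad = ~np.isin(arr, list(recoding))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"observer {obs!r}: label {arr[r, c]} at voxel ({r}, {c}) "
                "is not in the recoding"
            )
        out[obs] = lut[arr]
    return out


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def _unit_category_counts(ratings: np.ndarray, categories: np.ndarray) -> np.ndarray:
    """units x categories count matrix; NaN entries are missing ratings."""
    counts = np.zeros((ratings.shape[0], categories.size), dtype=float)
    for j, cat in enumerate(categories):
        counts[:, j] = np.sum(ratings == cat, axis=1)
    return counts


def coincidence_matrix(unit_counts: np.ndarray) -> np.ndarray:
    """Pairable-value coincidence matrix from per-unit category counts."""
    m_u = unit_counts.sum(axis=1)
    pairable = m_u >= 2
    if not pairable.any():
        raise UndefinedAlphaError("every unit has fewer than 2 ratings")
    c = unit_counts[pairable]
    w = 1.0 / (m_u[pairable] - 1.0)
    # ordered-pair counts within a unit: n_uc * n_uk (c != k), n_uc (n_uc - 1) on
    # the diagonal, each down-weighted by 1/(m_u - 1)
    O = np.einsum("u,uc,uk->ck", w, c, c)
    O[np.diag_indices_from(O)] -= (w[:, None] * c).sum(axis=0)
    return O


def _ordinal_delta2(n_marg: np.ndarray) -> np.ndarray:
    """Ordinal squared distance matrix from coincidence marginals."""
    K = n_marg.size
    cum = np.concatenate([[0.0], np.cumsum(n_marg)])
    d2 = np.zeros((K, K))
    for c in range(K):
        for k in range(c + 1, K):
            span = cum[k + 1] - cum[c]  # sum of n_g for g in c..k
            d2[c, k] = d2[k, c] = (span - (n_marg[c] + n_marg[k]) / 2.0) ** 2
    return d2


def alpha_from_coincidence(O: np.ndarray, metric: str = "ordinal") -> tuple[float, float, float]:
    """(alpha, D_o, D_e) from a coincidence matrix."""
    n_marg = O.sum(axis=1)
    n = n_marg.sum()
    if metric == "ordinal":
        d2 = _ordinal_delta2(n_marg)
    elif metric == "nominal":
        d2 = 1.0 - np.eye(n_marg.size)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    iu = np.triu_indices(n_marg.size, k=1)
    num = float((O[iu] * d2[iu]).sum())
    den = float((np.outer(n_marg, n_marg)[iu] * d2[iu]).sum())
    if den == 0.0:
        raise UndefinedAlphaError(
            "expected disagreement is zero (all ratings in one category)"
        )
    D_o = num / n
    D_e = den / (n * (n - 1.0))
    return 1.0 - D_o / D_e, D_o, D_e


def krippendorff_alpha(ratings: np.ndarray, metric: str = "ordinal") -> AgreementResult:
    """Alpha for a units x observers ratings matrix (NaN = missing).

    Requires at least one unit with >= 2 ratings and at least two distinct
    categories overall; otherwise raises :class:`UndefinedAlphaError`.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a units x observers matrix")
    observed = ratings[np.isfinite(ratings)]
    if observed.size == 0:
        raise UndefinedAlphaError("no ratings at all")
    categories = np.unique(observed)
    counts = _unit_category_counts(ratings, categories)
    O = coincidence_matrix(counts)
    alpha, D_o, D_e = alpha_from_coincidence(O, metric=metric)
    n_units = int((counts.sum(axis=1) >= 2).sum())
    return AgreementResult(alpha=alpha, D_o=D_o, D_e=D_e, n_units=n_units)


# ---------------------------------------------------------------------------
# per-footprint analysis over a cohort of slides
# ---------------------------------------------------------------------------

def footprint_counts(ordinal_maps: Mapping[str, np.ndarray],
                     footprint_observer: str,
                     categories: Sequence[int] = (0, 1, 2)) -> np.ndarray:
    """Per-unit category counts on one observer's footprint.

    Units are the voxels the footprint observer labeled non-zero; the
    ratings at each unit are every observer's recoded category there
    (an observer's 0 counts as a rating of the unlabeled category, not as
    missing).
    """
    fp = ordinal_maps[footprint_observer] != 0
    if not fp.any():
        raise ValueError(f"observer {footprint_observer!r} has an empty footprint")
    stack = np.stack([m[fp] for m in ordinal_maps.values()], axis=1)
    return _unit_category_counts(stack.astype(float), np.asarray(categories, float))


def alpha_per_footprint(ordinal_maps: Mapping[str, np.ndarray],
                        footprint_observer: str,
                        metric: str = "ordinal") -> AgreementResult:
    counts = footprint_counts(ordinal_maps, footprint_observer)
    alpha, D_o, D_e = alpha_from_coincidence(coincidence_matrix(counts), metric=metric)
    return AgreementResult(alpha=alpha, D_o=D_o, D_e=D_e,
                           n_units=counts.shape[0],
                           footprint_observer=footprint_observer)


def bootstrap_ci(statistic_fn: Callable[[Sequence], float],
                 units: Sequence, n_boot: int = 500, level: float = 0.95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Percentile bootstrap interval resampling ``units`` with replacement.

    ``units`` are typically slides. Resamples on which the statistic is
    undefined are dropped; more than 50% undefined raises.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 resampling units")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stats = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(units), size=len(units))
        try:
            stats.append(statistic_fn([units[i] for i in idx]))
        except (UndefinedAlphaError, ValueError):
            failed += 1
    if failed > n_boot / 2:
        raise UndefinedAlphaError(
            f"statistic undefined on {failed}/{n_boot} bootstrap resamples"
        )
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [q, 1.0 - q])
    return float(lo), float(hi)


def cohort_agreement(annotation_sets: Sequence[AnnotationSet],
                     recoding: Mapping[int, int] = DEFAULT_RECODING,
                     metric: str = "ordinal", n_boot: int = 500,
                     level: float = 0.95, seed: int = 0) -> list[AgreementResult]:
    """Per-footprint alpha pooled over slides, with slide-bootstrap CIs.

    Footprints with no annotated voxels on any slide are skipped. The
    point estimate pools voxels across all slides; the CI resamples slides.
    """
    ordinal_per_slide = [recode(a, recoding) for a in annotation_sets]
    observers = annotation_sets[0].observers
    results = []
    for obs in observers:
        per_slide_counts = []
        for maps in ordinal_per_slide:
            if (maps[obs] != 0).any():
                per_slide_counts.append(footprint_counts(maps, obs))
        if not per_slide_counts:
            continue
        pooled = np.concatenate(per_slide_counts, axis=0)
        alpha, D_o, D_e = alpha_from_coincidence(coincidence_matrix(pooled), metric)

        def stat(slide_counts):
            c = np.concatenate(slide_counts, axis=0)
            return alpha_from_coincidence(coincidence_matrix(c), metric)[0]

        ci = bootstrap_ci(stat, per_slide_counts, n_boot=n_boot, level=level,
                          seed=np.random.default_rng(
                              np.random.SeedSequence(seed, spawn_key=(3, observers.index(obs)))))
        if not (ci[0] <= alpha <= ci[1]):
            import logging
            logging.getLogger(__name__).warning(
                "footprint %s: point alpha %.4f outside bootstrap CI %s "
                "(bootstrap noise)", obs, alpha, ci)
        results.append(AgreementResult(alpha=alpha, D_o=D_o, D_e=D_e,
                                       n_units=pooled.shape[0], ci95=ci,
                                       footprint_observer=obs))
    return results
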