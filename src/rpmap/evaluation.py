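"""Statistical evaluation: empirical ROC, correlated-AUC comparison, and
repeated-measures ANOVA over the per-pathologist models.

The classification task is discriminating high-grade lesions (Gleason
pattern 4 and above) from low-grade (pattern 3) and benign regions, scored
by the ROI-median predicted epithelium density. AUC is computed by the
Mann–Whitney statistic with ties counted one half. Two AUCs measured on the
same lesions are compared with the Hanley–McNeil correlated-ROC z-test,

    z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2),
    SE^2 = [A(1-A) + (N1-1)(Q1 - A^2) + (N2-1)(Q2 - A^2)] / (N1 N2),
    Q1 = A/(2-A),  Q2 = 2A^2 / (1+A),

with N1 positives, N2 negatives, and the correlation term r taken as the
mean of the Kendall tau between the two score vectors on the positives and
on the negatives (the inputs to Hanley and McNeil's lookup table; a
user-supplied table can be interpolated instead). The per-model mean
predicted densities are compared by a one-way within-subject (repeated
measures) ANOVA with the lesion as subject, followed by Tukey's honest
significant difference on the within-subject error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n2 = int(np.sum(labels == 0))
    if n1 == 0 or n2 == 0:
        raise ValueError(f"both classes required (got {n1} positives, {n2} negatives)")
    if n1 + n2 != labels.size:
        raise ValueError("labels must be binary 0/1")
    return n1, n2


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney U probability, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1, n2 = _check_labels(labels)
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def empirical_roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Staircase ROC from a threshold sweep over the unique scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1, n2 = _check_labels(labels)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], labels[order]
    # step only where the score changes (ties move diagonally in one jump)
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(lab == 1)[idx]
    fps = np.cumsum(lab == 0)[idx]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n2]
    thresholds = np.r_[np.inf, s[idx]]
    return RocCurve(scores=scores, labels=labels, fpr=fpr, tpr=tpr,
                    thresholds=thresholds,
                    auc=auc_mann_whitney(scores, labels))


def classification_labels(groups: Sequence[str]) -> np.ndarray:
    """Binary task labels: high grade -> 1, low grade and benign -> 0."""
    out = np.asarray([1 if g == "high" else 0 for g in groups])
    return out


def auc_bootstrap_ci(scores: np.ndarray, labels: np.ndarray, *,
                     n_boot: int = 500, level: float = 0.95,
                     seed: int | np.random.Generator = 0,
                     stratified: bool = True) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over lesion resamples.

    Stratified resampling (default) keeps both classes present in every
    resample; unstratified resamples that lose a class are skipped, and
    more than 20% skipped is an error.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    _check_labels(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    aucs = []
    skipped = 0
    for _ in range(n_boot):
        if stratified:
            idx = np.r_[rng.choice(pos, pos.size, replace=True),
                        rng.choice(neg, neg.size, replace=True)]
        else:
            idx = rng.integers(0, labels.size, labels.size)
            if labels[idx].min() == labels[idx].max():
                skipped += 1
                continue
        aucs.append(auc_mann_whitney(scores[idx], labels[idx]))
    if skipped > 0.2 * n_boot:
        raise ValueError(f"{skipped}/{n_boot} bootstrap resamples lost a class")
    q = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [q, 1.0 - q])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Hanley–McNeil correlated-ROC comparison
# ---------------------------------------------------------------------------

@dataclass
class RocComparison:
    A1: float
    A2: float
    SE1: float
    SE2: float
    N1: int
    N2: int
    Q1: tuple[float, float]
    Q2: tuple[float, float]
    r: float
    z: float
    p: float


def hanley_mcneil_q(auc: float) -> tuple[float, float]:
    """(Q1, Q2) = (A/(2-A), 2A^2/(1+A)).

    Q1 is the probability two randomly chosen positives both outrank a
    random negative and Q2 the mirror-image quantity, evaluated under the
    negative-exponential ROC model; both equal 1/3 at A = 1/2 and 1 at
    A = 1.
    """
    return auc / (2.0 - auc), 2.0 * auc ** 2 / (1.0 + auc)


def hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    """Standard error of an AUC from positive/negative counts alone."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc outside [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one positive and one negative")
    q1, q2 = hanley_mcneil_q(auc)
    var = (auc * (1.0 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def roc_compare(scores1: np.ndarray, scores2: np.ndarray, labels: np.ndarray, *,
                r_lookup: Callable[[float, float], float] | None = None,
                as_printed: bool = False) -> RocComparison:
    """Correlated-ROC z-test for two score vectors on the same lesions.

    ``r_lookup(avg_auc, avg_tau) -> r`` may supply a tabulated correlation
    term; by default r is the mean of the Kendall tau on positives and on
    negatives. ``as_printed=True`` selects an audit variant that takes the
    typeset equations at face value (Q1 = A(2-A) and the denominator
    SE1^2 - SE2^2 - 2 r SE1 SE2 without a radical); the default is the
    standard Hanley–McNeil form.
    """
    scores1 = np.asarray(scores1, float)
    scores2 = np.asarray(scores2, float)
    labels = np.asarray(labels)
    n1, n2 = _check_labels(labels)
    if scores1.size != labels.size or scores2.size != labels.size:
        raise ValueError("score vectors and labels must align")
    if n1 < 2 or n2 < 2:
        raise ValueError("Kendall tau needs >= 2 positives and >= 2 negatives")
    a1 = auc_mann_whitney(scores1, labels)
    a2 = auc_mann_whitney(scores2, labels)
    if as_printed:
        def _se_printed(a):
            q1, q2 = a * (2.0 - a), 2.0 * a ** 2 / (1.0 + a)
            var = (a * (1.0 - a) + (n1 - 1) * (q1 - a ** 2)
                   + (n2 - 1) * (q2 - a ** 2)) / (n1 * n2)
            return float(np.sqrt(max(var, 0.0)))

        se1, se2 = _se_printed(a1), _se_printed(a2)
    else:
        se1 = hanley_mcneil_se(a1, n1, n2)
        se2 = hanley_mcneil_se(a2, n1, n2)
    pos, neg = labels == 1, labels == 0
    tau_pos = stats.kendalltau(scores1[pos], scores2[pos]).statistic
    tau_neg = stats.kendalltau(scores1[neg], scores2[neg]).statistic
    tau_pos = 0.0 if np.isnan(tau_pos) else float(tau_pos)
    tau_neg = 0.0 if np.isnan(tau_neg) else float(tau_neg)
    avg_tau = (tau_pos + tau_neg) / 2.0
    if r_lookup is not None:
        r = float(r_lookup((a1 + a2) / 2.0, avg_tau))
    else:
        r = avg_tau
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation term r={r} outside [-1, 1]")
    if as_printed:
        denom = se1 ** 2 - se2 ** 2 - 2.0 * r * se1 * se2
    else:
        var = se1 ** 2 + se2 ** 2 - 2.0 * r * se1 * se2
        if -1e-12 * (se1 ** 2 + se2 ** 2) <= var < 0.0:
            var = 0.0  # rounding residue when r = 1 and SE1 = SE2
        if var < 0:
            raise ValueError(
                f"negative variance in z denominator (SE1={se1}, SE2={se2}, "
                f"r={r}); the correlation term is inconsistent with the SEs"
            )
        denom = np.sqrt(var)
    if a1 == a2:
        z = 0.0  # identical AUCs: no evidence either way even if denom == 0
    elif denom == 0.0:
        raise ZeroDivisionError("zero denominator with unequal AUCs")
    else:
        z = float((a1 - a2) / denom)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RocComparison(A1=a1, A2=a2, SE1=se1, SE2=se2, N1=n1, N2=n2,
                         Q1=hanley_mcneil_q(a1), Q2=hanley_mcneil_q(a2),
                         r=r, z=z, p=p)


def orient_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Flip the score sign if needed so AUC >= 0.5 (e.g. ADC, where lower
    values indicate higher grade). Returns (scores, sign)."""
    scores = np.asarray(scores, float)
    if auc_mann_whitney(scores, labels) < 0.5:
        return -scores, -1
    return scores, 1


# ---------------------------------------------------------------------------
# repeated-measures ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    F: float
    df_model: int
    df_error: int
    p: float
    grand_mean: float
    model_means: np.ndarray
    ms_error: float
    tukey: pd.DataFrame
    degenerate: bool = False
    model_names: list[str] = field(default_factory=list)


def rm_anova_tukey(Y: np.ndarray, model_names: Sequence[str] | None = None,
                   alpha: float = 0.05) -> RmAnovaResult:
    """One-way within-subject ANOVA over a complete lesions x models matrix.

    The per-lesion (subject) effect is removed before forming the error
    term: F = MS_model / MS_error with df = (k-1, (k-1)(n-1)). Tukey's HSD
    uses q_ij = |mean_i - mean_j| / sqrt(MS_error / n) against the
    studentized range with (k, df_error).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a lesions x models matrix")
    n, k = Y.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 models and >= 3 lesions")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells: the design must be complete")
    names = list(model_names) if model_names is not None else [f"m{i+1}" for i in range(k)]
    grand = Y.mean()
    col_means = Y.mean(axis=0)
    row_means = Y.mean(axis=1)
    ss_model = n * np.sum((col_means - grand) ** 2)
    ss_subject = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_error = max(ss_total - ss_model - ss_subject, 0.0)
    # an error SS at rounding level of the decomposition counts as zero
    tiny = 1e-12 * max(ss_total, np.abs(Y).max() ** 2, 1e-300)
    if ss_error <= tiny:
        ss_error = 0.0
    if ss_model <= tiny:
        ss_model = 0.0
    df_model, df_error = k - 1, (k - 1) * (n - 1)
    ms_model = ss_model / df_model
    ms_error = ss_error / df_error
    degenerate = False
    if ms_model == 0.0:
        F, p = 0.0, 1.0
        degenerate = ms_error == 0.0
    elif ms_error == 0.0:
        F, p, degenerate = np.inf, 0.0, True
    else:
        F = ms_model / ms_error
        p = float(stats.f.sf(F, df_model, df_error))
    pairs = []
    sem = np.sqrt(ms_error / n) if ms_error > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = col_means[i] - col_means[j]
            if sem > 0:
                q = abs(diff) / sem
                p_adj = float(stats.studentized_range.sf(q, k, df_error))
            else:
                q = 0.0 if diff == 0 else np.inf
                p_adj = 1.0 if diff == 0 else 0.0
            pairs.append({"pair": f"{names[i]} vs {names[j]}",
                          "mean_diff": float(diff), "q": float(q),
                          "p_adj": p_adj, "significant": p_adj < alpha})
    return RmAnovaResult(F=float(F), df_model=df_model, df_error=df_error,
                         p=float(p), grand_mean=float(grand),
                         model_means=col_means, ms_error=float(ms_error),
                         tukey=pd.DataFrame(pairs), degenerate=degenerate,
                         model_names=names)
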