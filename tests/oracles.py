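"""Independent brute-force oracles shared by the test modules.

Each function recomputes a statistic from first principles (explicit loops,
exhaustive enumeration), deliberately sharing no code with the package.
"""

import numpy as np


def alpha_bruteforce(ratings, metric="ordinal"):
    """Krippendorff's alpha via explicit pairwise double sums."""
    from rpmap import UndefinedAlphaError

    ratings = np.asarray(ratings, dtype=float)
    units = [row[np.isfinite(row)] for row in ratings]
    pairable = [u for u in units if u.size >= 2]
    if not pairable:
        raise UndefinedAlphaError("no pairable units")
    values = np.concatenate(pairable)
    cats = np.unique(values)
    marg = {c: float(np.sum(values == c)) for c in cats}
    n = float(values.size)

    def delta2(a, b):
        if a == b:
            return 0.0
        if metric == "nominal":
            return 1.0
        lo, hi = min(a, b), max(a, b)
        span = sum(marg[c] for c in cats if lo <= c <= hi)
        return (span - (marg[a] + marg[b]) / 2.0) ** 2

    d_o = 0.0
    for u in pairable:
        m = u.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_o += delta2(u[i], u[j]) / (m - 1)
    d_o /= n
    d_e = 0.0
    for a in values:
        for b in values:
            d_e += delta2(a, b)
    d_e /= n * (n - 1.0)
    if d_e == 0.0:
        raise UndefinedAlphaError("no expected disagreement")
    return 1.0 - d_o / d_e


def auc_pair_counting(scores, labels):
    """Exhaustive concordant-pair count with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def pls1_nipals_loops(X, y, Xnew):
    """Predict y at Xnew via one NIPALS component, all plain loops."""
    n, k = len(X), len(X[0])
    xm = [sum(X[i][j] for i in range(n)) / n for j in range(k)]
    xs = [
        (sum((X[i][j] - xm[j]) ** 2 for i in range(n)) / (n - 1)) ** 0.5
        for j in range(k)
    ]
    ym = sum(y) / n
    Xc = [[(X[i][j] - xm[j]) / xs[j] for j in range(k)] for i in range(n)]
    yc = [y[i] - ym for i in range(n)]
    w = [sum(Xc[i][j] * yc[i] for i in range(n)) for j in range(k)]
    norm = sum(v * v for v in w) ** 0.5
    w = [v / norm for v in w]
    t = [sum(Xc[i][j] * w[j] for j in range(k)) for i in range(n)]
    tt = sum(v * v for v in t)
    q = sum(yc[i] * t[i] for i in range(n)) / tt
    preds = []
    for row in Xnew:
        score = sum((row[j] - xm[j]) / xs[j] * w[j] for j in range(k))
        preds.append(ym + q * score)
    return preds


def anova_ss_oracle(Y):
    """Brute-force within-subject sums-of-squares decomposition.

    Returns (F, MS_error).
    """
    n, k = len(Y), len(Y[0])
    grand = sum(Y[i][j] for i in range(n) for j in range(k)) / (n * k)
    col = [sum(Y[i][j] for i in range(n)) / n for j in range(k)]
    row = [sum(Y[i][j] for j in range(k)) / k for i in range(n)]
    ss_model = n * sum((c - grand) ** 2 for c in col)
    ss_subj = k * sum((r - grand) ** 2 for r in row)
    ss_tot = sum((Y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_model - ss_subj
    ms_model = ss_model / (k - 1)
    ms_err = ss_err / ((k - 1) * (n - 1))
    return ms_model / ms_err, ms_err
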