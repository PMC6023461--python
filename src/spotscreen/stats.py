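"""Heteroscedastic statistics for platform comparison and screen design.

Implements the analysis layer used to compare cell-array and multi-well
readouts: Welch's one-way ANOVA (unequal variances), the Games-Howell
post-hoc test with an internally integrated studentized-range
distribution, replicate Pearson correlation, Bartlett and two-sided F
variance tests, intra-plate variance, and the replicate-equivalence rule
n_a = (Var_a / Var_w) * n_w giving the number of array replicates needed
to match the standard error of n_w well replicates.

Tests operate on position-level readouts (one value per spot or well),
the observation unit that makes spot-to-spot and well-to-well variability
comparable across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "GroupSummary",
    "WelchAnovaResult",
    "PairwiseComparison",
    "ReplicateEquivalence",
    "ReplicateCorrelation",
    "summarize",
    "welch_anova",
    "studentized_range_cdf",
    "games_howell",
    "pearson_between_replicates",
    "bartlett_test",
    "variance_f_test",
    "intra_plate_variance",
    "replicates_needed",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: size, mean, unbiased variance."""

    label: str
    n: int
    mean: float
    variance: float


def summarize(groups: Mapping[str, Sequence[float]] | Iterable[GroupSummary]) -> list[GroupSummary]:
    """Normalize raw-sample mappings or summary iterables to summaries."""
    if isinstance(groups, Mapping):
        out = []
        for label, x in groups.items():
            x = np.asarray(x, float)
            if len(x) < 2:
                raise ValueError(f"group {label!r} needs n >= 2 observations")
            out.append(GroupSummary(str(label), len(x), float(x.mean()), float(x.var(ddof=1))))
        return out
    return list(groups)


@dataclass(frozen=True)
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p: float


def welch_anova(groups) -> WelchAnovaResult:
    """Welch's (1951) heteroscedastic one-way ANOVA.

    With weights w_i = n_i / s_i^2 and weighted grand mean x_w:
    F = [sum w_i (x_i - x_w)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) * L],
    L = sum (1 - w_i/sum w)^2 / (n_i - 1) ; df1 = k-1, df2 = (k^2-1)/(3L).
    """
    gs = summarize(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("welch_anova needs at least two groups")
    n = np.array([g.n for g in gs], float)
    m = np.array([g.mean for g in gs], float)
    v = np.array([g.variance for g in gs], float)
    if np.any(n < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(v <= 0):
        raise ValueError("every group needs positive variance")
    w = n / v
    sw = w.sum()
    xw = (w * m).sum() / sw
    lam = (((1.0 - w / sw) ** 2) / (n - 1.0)).sum()
    num = (w * (m - xw) ** 2).sum() / (k - 1)
    F = num / (1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * lam)
    df1 = float(k - 1)
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return WelchAnovaResult(float(F), df1, float(df2), p)


# ---------------------------------------------------------------------------
# studentized range distribution


def _gl_nodes(n: int, a: float, b: float, panels: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on [a, b] split into panels."""
    x, w = np.polynomial.legendre.leggauss(n)
    edges = np.linspace(a, b, panels + 1)
    half = np.diff(edges) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def _range_cdf_std(r: np.ndarray, k: int, nz: int = 64, panels: int = 4) -> np.ndarray:
    """P(range of k iid standard normals <= r), vectorized over r."""
    z, wz = _gl_nodes(nz, -9.0, 9.0, panels)
    phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    Fz = special.ndtr(z)
    diff = Fz[None, :] - special.ndtr(z[None, :] - r[:, None])
    np.clip(diff, 0.0, 1.0, out=diff)
    return k * (diff ** (k - 1) * (phi * wz)[None, :]).sum(axis=1)


def studentized_range_cdf(q: float, k: int, df: float, tol: float = 1e-8) -> float:
    """CDF of the studentized range Q = range(k normals) / s_df.

    Numerically integrates the scale mixture
    P(Q <= q) = Int_0^inf f_df(s) * P(range <= q s) ds, where s is a
    chi_df / sqrt(df) scale factor, with composite Gauss-Legendre panels
    doubled until successive refinements agree to ``tol`` (default well
    below the 1e-6 accuracy target).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if df <= 0:
        raise ValueError("df must be positive")
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0:
        return 0.0
    # integration support of the chi_df/sqrt(df) scale density
    s_lo = math.sqrt(sps.chi2.ppf(1e-14, df) / df)
    s_hi = math.sqrt(sps.chi2.isf(1e-14, df) / df)
    log_norm = (df / 2.0) * math.log(df) - math.lgamma(df / 2.0) - (df / 2.0 - 1.0) * math.log(2.0)

    def estimate(panels: int) -> float:
        s, ws = _gl_nodes(24, s_lo, s_hi, panels)
        log_f = log_norm + (df - 1.0) * np.log(s) - df * s * s / 2.0
        inner = _range_cdf_std(q * s, k, nz=24, panels=panels)
        return float((np.exp(log_f) * inner * ws).sum())

    panels = 2
    prev = estimate(panels)
    for _ in range(8):
        panels *= 2
        cur = estimate(panels)
        if abs(cur - prev) < tol:
            return float(min(max(cur, 0.0), 1.0))
        prev = cur
    return float(min(max(prev, 0.0), 1.0))


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    diff: float
    se: float
    df: float
    q: float
    p: float


def games_howell(groups) -> list[PairwiseComparison]:
    """Games-Howell pairwise post-hoc test for heteroscedastic groups.

    Per pair: SE = sqrt(s_i^2/n_i + s_j^2/n_j), Welch-Satterthwaite
    df_ij, q = sqrt(2) |x_i - x_j| / SE, and the adjusted
    p = 1 - F_Q(q; k, df_ij) from the studentized range with k equal to
    the total number of groups.  The family adjustment is inherent; no
    further multiple-testing correction is applied.
    """
    gs = summarize(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("games_howell needs at least two groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = gs[i], gs[j]
            if a.n < 2 or b.n < 2:
                raise ValueError("every group needs n >= 2")
            if a.variance <= 0 or b.variance <= 0:
                raise ValueError("every group needs positive variance")
            va, vb = a.variance / a.n, b.variance / b.n
            se = math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va * va / (a.n - 1) + vb * vb / (b.n - 1))
            diff = a.mean - b.mean
            q = math.sqrt(2.0) * abs(diff) / se
            p = 1.0 - studentized_range_cdf(q, k, df)
            out.append(PairwiseComparison(a.label, b.label, diff, se, df, q, p))
    return out


@dataclass(frozen=True)
class ReplicateCorrelation:
    mean_r: float
    pairwise: dict[tuple, float]


def pearson_between_replicates(
    table: pd.DataFrame,
    value: str = "frac_spindle",
    pairing: Sequence[str] = ("condition", "position"),
) -> ReplicateCorrelation:
    """Pearson correlation of position-level readouts between replicates.

    Positions are matched on ``pairing`` across replicates; with three
    replicates the mean of the three pairwise r values is reported.
    """
    wide = table.pivot_table(index=list(pairing), columns="replicate", values=value)
    wide = wide.dropna()
    reps = list(wide.columns)
    if len(reps) < 2:
        raise ValueError("need at least two replicates")
    if len(wide) < 3:
        raise ValueError("need at least three paired positions")
    pairwise = {}
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            x = wide[reps[i]].to_numpy(float)
            y = wide[reps[j]].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError("zero variance in a replicate vector")
            pairwise[(reps[i], reps[j])] = float(sps.pearsonr(x, y)[0])
    return ReplicateCorrelation(float(np.mean(list(pairwise.values()))), pairwise)


def bartlett_test(groups) -> tuple[float, float, float]:
    """Bartlett's homogeneity-of-variances test.

    Returns (chi-square statistic, k-1 degrees of freedom, p); computed
    from group summaries so it accepts raw samples or (n, variance) pairs.
    """
    gs = summarize(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("bartlett_test needs at least two groups")
    n = np.array([g.n for g in gs], float)
    v = np.array([g.variance for g in gs], float)
    if np.any(v <= 0):
        raise ValueError("every group needs positive variance")
    N = n.sum()
    sp2 = ((n - 1) * v).sum() / (N - k)
    stat = (N - k) * math.log(sp2) - ((n - 1) * np.log(v)).sum()
    corr = 1.0 + (np.sum(1.0 / (n - 1)) - 1.0 / (N - k)) / (3.0 * (k - 1))
    stat /= corr
    df = float(k - 1)
    return float(stat), df, float(sps.chi2.sf(stat, df))


def variance_f_test(a, b) -> tuple[float, tuple[float, float], float]:
    """Two-sided F test of equal variances (R ``var.test`` convention).

    Returns (F = s_a^2 / s_b^2, (df_a, df_b), two-sided p = 2 * min(tail,
    1 - tail), capped at 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 or vb <= 0:
        raise ValueError("both samples need positive variance")
    F = va / vb
    dfa, dfb = float(len(a) - 1), float(len(b) - 1)
    cdf = sps.f.cdf(F, dfa, dfb)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return float(F), (dfa, dfb), float(p)


def intra_plate_variance(
    table: pd.DataFrame,
    value: str = "frac_spindle",
    by_condition: bool = True,
) -> pd.DataFrame:
    """Variance of position-level readouts within each replicate plate or
    array, averaged across replicates.

    Replicates contributing fewer than two positions are excluded with a
    warning.  Returns one row per condition (or a single pooled row).
    """
    import warnings as _w

    keys = ["condition", "replicate"] if by_condition else ["replicate"]
    rows = []
    for key, grp in table.groupby(keys):
        if len(grp) < 2:
            _w.warn(f"{key}: fewer than two positions, excluded", stacklevel=2)
            continue
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["variance"] = float(grp[value].var(ddof=1))
        rows.append(rec)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        return pd.DataFrame(columns=["condition", "mean_intra_variance", "n_replicates"])
    if by_condition:
        agg = per_rep.groupby("condition")["variance"].agg(["mean", "count"])
        return agg.rename(
            columns={"mean": "mean_intra_variance", "count": "n_replicates"}
        ).reset_index()
    return pd.DataFrame(
        {
            "condition": ["all"],
            "mean_intra_variance": [per_rep["variance"].mean()],
            "n_replicates": [len(per_rep)],
        }
    )


@dataclass(frozen=True)
class ReplicateEquivalence:
    """Array replicates needed to match the well-plate standard error."""

    var_a: float
    var_w: float
    n_w: int
    n_exact: float
    n_ceiling: int


def replicates_needed(var_a: float, var_w: float, n_w: int) -> ReplicateEquivalence:
    """Replicate-equivalence rule n_a = (Var_a / Var_w) * n_w.

    The standard error of a mean over n replicates is sqrt(Var/n), so
    matching the well-plate standard error requires multiplying the
    replicate count by the quotient of the variances.  The exact value
    and its ceiling (for planning) are both reported.
    """
    if var_w <= 0:
        raise ValueError("var_w must be positive")
    if var_a < 0 or n_w < 1:
        raise ValueError("var_a must be >= 0 and n_w >= 1")
    exact = var_a / var_w * n_w
    return ReplicateEquivalence(var_a, var_w, int(n_w), float(exact), math.ceil(exact))
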