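"""Study statistics: normality-gated tests and GAPDH-normalized expression.

Between-group comparisons use the Welch-corrected unpaired t-test when both
groups pass a Shapiro–Wilk normality check and the Mann–Whitney U test
otherwise; within-group comparisons across the four monitoring periods use
one-way repeated-measures ANOVA or the Friedman test under the same gate.
Mann–Whitney p-values are exact by full enumeration for the small group
sizes of this design (n = 5 + 7), with a tie-corrected normal approximation
beyond that.  Gene expression is normalized per animal by the GAPDH
housekeeping level before Welch comparisons.

All p-values are two-sided; no multiple-testing correction is applied, and
SEM uses the n-1 variance denominator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "TestResult",
    "normality_gate",
    "welch_t",
    "mann_whitney",
    "rm_anova",
    "friedman",
    "compare_groups",
    "within_group_trend",
    "relative_expression",
]

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: float | tuple | None
    p: float
    summaries: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if not math.isnan(self.p) and not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


def _mean_sem(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")
    return {"mean": float(np.mean(x)), "sem": sem, "n": len(x)}


def _median_iqr(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": len(x)}


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(*groups, alpha: float = 0.05) -> str:
    """Choose 'parametric' unless any group fails Shapiro–Wilk at ``alpha``.

    Groups with n < 3 or degenerate (constant) values force the
    nonparametric route with a warning.
    """
    for g in groups:
        x = np.asarray(g, dtype=float)
        if len(x) < 3:
            warnings.warn("group too small for a normality test; using nonparametric")
            return NONPARAMETRIC
        if np.ptp(x) == 0:
            warnings.warn("degenerate (constant) group; using nonparametric")
            return NONPARAMETRIC
        if sst.shapiro(x).pvalue < alpha:
            return NONPARAMETRIC
    return PARAMETRIC


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def welch_t(x, y) -> TestResult:
    """Welch-corrected unpaired t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need n >= 2")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sst.t.sf(abs(t), df)
    return TestResult(
        method="welch_t",
        statistic=float(t),
        df=float(df),
        p=float(min(p, 1.0)),
        summaries={"x": _mean_sem(x), "y": _mean_sem(y)},
    )


def _u_statistic(ranks_x_sum: float, nx: int) -> float:
    return ranks_x_sum - nx * (nx + 1) / 2.0


def mann_whitney(x, y, exact_max_n: int = 14) -> TestResult:
    """Mann–Whitney U with mid-rank ties.

    Two-sided p is exact by full enumeration of all C(nx+ny, nx) group
    assignments when the pooled size is at most ``exact_max_n`` (the null U
    distribution is symmetric about nx*ny/2, ties included); otherwise a
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.concatenate([x, y])
    ranks = sst.rankdata(pooled)
    u_obs = _u_statistic(float(np.sum(ranks[:nx])), nx)
    mu = nx * ny / 2.0
    n = nx + ny

    if n <= exact_max_n:
        dev_obs = abs(u_obs - mu) - 1e-9
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), nx):
            u = _u_statistic(sum(ranks[i] for i in comb), nx)
            if abs(u - mu) >= dev_obs:
                count += 1
            total += 1
        p = count / total
        method = "mann_whitney_exact"
    else:
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            p = 2.0 * sst.norm.sf(max(z, 0.0))
        method = "mann_whitney_normal"
    return TestResult(
        method=method,
        statistic=float(u_obs),
        df=None,
        p=float(min(p, 1.0)),
        summaries={"x": _median_iqr(x), "y": _median_iqr(y)},
    )


# ---------------------------------------------------------------------------
# within-group (repeated measures) tests
# ---------------------------------------------------------------------------

def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a subjects x periods matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported (no imputation)")
    return m


def rm_anova(matrix) -> TestResult:
    """One-way repeated-measures ANOVA (subjects x periods).

    F = MS_period / MS_error after removing the subject effect, with
    df = (k-1, (n-1)(k-1)).  Sphericity is not corrected; only the omnibus
    p-value is reported.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 periods")
    grand = m.mean()
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_period = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_period
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    warns = ()
    if ms_err <= 0:
        f = 0.0 if ss_period <= 0 else float("inf")
        p = 1.0 if ss_period <= 0 else 0.0
        warns = ("zero within-subject error variance",)
    else:
        f = (ss_period / df1) / ms_err
        p = float(sst.f.sf(f, df1, df2))
    return TestResult(
        method="rm_anova",
        statistic=float(f),
        df=(df1, df2),
        p=p,
        summaries={"period_means": m.mean(axis=0).tolist()},
        warnings=warns,
    )


def friedman(matrix) -> TestResult:
    """Friedman chi-square on within-subject mid-ranks, tie-corrected.

    chi2 = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1), divided by the tie
    correction C = 1 - sum(t^3 - t) / (n k (k^2 - 1)); df = k - 1.  Fully
    tied data (C = 0) yields chi2 = 0 flagged degenerate.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 subjects and >= 3 periods")
    ranks = np.apply_along_axis(sst.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0:
        return TestResult(
            method="friedman",
            statistic=0.0,
            df=float(k - 1),
            p=float("nan"),
            warnings=("degenerate: all within-subject values tied",),
        )
    chi2 = chi2 / c
    p = float(sst.chi2.sf(chi2, k - 1))
    return TestResult(
        method="friedman",
        statistic=float(chi2),
        df=float(k - 1),
        p=p,
        summaries={"rank_sums": rj.tolist()},
    )


# ---------------------------------------------------------------------------
# gated dispatchers
# ---------------------------------------------------------------------------

def compare_groups(x, y, alpha: float = 0.05) -> TestResult:
    """Between-group comparison with the normality gate (Welch vs MWU)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gate = normality_gate(x, y, alpha=alpha)
    if gate == PARAMETRIC:
        return welch_t(x, y)
    return mann_whitney(x, y)


def within_group_trend(matrix, alpha: float = 0.05) -> TestResult:
    """Within-group comparison across periods (RM-ANOVA vs Friedman).

    The gate applies Shapiro–Wilk to each period column; a fully constant
    matrix is reported degenerate with p = NaN.
    """
    m = _as_matrix(matrix)
    if np.ptp(m) == 0:
        return TestResult(
            method="degenerate",
            statistic=0.0,
            df=None,
            p=float("nan"),
            warnings=("all values identical",),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gate = normality_gate(*[m[:, j] for j in range(m.shape[1])], alpha=alpha)
    if gate == PARAMETRIC and m.shape[0] >= 3:
        return rm_anova(m)
    return friedman(m)


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

def relative_expression(
    records: pd.DataFrame, housekeeping: str = "GAPDH", method: str = "ratio"
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, TestResult]]:
    """Normalize expression by the housekeeping gene and compare groups.

    ``records`` is tidy with columns animal, group, gene, raw_level.
    ``method='ratio'`` divides each target gene's raw level by the animal's
    GAPDH level (the study's Table-3 convention, values near 1);
    ``method='log2'`` returns log2 of that ratio (a 2^-dCt style scale).
    Animals with a missing or non-positive housekeeping level are excluded
    with a warning.  Returns (normalized records, per-gene/group mean±SEM
    summary, per-gene Welch tests between the two groups).
    """
    if method not in ("ratio", "log2"):
        raise ValueError("method must be 'ratio' or 'log2'")
    df = records.copy()
    hk = df[df["gene"] == housekeeping].set_index("animal")["raw_level"]
    ok_animals = set(hk[hk > 0].index)
    dropped = sorted(set(df["animal"]) - ok_animals)
    if dropped:
        warnings.warn(
            f"excluding animals without positive {housekeeping}: {dropped}"
        )
    norm = df[(df["gene"] != housekeeping) & df["animal"].isin(ok_animals)].copy()
    norm["normalized"] = norm["raw_level"] / norm["animal"].map(hk)
    if method == "log2":
        norm["normalized"] = np.log2(norm["normalized"])

    rows = []
    tests: dict[str, TestResult] = {}
    for gene, sub in norm.groupby("gene", sort=False):
        by_group = {g: s["normalized"].to_numpy() for g, s in sub.groupby("group")}
        for g, vals in by_group.items():
            stats = _mean_sem(vals)
            rows.append({"gene": gene, "group": g, **stats})
        if len(by_group) == 2:
            (ga, va), (gb, vb) = sorted(by_group.items())
            # convention: AF (or first alphabetically) as x
            try:
                tests[gene] = welch_t(va, vb)
            except ValueError as exc:
                tests[gene] = TestResult(
                    method="degenerate",
                    statistic=0.0,
                    df=None,
                    p=float("nan"),
                    summaries={"x": _mean_sem(va), "y": _mean_sem(vb)},
                    warnings=(str(exc),),
                )
    summary = pd.DataFrame(rows)
    return norm, summary, tests
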