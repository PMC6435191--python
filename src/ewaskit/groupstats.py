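"""Group-comparison and association statistics.

Pure-function statistics used throughout the pipeline, including
summary-statistic forms (pooled and Welch t from printed means/SDs/ns) so
that published comparison tables can be reproduced without sample-level
data, a tie-corrected Mann-Whitney Z, Pearson chi-square for 2x2 tables,
tie-aware Spearman correlations with BH adjustment, partial correlation,
and Pillai's-trace MANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD (ddof=1) and sample size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    method: str
    flag: str | None = None


def pooled_t_from_summary(s1: GroupSummary, s2: GroupSummary) -> TestResult:
    """Independent-samples t with a pooled variance; df = n1 + n2 - 2."""
    df = s1.n + s2.n - 2
    sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
    se = np.sqrt(sp2 * (1 / s1.n + 1 / s2.n))
    t = (s1.mean - s2.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "pooled t")


def welch_t_from_summary(s1: GroupSummary, s2: GroupSummary) -> TestResult:
    """Welch's unequal-variance t with Welch-Satterthwaite df."""
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    t = (s1.mean - s2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "Welch t")


def mann_whitney_z(x, y) -> TestResult:
    """Mann-Whitney U with the tie-corrected normal approximation.

    ``U`` counts (x > y) pairs (ties count one half), so Z shares its sign
    with ``mean(x) - mean(y)`` for location-shifted samples.  No continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2  # number of (x > y) pairs, ties as 1/2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult(0.0, np.nan, 1.0, "Mann-Whitney Z", flag="all values tied")
    z = (u1 - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return TestResult(float(z), np.nan, float(p), "Mann-Whitney Z")


def mann_whitney_u(x, y) -> float:
    """The U statistic itself (counting (x > y) pairs, ties as 1/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def chi_square_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 count table, df = 1.

    No continuity correction by default; set ``yates=True`` for the
    Yates-corrected variant.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    stat, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return TestResult(float(stat), float(df), float(p), "Pearson chi-square")


def spearman_with_bh(z_matrix: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Tie-aware Spearman correlation of every (probe, domain) pair with BH.

    ``z_matrix`` is probes x samples; ``scores`` is samples x domains.
    Samples missing a domain score are dropped pairwise.  Returns a table
    with rho, nominal p, BH-adjusted p (across all pairs) and hit flags;
    constant inputs yield NaN rho with a flag.
    """
    common = z_matrix.columns.intersection(scores.index)
    if len(common) < 4:
        raise ValueError("need at least 4 aligned samples")
    rows = []
    for domain in scores.columns:
        s = scores.loc[common, domain].dropna()
        if len(s) < 4:
            raise ValueError(f"need at least 4 observations for {domain}")
        sub = z_matrix.loc[:, s.index].to_numpy(dtype=float)
        for probe, vals in zip(z_matrix.index, sub):
            if np.std(vals) == 0 or np.std(s.to_numpy()) == 0:
                rows.append((probe, domain, np.nan, np.nan, "constant input"))
                continue
            rho, p = sps.spearmanr(vals, s.to_numpy())
            rows.append((probe, domain, rho, p, None))
    out = pd.DataFrame(rows, columns=["probe_id", "domain", "rho", "p", "flag"])
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["p_adj"] = adj
    out["nominal_hit"] = out["p"] < 0.05
    out["adjusted_hit"] = out["p_adj"] < 0.05
    return out


def partial_correlation(x, y, covariates=None) -> TestResult:
    """Pearson correlation of x and y after removing covariates by OLS.

    With no covariates this is the plain Pearson correlation.  The p-value
    uses a t reference with n - 2 - k degrees of freedom, where k is the
    number of covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    H, *_ = np.linalg.lstsq(X, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - X @ H
    rx, ry = resid[:, 0], resid[:, 1]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return TestResult(np.nan, np.nan, np.nan, "partial r", flag="constant residual")
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(r, float(df), float(p), "partial r")


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((y - X @ coef) ** 2).sum())


def manova_pillai(response_matrix, design, term: str | None = None) -> TestResult:
    """Pillai's trace MANOVA for one design term.

    ``response_matrix`` is samples x responses; ``design`` is a DataFrame of
    predictors (an intercept is added).  ``term`` names the tested column
    (default: the last one).  Returns the Pillai-trace F approximation.
    """
    Y = np.asarray(response_matrix, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = pd.DataFrame(design).copy()
    if term is None:
        term = X.columns[-1]
    exog = pd.concat(
        [pd.Series(1.0, index=X.index, name="intercept"), X.astype(float)], axis=1
    )
    n, p = Y.shape
    if n - exog.shape[1] < p:
        raise ValueError("more responses than residual degrees of freedom")
    names = list(exog.columns)
    if p == 1:
        # Pillai's trace with a single response reduces exactly to the
        # univariate partial F for the term
        X = exog.to_numpy(dtype=float)
        y = Y[:, 0]
        rss_full = _rss(X, y)
        X_red = np.delete(X, names.index(term), axis=1)
        rss_red = _rss(X_red, y)
        df_den = n - X.shape[1]
        F = (rss_red - rss_full) / (rss_full / df_den)
        pval = sps.f.sf(F, 1, df_den)
        return TestResult(float(F), 1.0, float(pval), "Pillai's trace F")
    mv = MANOVA(endog=Y, exog=exog.to_numpy())
    contrast = np.zeros((1, len(names)))
    contrast[0, names.index(term)] = 1.0
    res = mv.mv_test(hypotheses=[(str(term), contrast, None)])
    tbl = res.results[str(term)]["stat"]
    row = tbl.loc["Pillai's trace"]
    return TestResult(
        float(row["F Value"]),
        float(row["Num DF"]),
        float(row["Pr > F"]),
        "Pillai's trace F",
    )
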