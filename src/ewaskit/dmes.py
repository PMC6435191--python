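"""Differentially methylated CpG site (DMES) calling.

The caller follows the classic microarray cascade: a two-group moderated
t-test with empirical-Bayes variance shrinkage (the per-probe variance is
squeezed toward a prior estimated by a method-of-moments fit of a scaled
F distribution to the sample variances), Benjamini-Hochberg adjustment, a
signed beta-value fold-change gate, and finally a conservative elimination
of candidates whose methylation associates with blood cell composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from ewaskit.simulate import CELL_TYPES


@dataclass(frozen=True)
class EbayesPrior:
    """Prior degrees of freedom and variance of the variance shrinkage."""

    d0: float  # may be inf
    s0_sq: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_ebayes_prior(sample_variances, residual_df: float) -> EbayesPrior:
    """Method-of-moments fit of ``s^2 ~ s0^2 F(df, d0)`` to sample variances.

    Matches the mean and variance of ``log s^2`` to the scaled-F model via
    digamma/trigamma inversion.  When the spread of log variances does not
    exceed what the chi-square sampling noise alone explains, the prior
    degrees of freedom are infinite (no excess dispersion) and ``s0^2`` is
    the corresponding bias-corrected geometric mean.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if np.any(s2 <= 0):
        warnings.warn("nonpositive sample variances floored at 1e-12", stacklevel=2)
        s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    df2 = residual_df / 2.0
    e = z - digamma(df2) + np.log(df2)
    evar = z.var(ddof=1) - _trigamma(df2)
    if evar <= 0:
        return EbayesPrior(d0=np.inf, s0_sq=float(np.exp(e.mean())))
    d0_half = _trigamma_inverse(evar)
    d0 = 2.0 * d0_half
    s0_sq = float(np.exp(e.mean() + digamma(d0_half) - np.log(d0_half)))
    return EbayesPrior(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    beta: pd.DataFrame, groups: pd.Series, prior: EbayesPrior | None = None
):
    """Per-probe moderated t between two groups.

    The posterior variance is ``(d0 s0^2 + df s^2) / (d0 + df)``; the
    statistic is referred to a t distribution with ``d0 + df`` degrees of
    freedom (a large-df t when ``d0`` is infinite).  Returns a DataFrame with
    group means, delta, t, p, the pooled per-probe variance and the prior.
    """
    groups = pd.Series(groups).loc[beta.columns]
    labels = sorted(groups.unique(), key=lambda g: (g != "IC", g))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = labels
    X1 = beta.loc[:, groups == g1].to_numpy(dtype=float)
    X2 = beta.loc[:, groups == g2].to_numpy(dtype=float)
    n1, n2 = X1.shape[1], X2.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (X1.var(axis=1, ddof=1) * (n1 - 1) + X2.var(axis=1, ddof=1) * (n2 - 1)) / df
    if prior is None:
        prior = estimate_ebayes_prior(s2, df)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = 1e9  # normal limit of the t reference
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            f"mean_{g1.lower()}": m1,
            f"mean_{g2.lower()}": m2,
            "delta": m1 - m2,
            "s2": s2,
            "t_mod": t,
            "p": p,
        },
        index=beta.index,
    )
    out.attrs["prior"] = prior
    out.attrs["df_residual"] = df
    out.attrs["groups"] = (g1, g2)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def beta_fold_change(mean_ic, mean_bfc):
    """Signed fold change of group mean betas; |fc| >= 1 always.

    Positive when the first (exposed) group is more methylated:
    ``fc = m1/m2`` if ``m1 >= m2`` else ``-m2/m1``.  Zero means are floored
    at 1e-6 with a warning.
    """
    m1 = np.asarray(mean_ic, dtype=float)
    m2 = np.asarray(mean_bfc, dtype=float)
    if np.any(m1 <= 0) or np.any(m2 <= 0):
        warnings.warn("nonpositive group means floored at 1e-6", stacklevel=2)
        m1, m2 = np.maximum(m1, 1e-6), np.maximum(m2, 1e-6)
    return np.where(m1 >= m2, m1 / m2, -m2 / m1)


def cell_association_filter(
    beta_at_candidates: pd.DataFrame,
    fractions: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Index:
    """Candidates whose methylation associates with cell composition.

    Per candidate probe, OLS of beta on five cell-fraction predictors (the
    granulocyte fraction is dropped to break the simplex collinearity) plus
    an intercept; the probe is flagged for removal when the overall
    regression F-test has p < ``alpha``.  Constant-beta probes are skipped.
    """
    samples = beta_at_candidates.columns
    X = fractions.loc[samples, [c for c in CELL_TYPES if c != "Gran"]].to_numpy()
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("too few samples for the cell-association regression")
    D = np.column_stack([np.ones(n), X])
    Y = beta_at_candidates.to_numpy(dtype=float).T  # samples x probes
    Yc = Y - Y.mean(axis=0)
    tss = (Yc**2).sum(axis=0)
    H, *_ = np.linalg.lstsq(D, Y, rcond=None)
    rss = ((Y - D @ H) ** 2).sum(axis=0)
    df_num, df_den = k, n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / df_num) / (rss / df_den)
    pvals = sps.f.sf(F, df_num, df_den)
    keepable = tss > 0  # constant response: flagged, skipped
    removed = (pvals < alpha) & keepable
    return beta_at_candidates.index[removed]


def call_dmes(
    beta: pd.DataFrame,
    groups: pd.Series,
    fractions: pd.DataFrame | None = None,
    padj_threshold: float = 0.05,
    fc_threshold: float = 1.2,
    cell_alpha: float = 0.05,
    prior: EbayesPrior | None = None,
):
    """Full DMES cascade: moderated t -> BH -> fold-change gate -> cell filter.

    Returns ``(table, cascade)`` where ``table`` has one row per probe with
    test results, fold change, direction and filter flags, and ``cascade``
    logs the count surviving each stage.
    """
    table = moderated_t_test(beta, groups, prior)
    g1, g2 = table.attrs["groups"]
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["fc"] = beta_fold_change(
        table[f"mean_{g1.lower()}"].to_numpy(), table[f"mean_{g2.lower()}"].to_numpy()
    )
    table["direction"] = np.where(table["delta"] > 0, "hyper", "hypo")
    table["passed_padj"] = table["p_adj"] < padj_threshold
    table["passed_fc"] = np.abs(table["fc"]) >= fc_threshold
    candidates = table.index[table["passed_padj"] & table["passed_fc"]]
    removed = pd.Index([])
    if len(candidates) and fractions is not None:
        removed = cell_association_filter(beta.loc[candidates], fractions, cell_alpha)
    table["removed_by_cell_filter"] = table.index.isin(removed)
    table["is_dmes"] = (
        table["passed_padj"] & table["passed_fc"] & ~table["removed_by_cell_filter"]
    )
    dmes = table[table["is_dmes"]]
    cascade = {
        "n_tested": int(len(table)),
        "n_significant": int(table["passed_padj"].sum()),
        "n_significant_and_fc": int(len(candidates)),
        "n_removed_by_cell_filter": int(len(removed)),
        "n_dmes": int(table["is_dmes"].sum()),
        "n_hyper": int((dmes["direction"] == "hyper").sum()),
        "n_hypo": int((dmes["direction"] == "hypo").sum()),
    }
    table.attrs["cascade"] = cascade
    return table, cascade


def candidate_region_scan(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    region: tuple,
    flank: int = 0,
):
    """Nominal-significance scan of probes inside a genomic region.

    ``region`` is ``(chromosome, start, end)``, 1-based inclusive, optionally
    widened by ``flank`` bases on each side.  Returns ``(table, count)``
    where ``table`` lists per-probe unadjusted group-difference p and
    direction and ``count`` is the number with p < 0.05.
    """
    chrom, start, end = region
    ann = annotation.loc[annotation.index.intersection(results.index)]
    mask = (
        (ann["chromosome"] == chrom)
        & (ann["position"] >= start - flank)
        & (ann["position"] <= end + flank)
    )
    hits = ann.index[mask]
    cols = ["delta", "t_mod", "p"]
    if "direction" in results.columns:
        cols.append("direction")
    table = results.loc[hits, cols].copy()
    if "direction" not in table.columns:
        table["direction"] = np.where(table["delta"] > 0, "hyper", "hypo")
    table["nominal_significant"] = table["p"] < 0.05
    return table, int(table["nominal_significant"].sum())
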