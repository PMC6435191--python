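"""Reference-based leukocyte deconvolution by constrained projection.

Each whole-blood methylation profile is modeled as a nonnegative mixture of
six leukocyte reference profiles (CD4+ T, CD8+ T, B, NK, monocyte,
granulocyte).  Fractions are recovered per sample by nonnegative least
squares on a set of cell-type discriminating probes, with a penalty row
driving the fractions toward the simplex, followed by renormalization — the
constrained-projection convention of reference-based blood deconvolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ewaskit import groupstats
from ewaskit.simulate import CELL_TYPES, ReferenceMethylome

#: CD4/CD8 ratios are undefined below this CD8 fraction.
MIN_CD8_FOR_RATIO = 0.005


def select_discriminating_probes(
    reference: ReferenceMethylome, k_per_type: int
) -> pd.Index:
    """For each cell type, the k probes maximizing |value - mean(others)|.

    The union over types is deduplicated; selection is deterministic.
    """
    if k_per_type < 1:
        raise ValueError("k_per_type must be >= 1")
    R = reference.matrix
    n, t = R.shape
    if k_per_type > n:
        raise ValueError("k_per_type exceeds the number of reference probes")
    chosen: list[str] = []
    for col in range(t):
        others = np.delete(R, col, axis=1).mean(axis=1)
        score = np.abs(R[:, col] - others)
        top = np.argsort(-score, kind="stable")[:k_per_type]
        chosen.extend(reference.probe_ids[np.sort(top)])
    return pd.Index(dict.fromkeys(chosen))  # order-preserving dedup


def estimate_cell_fractions(
    beta: pd.DataFrame,
    reference: ReferenceMethylome,
    probe_set=None,
    sum_penalty: float = 1000.0,
) -> pd.DataFrame:
    """Estimate six leukocyte fractions per sample.

    Solves, per sample, ``min ||m - R w||^2`` over ``w >= 0`` with a penalty
    row pulling ``sum(w)`` to 1, then renormalizes exactly.  Returns a
    DataFrame (samples x cell types) plus a ``cd4_cd8_ratio`` column
    (NaN when the CD8 fraction is below ``MIN_CD8_FOR_RATIO``).
    """
    ref = reference.to_frame()
    if probe_set is None:
        probe_set = ref.index.intersection(beta.index)
    probe_set = pd.Index(probe_set)
    if probe_set.difference(beta.index).size or probe_set.difference(ref.index).size:
        raise ValueError("probe_set must be present in both beta and reference")
    R = ref.loc[probe_set].to_numpy()
    if np.linalg.matrix_rank(R) < 6:
        raise ValueError(
            "reference is rank-deficient on the selected probes; "
            "increase k_per_type for probe selection"
        )
    lam = np.sqrt(sum_penalty)
    A = np.vstack([R, lam * np.ones((1, 6))])
    M = beta.loc[probe_set].to_numpy()
    W = np.empty((beta.shape[1], 6))
    for i in range(beta.shape[1]):
        b = np.concatenate([M[:, i], [lam]])
        W[i], _ = nnls(A, b)
    sums = W.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("degenerate sample with all-zero fraction estimate")
    W = W / sums[:, None]
    out = pd.DataFrame(W, index=beta.columns, columns=list(CELL_TYPES))
    cd8 = out["CD8T"].to_numpy()
    out["cd4_cd8_ratio"] = np.where(
        cd8 >= MIN_CD8_FOR_RATIO, out["CD4T"].to_numpy() / np.where(cd8 > 0, cd8, np.nan), np.nan
    )
    return out


def compare_cell_composition(
    fractions: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Two-group comparison per cell type and for the CD4/CD8 ratio.

    Reports group means and SDs, pooled and Welch t (with p), and the
    tie-corrected Mann-Whitney Z.  Group labels come from
    ``samples['group']``; the first group named 'IC' (or the first label in
    sorted order otherwise) is compared against the other.
    """
    groups = samples.loc[fractions.index, "group"]
    labels = sorted(groups.unique(), key=lambda g: (g != "IC", g))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = labels
    rows = []
    for col in list(CELL_TYPES) + ["cd4_cd8_ratio"]:
        x = fractions.loc[groups == g1, col].dropna().to_numpy()
        y = fractions.loc[groups == g2, col].dropna().to_numpy()
        if min(len(x), len(y)) < 2:
            raise ValueError(f"group with fewer than 2 samples for {col}")
        s1 = groupstats.GroupSummary(x.mean(), x.std(ddof=1), len(x))
        s2 = groupstats.GroupSummary(y.mean(), y.std(ddof=1), len(y))
        pooled = groupstats.pooled_t_from_summary(s1, s2)
        welch = groupstats.welch_t_from_summary(s1, s2)
        mw = groupstats.mann_whitney_z(x, y)
        rows.append(
            {
                "measure": col,
                f"mean_{g1.lower()}": s1.mean,
                f"sd_{g1.lower()}": s1.sd,
                f"mean_{g2.lower()}": s2.mean,
                f"sd_{g2.lower()}": s2.sd,
                "t_pooled": pooled.statistic,
                "p_pooled": pooled.p_two_sided,
                "t_welch": welch.statistic,
                "df_welch": welch.df,
                "p_welch": welch.p_two_sided,
                "mw_z": mw.statistic,
                "p_mw": mw.p_two_sided,
            }
        )
    return pd.DataFrame(rows).set_index("measure")
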