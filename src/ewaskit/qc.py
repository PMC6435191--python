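"""Probe-level QC filtering and stratified quantile normalization.

The filtering cascade mirrors standard methylation-array preprocessing:
probes with failed detection p-values or missing betas are removed first,
then probes on the sex chromosomes, then probes overlapping common SNPs
(minor allele frequency at or above a threshold).  Between-sample
normalization is quantile normalization applied within probe strata.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500", "5'UTR", "1stExon"})


@dataclass(frozen=True)
class FilterReport:
    """Per-class removal counts of the probe filtering cascade.

    A probe is counted once, in the first filter class it hits (detection /
    missing, then sex chromosome, then SNP overlap).
    """

    n_input: int
    n_removed_detection: int
    n_removed_missing: int
    n_removed_sex: int
    n_removed_snp: int
    n_retained: int

    def __post_init__(self):
        removed = (
            self.n_removed_detection
            + self.n_removed_missing
            + self.n_removed_sex
            + self.n_removed_snp
        )
        if self.n_retained != self.n_input - removed:
            raise ValueError("FilterReport counts do not conserve probes")
        if min(asdict(self).values()) < 0:
            raise ValueError("FilterReport counts must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def apply_detection_filter(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    threshold: float = 0.05,
    max_fail_fraction: float = 0.0,
):
    """Remove probes with failed detection or missing beta values.

    A probe fails if the fraction of samples with detection p > ``threshold``
    exceeds ``max_fail_fraction`` (the default 0.0 removes a probe on any
    failing sample — the strictest reading), or if any beta value is missing.

    Returns ``(filtered_beta, removed_detection_ids, removed_missing_ids)``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if beta.shape != detp.shape or not beta.index.equals(detp.index):
        raise ValueError("beta and detection-p matrices must share shape and index")
    fail_frac = (detp.to_numpy() > threshold).mean(axis=1)
    bad_det = fail_frac > max_fail_fraction
    bad_missing = beta.isna().any(axis=1).to_numpy() & ~bad_det
    keep = ~(bad_det | bad_missing)
    return (
        beta.loc[keep],
        beta.index[bad_det],
        beta.index[bad_missing],
    )


def drop_sex_and_snp_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    maf_threshold: float = 0.05,
):
    """Remove sex-chromosome probes and probes with common SNPs (MAF >= threshold).

    Returns ``(filtered_beta, removed_sex_ids, removed_snp_ids)``.  Every
    probe in ``beta`` must be annotated.
    """
    missing = beta.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"unannotated probes: {list(missing[:10])}")
    ann = annotation.loc[beta.index]
    on_sex = ann["chromosome"].isin(("chrX", "chrY")).to_numpy()
    maf = ann["snp_maf"].to_numpy(dtype=float)
    common_snp = (~np.isnan(maf)) & (maf >= maf_threshold) & ~on_sex
    keep = ~(on_sex | common_snp)
    return beta.loc[keep], beta.index[on_sex], beta.index[common_snp]


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_threshold: float = 0.05,
    maf_threshold: float = 0.05,
    max_fail_fraction: float = 0.0,
):
    """Full filtering cascade; returns ``(filtered_beta, FilterReport)``."""
    n_input = beta.shape[0]
    beta1, det_ids, miss_ids = apply_detection_filter(
        beta, detp, detection_threshold, max_fail_fraction
    )
    beta2, sex_ids, snp_ids = drop_sex_and_snp_probes(beta1, annotation, maf_threshold)
    report = FilterReport(
        n_input=n_input,
        n_removed_detection=len(det_ids),
        n_removed_missing=len(miss_ids),
        n_removed_sex=len(sex_ids),
        n_removed_snp=len(snp_ids),
        n_retained=beta2.shape[0],
    )
    return beta2, report


def promoter_strata(annotation: pd.DataFrame, probe_ids) -> pd.Series:
    """Default two-stratum assignment: promoter-like genic regions vs. other."""
    region = annotation.loc[probe_ids, "genic_region"]
    return pd.Series(
        np.where(region.isin(PROMOTER_REGIONS), "promoter", "other"),
        index=probe_ids,
        name="stratum",
    )


def quantile_normalize(beta: pd.DataFrame, strata_labels: pd.Series | None = None) -> pd.DataFrame:
    """Stratified between-sample quantile normalization.

    Within each stratum every sample's sorted values are replaced by the
    stratum-wide mean quantile vector; ties receive the mean of the target
    quantiles they span.  Probe order is preserved.  With ``strata_labels``
    omitted, a single stratum is used.
    """
    if beta.isna().any().any():
        raise ValueError("quantile normalization requires complete data")
    if strata_labels is None:
        strata_labels = pd.Series("all", index=beta.index)
    strata_labels = strata_labels.loc[beta.index]
    out = beta.copy()
    for stratum, idx in beta.index.groupby(strata_labels).items():
        sub = beta.loc[idx].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            warnings.warn(
                f"stratum {stratum!r} has fewer than 2 probes; passed through unchanged",
                stacklevel=2,
            )
            continue
        out.loc[idx] = _quantile_normalize_array(sub)
    return out


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``x`` to their mean quantile vector."""
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    target = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks = np.empty(len(col), dtype=int)
        ranks[order[:, j]] = np.arange(len(col))
        vals = target[ranks]
        # average targets across tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=vals)
            counts = np.bincount(inv)
            vals = (sums / counts)[inv]
        out[:, j] = vals
    return out
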