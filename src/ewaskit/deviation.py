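"""Deviation-from-normative-profile analysis.

Each exposed-group (IC) child's multivariate profile — four behavior-domain
Z-scores (D_VABS) or the methylation z-values of the called DMESs (D_EPI) —
is summarized by its Euclidean distance from the comparison group's mean
("normative") profile.  Distances are rescaled into [0, 1] for presentation;
every reported correlation and R-squared is exactly invariant to any
positive rescaling, so the scaling rule cannot affect the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ewaskit.groupstats import TestResult, partial_correlation


@dataclass
class DeviationResult:
    """Per-sample deviations and their cohort-level association statistics."""

    per_sample: pd.DataFrame  # columns: duration, d_epi, d_vabs
    r_depi_duration: TestResult
    r_dvabs_duration: TestResult
    full: dict = field(default_factory=dict)  # r, p, r_squared, n
    subcohort: dict | None = None


def normative_profile(bfc_matrix) -> np.ndarray:
    """Arithmetic mean profile of the comparison group (samples x dims)."""
    M = np.asarray(bfc_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 comparison-group profiles")
    if np.any(np.isnan(M)):
        raise ValueError("normative profile requires complete data")
    return M.mean(axis=0)


def deviation_scores(ic_matrix, normative, scaling: str = "cohort-max") -> np.ndarray:
    """Euclidean distance of each profile from the normative vector, in [0, 1].

    ``scaling='cohort-max'`` (default) divides by the maximum distance over
    the cohort; ``'theoretical-max'`` divides by ``sqrt(p)`` (the largest
    possible distance when every dimension deviates by 1, suited to
    unit-bounded data); ``'none'`` returns raw distances.  A profile equal
    to the normative vector scores 0 under any rule.
    """
    X = np.asarray(ic_matrix, dtype=float)
    nv = np.asarray(normative, dtype=float)
    if X.ndim != 2 or X.shape[1] != nv.size:
        raise ValueError("profile and normative dimensions do not match")
    d = np.sqrt(((X - nv) ** 2).sum(axis=1))
    if scaling == "none":
        return d
    if scaling == "cohort-max":
        m = d.max()
        if m == 0:
            return d  # all profiles identical to normative: all zeros
        return d / m
    if scaling == "theoretical-max":
        return d / np.sqrt(nv.size)
    raise ValueError(f"unknown scaling rule {scaling!r}")


def deviation_associations(
    d_epi,
    d_vabs,
    durations,
    subcohort_mask=None,
) -> DeviationResult:
    """Correlate the two deviation indices with exposure duration and each other.

    Pearson r (with two-sided p) of each distance against duration, plus the
    r and R-squared between the epigenetic and behavioral deviations, for
    the full cohort and, when ``subcohort_mask`` is given, for that
    subcohort (e.g. children institutionalized at birth).
    """
    d_epi = np.asarray(d_epi, dtype=float)
    d_vabs = np.asarray(d_vabs, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if not (len(d_epi) == len(d_vabs) == len(durations)):
        raise ValueError("aligned vectors required")
    if len(d_epi) < 4:
        raise ValueError("need at least 4 samples")
    per_sample = pd.DataFrame(
        {"duration": durations, "d_epi": d_epi, "d_vabs": d_vabs}
    )
    r_ed = partial_correlation(d_epi, durations)
    r_vd = partial_correlation(d_vabs, durations)

    def _pair(mask):
        e, v = d_epi[mask], d_vabs[mask]
        res = partial_correlation(e, v)
        return {
            "r": res.statistic,
            "p": res.p_two_sided,
            "r_squared": res.statistic**2 if np.isfinite(res.statistic) else np.nan,
            "n": int(mask.sum()),
        }

    full_mask = np.ones(len(d_epi), dtype=bool)
    sub = None
    if subcohort_mask is not None:
        subcohort_mask = np.asarray(subcohort_mask, dtype=bool)
        if subcohort_mask.sum() >= 4:
            sub = _pair(subcohort_mask)
    return DeviationResult(
        per_sample=per_sample,
        r_depi_duration=r_ed,
        r_dvabs_duration=r_vd,
        full=_pair(full_mask),
        subcohort=sub,
    )
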