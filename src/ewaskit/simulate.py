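"""Seeded synthetic methylation cohorts with known ground truth.

The simulator emulates a two-group whole-blood methylation study of young
children: an institutional-care group (IC) and a biological-family-care group
(BFC), 29 children each.  Per-sample beta-values arise from a cell-type
mixture model

    beta[p, i] = sum_t R[p, t] * w[i, t]  (+ planted and demographic effects),

where ``R`` is a reference methylome over six leukocyte types and ``w`` are
per-sample cell fractions drawn from group-specific Dirichlet distributions.
Group-differential CpGs are planted on the beta scale, demographic (age,
gender) effects enter a small random probe subset, measurement noise is
Gaussian on the logit scale, and four adaptive-behavior domain scores are
coupled to the planted CpGs so the downstream association and deviation
analyses have recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

CELL_TYPES = ("CD4T", "CD8T", "Bcell", "NK", "Mono", "Gran")

VABS_DOMAINS = (
    "Communication",
    "Daily Living Skills",
    "Socialization",
    "Motor Skills",
)

def _simplex(values):
    total = sum(values)
    return tuple(v / total for v in values)


#: Group mean leukocyte fractions used as Dirichlet means (study-design
#: values for the IC and BFC groups, normalized onto the simplex).
IC_CELL_MEANS = _simplex((0.242, 0.128, 0.143, 0.037, 0.058, 0.397))
BFC_CELL_MEANS = _simplex((0.283, 0.127, 0.187, 0.039, 0.050, 0.318))

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_GENIC_REGIONS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
_CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")


@dataclass(frozen=True)
class ReferenceMethylome:
    """Cell-type reference: probes x six leukocyte types, betas in [0, 1]."""

    probe_ids: np.ndarray
    matrix: np.ndarray
    cell_type_names: tuple = CELL_TYPES

    def __post_init__(self):
        if self.matrix.shape != (len(self.probe_ids), len(self.cell_type_names)):
            raise ValueError("reference matrix shape inconsistent with probe ids")
        if len(self.cell_type_names) != 6:
            raise ValueError("reference must cover exactly six cell types")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("reference entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.probe_ids, columns=list(self.cell_type_names)
        )


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    Defaults reproduce the emulated study design: 29 + 29 samples, six-type
    leukocyte mixtures with the groups' mean fractions differing as printed
    for the real cohort, planted group-differential CpGs at low-methylated
    probes, demographic effects on a random 5% probe subset, and behavior
    scores coupled to the planted CpGs.
    """

    n_ic: int = 29
    n_bfc: int = 29
    n_probes: int = 5000
    n_planted_dmes: int = 60
    effect_delta: float = 0.08
    dirichlet_means_ic: tuple = IC_CELL_MEANS
    dirichlet_means_bfc: tuple = BFC_CELL_MEANS
    # Dirichlet concentration ~30 reproduces the order of the per-type SDs
    # printed for the real cohort (e.g. granulocyte SD ~ 0.08-0.105).
    concentration: float = 30.0
    # Logit-scale measurement/biological noise; 0.35 induces a beta-scale SD
    # of ~0.05 at mid-low methylation levels, typical between-subject spread.
    noise_sd: float = 0.35
    demo_effect_size: float = 1.0
    frac_demo_probes: float = 0.05
    vabs_coupling: float = 3.0
    vabs_noise_sd: float = 6.0
    duration_coupling: float = 0.5
    # Planted effects emulate condition-driven, cell-intrinsic differential
    # methylation: the per-sample effect pattern is orthogonalized against
    # the realized cell-fraction matrix, so the planted ground truth is
    # composition-independent by construction (the property the
    # cell-composition elimination filter screens for).
    composition_orthogonal: bool = True
    # Fraction of (probe, sample) cells with a failed detection p-value;
    # under the any-sample removal rule this removes ~1% of probes at n=58.
    detp_fail_rate: float = 2e-4
    frac_sex_probes: float = 0.03
    frac_snp_probes: float = 0.015
    n_vabs_missing_bfc: int = 4
    p_placed_at_birth: float = 15.0 / 29.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ic, self.n_bfc, self.n_probes) <= 0:
            raise ValueError("sample and probe counts must be positive")
        if self.n_planted_dmes < 0:
            raise ValueError("n_planted_dmes must be >= 0")
        if not 0 < self.effect_delta < 0.5:
            raise ValueError("effect_delta must lie in (0, 0.5)")
        for means in (self.dirichlet_means_ic, self.dirichlet_means_bfc):
            _check_simplex(np.asarray(means, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    beta: pd.DataFrame
    detp: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    vabs_raw: pd.DataFrame
    truth: dict


def _check_simplex(means: np.ndarray) -> None:
    if means.ndim != 1 or means.size != 6:
        raise ValueError("Dirichlet means must be a 6-vector")
    if np.any(means < 0) or abs(means.sum() - 1.0) > 1e-8:
        raise ValueError("Dirichlet means must be nonnegative and sum to 1")


def generate_reference_methylome(
    n_probes: int, k_discriminating_per_type: int, seed: int
) -> ReferenceMethylome:
    """Build a six-cell-type reference with planted discriminating blocks.

    The first ``6 * k`` probes form per-type discriminating blocks: for block
    ``t`` the probe is near-fully methylated (or unmethylated, alternating) in
    cell type ``t`` and at the opposite extreme in the other five types, so
    |entry - mean(others)| >= 0.3 holds by construction.  Remaining probes
    share a bimodal baseline across cell types with small jitter.
    """
    k = int(k_discriminating_per_type)
    if k < 1:
        raise ValueError("k_discriminating_per_type must be >= 1")
    if n_probes < 6 * k:
        raise ValueError(
            f"n_probes={n_probes} too small for 6 blocks of {k} discriminating probes"
        )
    rng = np.random.default_rng(seed)
    # bimodal baseline: mostly low or high, some intermediate
    comp = rng.choice(3, size=n_probes, p=(0.45, 0.35, 0.20))
    base = np.where(
        comp == 0,
        rng.beta(2.0, 8.0, size=n_probes),
        np.where(comp == 1, rng.beta(8.0, 2.0, size=n_probes), rng.beta(2.0, 2.0, size=n_probes)),
    )
    matrix = np.clip(base[:, None] + rng.normal(0.0, 0.02, size=(n_probes, 6)), 0.01, 0.99)
    for t in range(6):
        rows = slice(t * k, (t + 1) * k)
        high = np.arange(t * k, (t + 1) * k) % 2 == 0
        target = np.where(high, 0.90, 0.10) + rng.uniform(-0.03, 0.03, size=k)
        others = np.where(high, 0.10, 0.90)[:, None] + rng.uniform(
            -0.03, 0.03, size=(k, 5)
        )
        block = np.empty((k, 6))
        other_cols = [c for c in range(6) if c != t]
        block[:, t] = target
        block[:, other_cols] = others
        matrix[rows] = np.clip(block, 0.01, 0.99)
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    return ReferenceMethylome(probe_ids=probe_ids, matrix=matrix)


def discriminating_block_ids(reference: ReferenceMethylome, k_per_type: int) -> np.ndarray:
    """Probe ids of the planted discriminating blocks of a generated reference."""
    return reference.probe_ids[: 6 * k_per_type]


def sample_cell_fractions(
    n: int,
    dirichlet_means,
    concentration: float,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` leukocyte fraction vectors from a Dirichlet distribution.

    ``dirichlet_means`` is the mean simplex vector; ``concentration`` scales
    the Dirichlet precision (variance of type t is m_t(1-m_t)/(c+1)).  Types
    with mean exactly 0 receive fraction 0 in every draw.  Rows are
    renormalized to sum to 1 exactly.
    """
    means = np.asarray(dirichlet_means, dtype=float)
    _check_simplex(means)
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    out = np.zeros((n, 6))
    pos = means > 0
    if pos.sum() == 1:
        out[:, pos] = 1.0
    else:
        out[:, pos] = rng.dirichlet(means[pos] * concentration, size=n)
    out /= out.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, columns=list(CELL_TYPES))


def _sample_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_ic + design.n_bfc
    ids = [f"IC{i + 1:03d}" for i in range(design.n_ic)] + [
        f"BFC{i + 1:03d}" for i in range(design.n_bfc)
    ]
    group = ["IC"] * design.n_ic + ["BFC"] * design.n_bfc
    p_female = np.where(np.array(group) == "IC", 9.0 / 29.0, 11.0 / 29.0)
    gender = (rng.uniform(size=n) < p_female).astype(int)  # 1 = female
    age = np.clip(rng.normal(20.4, 6.9, size=n), 8.0, 35.0).round(1)
    gap = np.clip(rng.normal(1.3, 2.4, size=n), 0.0, 8.0).round(1)
    age_vabs = age + gap
    placement = np.full(n, np.nan)
    ic = np.arange(design.n_ic)
    at_birth = rng.uniform(size=design.n_ic) < design.p_placed_at_birth
    placement[ic] = np.where(
        at_birth,
        rng.uniform(0.0, 1.0, size=design.n_ic),
        rng.uniform(1.0, np.maximum(0.8 * age[ic], 1.5), size=design.n_ic),
    ).round(1)
    duration = np.full(n, np.nan)
    duration[ic] = np.maximum(age[ic] - placement[ic], 0.5).round(1)
    return pd.DataFrame(
        {
            "group": group,
            "gender": gender,
            "age_months": age,
            "age_vabs_months": age_vabs,
            "age_at_placement_months": placement,
            "duration_months": duration,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def _annotation(
    design: CohortDesign,
    probe_ids: np.ndarray,
    protected: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random probe annotation; ``protected`` probes stay autosomal/SNP-free."""
    n = len(probe_ids)
    chrom = rng.choice(_AUTOSOMES, size=n)
    maf = np.full(n, np.nan)
    eligible = ~protected
    idx = np.flatnonzero(eligible)
    n_sex = int(round(design.frac_sex_probes * n))
    n_snp = int(round(design.frac_snp_probes * n))
    pick = rng.choice(idx, size=min(n_sex + n_snp, idx.size), replace=False)
    sex_pick, snp_pick = pick[:n_sex], pick[n_sex:]
    chrom[sex_pick] = rng.choice(["chrX", "chrY"], size=sex_pick.size, p=[0.8, 0.2])
    maf[snp_pick] = rng.uniform(0.05, 0.5, size=snp_pick.size)
    # some probes carry benign, sub-threshold polymorphisms
    low = rng.choice(idx, size=min(int(0.05 * n), idx.size), replace=False)
    low = np.setdiff1d(low, snp_pick, assume_unique=False)
    maf[low] = rng.uniform(0.0, 0.049, size=low.size)
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": rng.integers(1, 2_000_000_00, size=n),
            "snp_maf": maf,
            "genic_region": rng.choice(
                _GENIC_REGIONS, size=n, p=(0.15, 0.15, 0.10, 0.05, 0.40, 0.15)
            ),
            "cgi_relation": rng.choice(
                _CGI_RELATIONS, size=n, p=(0.30, 0.10, 0.10, 0.05, 0.05, 0.40)
            ),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def generate_cohort(
    design: CohortDesign, reference: ReferenceMethylome
) -> SyntheticCohort:
    """Generate a full synthetic cohort from a design and a reference.

    Steps (all randomness flows from ``design.seed`` through one generator):

    1. per-sample cell fractions from group-specific Dirichlets;
    2. clean betas from the mixture ``R @ w``;
    3. planted group-differential effects at low-methylated non-discriminating
       probes (half hyper-, half hypomethylated in the IC group), with the
       per-sample effect magnitude drifting with institutionalization duration
       when ``duration_coupling > 0``;
    4. demographic (age, gender) effects on a random probe subset;
    5. logit-scale Gaussian noise, inverse-logit, clip to [1e-6, 1 - 1e-6];
    6. detection p-values, annotation, sample sheet and coupled behavior
       scores.
    """
    design.validate()
    if len(reference.probe_ids) < design.n_probes:
        raise ValueError("reference has fewer probes than design.n_probes")
    rng = np.random.default_rng(design.seed)
    probe_ids = reference.probe_ids[: design.n_probes]
    R = reference.matrix[: design.n_probes]
    n = design.n_ic + design.n_bfc

    samples = _sample_sheet(design, rng)
    is_ic = (samples["group"] == "IC").to_numpy()

    frac_ic = sample_cell_fractions(
        design.n_ic,
        design.dirichlet_means_ic,
        design.concentration,
        seed=int(rng.integers(2**31)),
    )
    frac_bfc = sample_cell_fractions(
        design.n_bfc,
        design.dirichlet_means_bfc,
        design.concentration,
        seed=int(rng.integers(2**31)),
    )
    w = np.vstack([frac_ic.to_numpy(), frac_bfc.to_numpy()])
    true_fractions = pd.DataFrame(w, index=samples.index, columns=list(CELL_TYPES))

    beta = R @ w.T  # probes x samples

    # --- planted group-differential CpGs -----------------------------------
    ref_mean = R.mean(axis=1)
    ref_spread = R.max(axis=1) - R.min(axis=1)
    candidates = np.flatnonzero(
        (ref_mean > 0.12) & (ref_mean < 0.32) & (ref_spread < 0.2)
    )
    if candidates.size < design.n_planted_dmes:
        raise ValueError(
            "not enough low-methylated non-discriminating probes to plant effects"
        )
    planted = rng.choice(candidates, size=design.n_planted_dmes, replace=False)
    planted.sort()
    signs = np.ones(design.n_planted_dmes)
    signs[1::2] = -1.0  # half hyper-, half hypomethylated in IC

    dur = samples.loc[is_ic, "duration_months"].to_numpy()
    if design.n_ic > 1 and dur.std(ddof=0) > 0:
        mult = 1.0 + design.duration_coupling * (dur - dur.mean()) / dur.std(ddof=0)
    else:
        mult = np.ones(design.n_ic)
    mult = np.clip(mult, 0.1, 2.5)
    if mult.mean() > 0:
        mult = mult / mult.mean()  # keep the group mean shift at effect_delta

    pattern = np.zeros(n)
    pattern[is_ic] = mult
    if design.composition_orthogonal and design.n_planted_dmes > 0:
        # remove the component of the effect pattern that lies in the span of
        # the cell fractions (plus intercept): the ground truth is
        # condition-driven signal unexplained by blood composition
        X = np.column_stack([np.ones(n), w])
        pattern = pattern - X @ np.linalg.lstsq(X, pattern, rcond=None)[0]
        contrast = pattern[is_ic].mean() - pattern[~is_ic].mean()
        if abs(contrast) < 1e-8:
            raise ValueError(
                "cell fractions fully explain the group contrast; cannot plant "
                "composition-orthogonal effects"
            )
        pattern = pattern / contrast  # group mean difference back to 1
    effect = np.zeros((design.n_probes, n))
    effect[planted] = design.effect_delta * signs[:, None] * pattern[None, :]
    beta = beta + effect

    # --- demographic effects on a random probe subset ----------------------
    non_planted = np.setdiff1d(np.arange(design.n_probes), planted)
    n_demo = int(round(design.frac_demo_probes * design.n_probes))
    demo = rng.choice(non_planted, size=min(n_demo, non_planted.size), replace=False)
    demo.sort()
    age_c = samples["age_months"].to_numpy() - samples["age_months"].mean()
    gender = samples["gender"].to_numpy()
    age_slope = design.demo_effect_size * rng.normal(0.004, 0.001, size=demo.size)
    sex_off = design.demo_effect_size * rng.normal(0.0, 0.03, size=demo.size)
    beta[demo] += age_slope[:, None] * age_c[None, :] + sex_off[:, None] * gender[None, :]

    # --- measurement noise on the logit scale ------------------------------
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    if design.noise_sd > 0:
        beta = expit(logit(beta) + rng.normal(0.0, design.noise_sd, size=beta.shape))
    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"),
                           columns=samples.index)

    # --- detection p-values ------------------------------------------------
    detp = rng.uniform(1e-6, 0.01, size=beta.shape)
    protected_rows = np.zeros(design.n_probes, dtype=bool)
    protected_rows[planted] = True
    protected_rows[: _head_block_len(R)] = True
    cells = np.flatnonzero(~protected_rows[:, None] & np.ones((1, n), dtype=bool))
    n_fail = int(round(design.detp_fail_rate * design.n_probes * n))
    if n_fail > 0 and cells.size:
        fail = rng.choice(cells, size=min(n_fail, cells.size), replace=False)
        detp.flat[fail] = rng.uniform(0.051, 0.8, size=fail.size)
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=beta_df.columns)

    annotation = _annotation(design, probe_ids, protected_rows, rng)

    # --- behavior scores coupled to planted CpGs ---------------------------
    zb = beta[planted] if planted.size else np.zeros((0, n))
    if planted.size:
        zb = (zb - zb.mean(axis=1, keepdims=True)) / np.where(
            zb.std(axis=1, ddof=0) > 0, zb.std(axis=1, ddof=0), 1.0
        )[:, None]
        epi_score = (-signs[:, None] * zb).mean(axis=0)
    else:
        epi_score = np.zeros(n)
    intercepts = dict(zip(VABS_DOMAINS, (30.0, 25.0, 30.0, 35.0)))
    slopes = dict(zip(VABS_DOMAINS, (1.5, 1.2, 1.4, 1.8)))
    vabs = {}
    for d in VABS_DOMAINS:
        vabs[d] = np.maximum(
            intercepts[d]
            + slopes[d] * samples["age_vabs_months"].to_numpy()
            + design.vabs_coupling * epi_score
            + rng.normal(0.0, design.vabs_noise_sd, size=n),
            0.0,
        ).round(1)
    vabs_raw = pd.DataFrame(vabs, index=samples.index)
    if design.n_vabs_missing_bfc > 0:
        bfc_ids = samples.index[~is_ic]
        miss = rng.choice(
            bfc_ids, size=min(design.n_vabs_missing_bfc, bfc_ids.size), replace=False
        )
        vabs_raw.loc[miss] = np.nan

    truth = {
        "planted_probes": list(probe_ids[planted]),
        "planted_signs": {probe_ids[p]: float(s) for p, s in zip(planted, signs)},
        "duration_multipliers": {
            sid: float(m) for sid, m in zip(samples.index[is_ic], mult)
        },
        "demo_probes": list(probe_ids[demo]),
        "vabs_coupling": design.vabs_coupling,
        "duration_coupling": design.duration_coupling,
        "effect_delta": design.effect_delta,
        "seed": design.seed,
    }
    return SyntheticCohort(
        beta=beta_df,
        detp=detp_df,
        annotation=annotation,
        samples=samples,
        vabs_raw=vabs_raw,
        truth={**truth, "true_fractions": true_fractions},
    )


def _head_block_len(R: np.ndarray) -> int:
    """Length of the discriminating head block of a generated reference.

    Generated references place their discriminating probes first; they are
    recognizable by a cross-type spread >= 0.6.  Scanning from the top keeps
    the simulator independent of how the reference was parameterized.
    """
    spread = R.max(axis=1) - R.min(axis=1)
    i = 0
    while i < len(spread) and spread[i] >= 0.6:
        i += 1
    return i
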