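"""Euclidean deviation from the normative profile.

Each exposed-group child's behavior Z-profile and DMES methylation z-profile
is summarized by its distance from the comparison group's mean profile
(D_VABS, D_EPI, scaled into [0, 1]); the distances are correlated with
institutionalization duration and with each other (shared variance R^2).
"""

from ewaskit.adjust import adjust_betas, adjust_vabs
from ewaskit.deviation import deviation_associations, deviation_scores, normative_profile
from ewaskit.simulate import CohortDesign, generate_cohort, generate_reference_methylome

reference = generate_reference_methylome(2000, 30, seed=1)
cohort = generate_cohort(
    CohortDesign(n_probes=2000, vabs_coupling=6.0, n_vabs_missing_bfc=0, seed=7),
    reference,
)

vabs_z = adjust_vabs(cohort.vabs_raw, cohort.samples)
zvalues = adjust_betas(cohort.beta.loc[cohort.truth["planted_probes"]], cohort.samples)
ic = cohort.samples.index[cohort.samples["group"] == "IC"]
bfc = cohort.samples.index[cohort.samples["group"] == "BFC"]

d_vabs = deviation_scores(vabs_z.loc[ic].to_numpy(), normative_profile(vabs_z.loc[bfc].to_numpy()))
d_epi = deviation_scores(zvalues[ic].to_numpy().T, normative_profile(zvalues[bfc].to_numpy().T))

placement = cohort.samples.loc[ic, "age_at_placement_months"].to_numpy(float)
res = deviation_associations(
    d_epi, d_vabs,
    cohort.samples.loc[ic, "duration_months"].to_numpy(float),
    subcohort_mask=placement <= 1.0,  # institutionalized at birth
)
print(f"r(D_EPI,  duration) = {res.r_depi_duration.statistic:.4f} "
      f"(p = {res.r_depi_duration.p_two_sided:.4f})")
print(f"r(D_VABS, duration) = {res.r_dvabs_duration.statistic:.4f} "
      f"(p = {res.r_dvabs_duration.p_two_sided:.4f})")
print(f"R^2(D_EPI, D_VABS), full cohort (n={res.full['n']}): {res.full['r_squared']:.4f}")
if res.subcohort:
    print(f"R^2, placed-at-birth subcohort (n={res.subcohort['n']}): "
          f"{res.subcohort['r_squared']:.4f}")
# Longer institutionalization pushes both profiles away from the normative
# one; the shared variance links the epigenetic and behavioral deviations.
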