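"""Call differentially methylated CpG sites (DMESs) and check recovery.

The cascade: empirical-Bayes moderated t -> Benjamini-Hochberg -> signed
beta fold-change gate (|FC| >= 1.2) -> elimination of candidates whose
methylation tracks blood cell composition.
"""

from ewaskit import deconvolution, qc
from ewaskit.dmes import call_dmes
from ewaskit.simulate import CohortDesign, generate_cohort, generate_reference_methylome

reference = generate_reference_methylome(5000, 50, seed=7)
cohort = generate_cohort(CohortDesign(noise_sd=0.05, seed=7), reference)

beta, _ = qc.filter_probes(cohort.beta, cohort.detp, cohort.annotation)
beta = qc.quantile_normalize(beta, qc.promoter_strata(cohort.annotation, beta.index))
probes = deconvolution.select_discriminating_probes(reference, 50).intersection(beta.index)
fractions = deconvolution.estimate_cell_fractions(beta, reference, probes)

table, cascade = call_dmes(beta, cohort.samples["group"], fractions)
for key, value in cascade.items():
    print(f"{key:>26}: {value}")

called = set(table.index[table["is_dmes"]])
planted = set(cohort.truth["planted_probes"])
tp = len(called & planted)
print(f"\nsensitivity vs. planted truth: {tp / len(planted):.2f}")
print(f"empirical FDR:                 {(len(called) - tp) / max(1, len(called)):.2f}")
print("\nstrongest hypermethylated DMES:")
print(table[table["is_dmes"] & (table["direction"] == "hyper")]
      .nsmallest(1, "p_adj")[["delta", "fc", "t_mod", "p_adj"]].round(4).to_string())
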