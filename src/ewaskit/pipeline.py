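"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes, on a cohort TSV bundle: probe filtering ->
stratified quantile normalization -> leukocyte deconvolution -> DMES calling
(moderated t, BH, fold-change gate, cell-composition elimination) ->
demographic residualization -> methylation/behavior association ->
deviation-from-normative-profile analysis; it writes stage outputs, a
cascade-count log and a JSON + Markdown report.  ``simulate`` wraps the
synthetic cohort generator and writes a bundle that ``run_pipeline`` accepts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from ewaskit import adjust, deconvolution, deviation, dmes, io, qc, simulate as sim
from ewaskit.simulate import CohortDesign, ReferenceMethylome


@dataclass
class PipelineConfig:
    indir: str
    outdir: str
    detection_threshold: float = 0.05
    max_fail_fraction: float = 0.0
    maf_threshold: float = 0.05
    strata: str = "promoter"  # 'promoter' (two strata) or 'single'
    k_discriminating: int = 50
    padj_threshold: float = 0.05
    fc_threshold: float = 1.2
    cell_alpha: float = 0.05
    scaling: str = "cohort-max"
    birth_cutoff_months: float = 1.0
    seed: int = 0

    _RANGES = {
        "detection_threshold": (0.0, 1.0),
        "max_fail_fraction": (0.0, 1.0),
        "maf_threshold": (0.0, 0.5),
        "padj_threshold": (0.0, 1.0),
        "fc_threshold": (1.0, 10.0),
        "cell_alpha": (0.0, 1.0),
    }

    def validate(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"{key}={v} outside [{lo}, {hi}]")
        if self.strata not in ("promoter", "single"):
            raise ValueError("strata must be 'promoter' or 'single'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Plain ``key = value`` text format; unknown keys are rejected."""
        fields = {f: type(getattr(cls, f, "")) for f in cls.__dataclass_fields__}
        kwargs = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if key in ("indir", "outdir", "strata", "scaling"):
                kwargs[key] = value
            elif key in ("k_discriminating", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def simulate(design: CohortDesign, outdir, k_discriminating: int = 50) -> Path:
    """Generate a cohort bundle (including the reference methylome) on disk."""
    reference = sim.generate_reference_methylome(
        design.n_probes, k_discriminating, seed=design.seed + 1_000_003
    )
    cohort = sim.generate_cohort(design, reference)
    outdir = io.write_cohort(cohort, outdir)
    io.write_table(reference.to_frame(), outdir / "reference.tsv")
    meta = {"seed": design.seed, "design": {k: v for k, v in asdict(design).items()}}
    (outdir / f"design_seed{design.seed}.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=list) + "\n",
        encoding="utf-8",
    )
    return outdir


def _load_reference(indir) -> ReferenceMethylome:
    ref = io.read_table(Path(indir) / "reference.tsv")
    return ReferenceMethylome(
        probe_ids=ref.index.to_numpy(), matrix=ref.to_numpy(dtype=float)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a cohort bundle; returns the report dictionary."""
    config.validate()
    indir, outdir = Path(config.indir), Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = io.read_cohort(indir)
    reference = _load_reference(indir)
    samples = cohort.samples

    # --- stage 1: probe filtering -----------------------------------------
    beta_f, report = qc.filter_probes(
        cohort.beta,
        cohort.detp,
        cohort.annotation,
        detection_threshold=config.detection_threshold,
        maf_threshold=config.maf_threshold,
        max_fail_fraction=config.max_fail_fraction,
    )

    # --- stage 2: normalization -------------------------------------------
    strata = (
        qc.promoter_strata(cohort.annotation, beta_f.index)
        if config.strata == "promoter"
        else None
    )
    beta_n = qc.quantile_normalize(beta_f, strata)

    # --- stage 3: deconvolution -------------------------------------------
    probes = deconvolution.select_discriminating_probes(
        reference, config.k_discriminating
    ).intersection(beta_n.index)
    fractions = deconvolution.estimate_cell_fractions(beta_n, reference, probes)
    composition = deconvolution.compare_cell_composition(fractions, samples)
    io.write_table(fractions, outdir / "fractions.tsv")
    io.write_table(composition, outdir / "composition_tests.tsv")

    # --- stage 4: DMES calling --------------------------------------------
    table, cascade = dmes.call_dmes(
        beta_n,
        samples["group"],
        fractions,
        padj_threshold=config.padj_threshold,
        fc_threshold=config.fc_threshold,
        cell_alpha=config.cell_alpha,
    )
    io.write_table(table, outdir / "dmes.tsv")
    dmes_ids = table.index[table["is_dmes"]]

    # --- stage 5: demographic adjustment ----------------------------------
    vabs_z = adjust.adjust_vabs(cohort.vabs_raw, samples)
    io.write_table(vabs_z, outdir / "vabs_z.tsv")
    report_out = {
        "filter_report": report.to_dict(),
        "cascade": cascade,
        "n_dmes": int(len(dmes_ids)),
        "composition": {
            "granulocyte_t_welch": float(composition.loc["Gran", "t_welch"]),
        },
    }

    deviation_summary = None
    if len(dmes_ids):
        zvalues = adjust.adjust_betas(beta_n.loc[dmes_ids], samples)
        io.write_table(zvalues, outdir / "zvalues.tsv")

        # --- stage 6: association with behavior ---------------------------
        from ewaskit.groupstats import partial_correlation, spearman_with_bh

        spearman = spearman_with_bh(zvalues, vabs_z)
        io.write_table(spearman.set_index("probe_id"), outdir / "spearman.tsv")
        report_out["n_nominal_spearman_probes"] = int(
            spearman[spearman["nominal_hit"].fillna(False)]["probe_id"].nunique()
        )

        ic = samples.index[samples["group"] == "IC"]
        cov = samples.loc[ic, ["gender", "age_at_placement_months"]].to_numpy(float)
        dur = samples.loc[ic, "duration_months"].to_numpy(float)
        rows = []
        for probe in dmes_ids:
            res = partial_correlation(zvalues.loc[probe, ic].to_numpy(), dur, cov)
            rows.append((probe, res.statistic, res.p_two_sided))
        duration_tbl = pd.DataFrame(
            rows, columns=["probe_id", "partial_r", "p"]
        ).set_index("probe_id")
        io.write_table(duration_tbl, outdir / "duration_partial_corr.tsv")
        report_out["n_nominal_duration_probes"] = int((duration_tbl["p"] < 0.05).sum())

        # --- stage 7: deviation analysis -----------------------------------
        ic_v = [s for s in ic if vabs_z.loc[s].notna().all()]
        bfc = samples.index[samples["group"] == "BFC"]
        bfc_v = [s for s in bfc if vabs_z.loc[s].notna().all()]
        nv_vabs = deviation.normative_profile(vabs_z.loc[bfc_v].to_numpy())
        nv_epi = deviation.normative_profile(zvalues[bfc].to_numpy().T)
        d_vabs = deviation.deviation_scores(
            vabs_z.loc[ic_v].to_numpy(), nv_vabs, config.scaling
        )
        d_epi = deviation.deviation_scores(
            zvalues[ic_v].to_numpy().T, nv_epi, config.scaling
        )
        placement = samples.loc[ic_v, "age_at_placement_months"].to_numpy(float)
        assoc = deviation.deviation_associations(
            d_epi,
            d_vabs,
            samples.loc[ic_v, "duration_months"].to_numpy(float),
            subcohort_mask=placement <= config.birth_cutoff_months,
        )
        dev_tbl = assoc.per_sample.copy()
        dev_tbl.insert(0, "sample_id", ic_v)
        io.write_table(dev_tbl.set_index("sample_id"), outdir / "deviation.tsv")
        deviation_summary = {
            "r_depi_duration": assoc.r_depi_duration.statistic,
            "p_depi_duration": assoc.r_depi_duration.p_two_sided,
            "r_dvabs_duration": assoc.r_dvabs_duration.statistic,
            "p_dvabs_duration": assoc.r_dvabs_duration.p_two_sided,
            "full": assoc.full,
            "subcohort_at_birth": assoc.subcohort,
        }
    report_out["deviation"] = deviation_summary

    # --- provenance and report --------------------------------------------
    from ewaskit import __version__

    # paths are excluded so that identical analyses are byte-identical
    # regardless of where their inputs and outputs live
    cfg = {k: v for k, v in asdict(config).items() if k not in ("indir", "outdir")}
    report_out["provenance"] = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    (outdir / "report.json").write_text(
        json.dumps(report_out, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )
    (outdir / "report.md").write_text(_markdown_report(report_out), encoding="utf-8")
    return report_out


def _markdown_report(rep: dict) -> str:
    fr = rep["filter_report"]
    ca = rep["cascade"]
    lines = [
        "# Pipeline report",
        "",
        "## Probe filtering",
        f"- input probes: {fr['n_input']}",
        f"- removed (detection): {fr['n_removed_detection']}",
        f"- removed (missing): {fr['n_removed_missing']}",
        f"- removed (sex chromosomes): {fr['n_removed_sex']}",
        f"- removed (common SNPs): {fr['n_removed_snp']}",
        f"- retained: {fr['n_retained']}",
        "",
        "## Differential methylation cascade",
        f"- tested: {ca['n_tested']}",
        f"- significant after BH: {ca['n_significant']}",
        f"- plus fold-change gate: {ca['n_significant_and_fc']}",
        f"- removed by cell-composition filter: {ca['n_removed_by_cell_filter']}",
        f"- final DMESs: {ca['n_dmes']} ({ca['n_hyper']} hyper / {ca['n_hypo']} hypo)",
        "",
    ]
    dev = rep.get("deviation")
    if dev is None:
        lines += ["## Deviation analysis", "- 0 DMES sites: deviation analysis skipped", ""]
    else:
        lines += [
            "## Deviation analysis",
            f"- r(D_EPI, duration) = {dev['r_depi_duration']:.4f} (p = {dev['p_depi_duration']:.4f})",
            f"- r(D_VABS, duration) = {dev['r_dvabs_duration']:.4f} (p = {dev['p_dvabs_duration']:.4f})",
            f"- R^2(D_EPI, D_VABS), full cohort = {dev['full']['r_squared']:.4f}",
            "",
        ]
    lines.append(f"config sha256: {rep['provenance']['config_sha256']}")
    lines.append("")
    return "\n".join(lines)
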