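"""Reading and writing the cohort TSV bundle.

All tables are UTF-8 TSV with a header row and '.' decimals; probe-indexed
tables share one probe order.  A fixture directory contains ``beta.tsv``,
``detp.tsv``, ``annotation.tsv``, ``samples.tsv``, ``vabs.tsv`` and
``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort, outdir) -> Path:
    """Write a :class:`~ewaskit.simulate.SyntheticCohort` as a TSV bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.beta, outdir / "beta.tsv")
    write_table(cohort.detp, outdir / "detp.tsv")
    write_table(cohort.annotation, outdir / "annotation.tsv")
    write_table(cohort.samples, outdir / "samples.tsv")
    write_table(cohort.vabs_raw, outdir / "vabs.tsv")
    truth = dict(cohort.truth)
    fractions = truth.pop("true_fractions")
    write_table(fractions, outdir / "true_fractions.tsv")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def read_cohort(indir):
    """Read a TSV bundle back into a :class:`~ewaskit.simulate.SyntheticCohort`."""
    from ewaskit.simulate import SyntheticCohort

    indir = Path(indir)
    with open(indir / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    truth["true_fractions"] = read_table(indir / "true_fractions.tsv")
    return SyntheticCohort(
        beta=read_table(indir / "beta.tsv"),
        detp=read_table(indir / "detp.tsv"),
        annotation=read_table(indir / "annotation.tsv"),
        samples=read_table(indir / "samples.tsv"),
        vabs_raw=read_table(indir / "vabs.tsv"),
        truth=truth,
    )
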