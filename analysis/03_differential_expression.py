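#!/usr/bin/env python
"""Differential-expression reduction on the synthetic arrays and gels.

Runs the two-channel array pipeline for both comparisons (N vs C and
CN vs C), applies the standard (fold > 2, BH-adjusted p < 0.05) and
strict (fold > 3.5, raw p < 0.03) filters, calls 2-D-gel protein spots,
and counts comparison overlap and transcript-protein concordance.
Writes results/de/.
"""

from pathlib import Path

import pandas as pd

from phaomics import io, omics_de

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "synthetic_study"
OUT = ROOT / "results" / "de"


def run_comparison(label: str) -> pd.DataFrame:
    arrays = io.read_arrays(DATA / f"arrays_{label}.tsv")
    ratios = omics_de.normalize_and_logratio(arrays)
    table = omics_de.transcript_de_table(ratios)
    called, summary = omics_de.call_transcript_de(table)
    called.to_csv(OUT / f"de_{label}.tsv", sep="\t")
    strict = omics_de.strict_cutoff_filter(table)
    truth = pd.read_csv(
        DATA / f"arrays_{label}_truth.tsv", sep="\t", index_col=0
    )
    planted = int(truth["is_de"].sum())
    print(
        f"{label}: {summary.n_up} up / {summary.n_down} down of "
        f"{planted} planted; strict cut-off keeps {len(strict)}"
    )
    return called


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run 01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    called_n = run_comparison("N_vs_C")
    called_cn = run_comparison("CN_vs_C")

    spots = io.read_spots(DATA / "spots_N_vs_C.tsv")
    protein = omics_de.call_protein_de(spots)
    protein.to_csv(OUT / "protein_calls_N_vs_C.tsv", sep="\t")

    result = omics_de.overlap_and_concordance(called_n, called_cn, protein)
    result["concordance"].to_csv(OUT / "concordance.tsv", sep="\t", index=False)
    n_spots_de = int((protein["call"] != "ns").sum())
    print(
        f"comparisons share {result['n_shared']} DE loci; "
        f"{n_spots_de} DE spots, {result['n_concordant']} concordant "
        "with their transcripts"
    )


if __name__ == "__main__":
    main()
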