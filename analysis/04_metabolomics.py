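#!/usr/bin/env python
"""Metabolite annotation, normalization, QC and level-change calls.

Annotates the synthetic GC-MS peaks against the library via retention
index + match factor, normalizes by ribitol internal standard and CDW,
computes technical/biological RSDs and the condition-profile Pearson
correlations, and calls level changes relative to the carbon-limited
reference.  Writes results/metabolomics/.
"""

from pathlib import Path

import pandas as pd

from phaomics import io, metabolomics as mb, synthetic

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "synthetic_study"
OUT = ROOT / "results" / "metabolomics"


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run 01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    ladder = io.read_ladder(DATA / "ladder.tsv")
    library = io.read_library(DATA / "library.tsv")
    samples = io.read_peaks(DATA / "peaks.tsv")

    rows = []
    for sample_id, peaks in samples.items():
        condition, replicate = sample_id.split("_", 1)
        annotated = []
        for peak in peaks:
            indexed = mb.MetabolitePeak(
                retention_time=peak.retention_time,
                area=peak.area,
                spectrum=peak.spectrum,
                retention_index=mb.retention_index(peak.retention_time, ladder),
                sample_id=sample_id,
            )
            hit = mb.annotate(indexed, library)
            annotated.append((indexed, hit))
        is_area = sum(
            p.area for p, h in annotated
            if h and h.name == synthetic.INTERNAL_STANDARD_NAME
        )
        for peak, hit in annotated:
            if hit is None or hit.name == synthetic.INTERNAL_STANDARD_NAME:
                continue
            rows.append(
                {
                    "metabolite": hit.name,
                    "condition": condition,
                    "replicate_class": "technical",
                    "replicate": replicate,
                    "value": mb.normalize_abundance(peak.area, is_area, 0.01),
                    "match": hit.match,
                }
            )
    abundance = pd.DataFrame(rows)
    abundance.to_csv(OUT / "abundance.tsv", sep="\t", index=False)

    # technical RSD is within-fermentor: group by (condition, cultivation)
    within = abundance.copy()
    within["condition"] = (
        within["condition"] + ":" + within["replicate"].str.split("_").str[0]
    )
    qc_technical = mb.qc_metrics(within)
    qc_technical["rsd_table"].to_csv(OUT / "qc.tsv", sep="\t", index=False)
    mean_rsd = qc_technical["mean_rsd_percent"].get("technical", float("nan"))
    qc = mb.qc_metrics(abundance)
    print(f"annotated {abundance['metabolite'].nunique()} metabolites; "
          f"mean technical RSD {mean_rsd:.1f}%")
    for pair, r in qc["pearson_log10"].items():
        print(f"Pearson r (log10 mean profiles) {pair[0]} vs {pair[1]}: {r:.3f}")

    calls = mb.level_change_calls(
        abundance, "carbon", excluded=qc["excluded_metabolites"]
    )
    calls.to_csv(OUT / "level_changes.tsv", sep="\t")
    print("level-change calls vs carbon limitation:")
    print(calls.to_string())


if __name__ == "__main__":
    main()
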