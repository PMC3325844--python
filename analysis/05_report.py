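#!/usr/bin/env python
"""Assemble the final summary tables from the completed analysis steps.

Collects the physiology summary, DE counts and metabolite level-change
calls into results/report/ and prints a compact overview.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
OUT = RESULTS / "report"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    produced = []

    physiology_path = RESULTS / "physiology_summary.tsv"
    if physiology_path.exists():
        summary = pd.read_csv(physiology_path, sep="\t", index_col=0)
        summary.to_csv(OUT / "physiology_summary.tsv", sep="\t")
        produced.append("physiology")
        print("physiology:")
        print(
            summary[["c0_n0", "y_xc", "y_xn", "regime", "q_pha"]]
            .round(3)
            .to_string()
        )

    de_dir = RESULTS / "de"
    if de_dir.exists():
        counts = []
        for path in sorted(de_dir.glob("de_*.tsv")):
            table = pd.read_csv(path, sep="\t", index_col=0)
            vc = table["call"].value_counts()
            counts.append(
                {
                    "comparison": path.stem.removeprefix("de_"),
                    "n_up": int(vc.get("up", 0)),
                    "n_down": int(vc.get("down", 0)),
                }
            )
        de_summary = pd.DataFrame(counts)
        de_summary.to_csv(OUT / "de_summary.tsv", sep="\t", index=False)
        produced.append("differential expression")
        print("\ndifferential expression:")
        print(de_summary.to_string(index=False))

    lc_path = RESULTS / "metabolomics" / "level_changes.tsv"
    if lc_path.exists():
        calls = pd.read_csv(lc_path, sep="\t", index_col=0)
        calls.to_csv(OUT / "level_changes.tsv", sep="\t")
        produced.append("metabolite level changes")

    if not produced:
        raise SystemExit("no stage outputs found; run the earlier steps")
    print(f"\nreport tables written to {OUT} ({', '.join(produced)})")


if __name__ == "__main__":
    main()
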