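#!/usr/bin/env python
"""Generate the synthetic study used by the downstream analysis steps.

Writes all pipeline input tables (feed, steady states, traces, GC peak
tables, arrays, spots, metabolite peaks, ladder, library) plus the
planted truth under results/synthetic_study/.
"""

import json
from pathlib import Path

from phaomics import io, synthetic

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = synthetic.simulate_study(seed=SEED)
    io.write_feed({s.name: s.feed for s in study.conditions}, OUT / "feed.tsv")
    io.write_steady_states(study.steady_states, OUT / "steadystate.tsv")
    study.replicates.to_csv(OUT / "replicates.tsv", sep="\t", index=False)
    for cond, trace in study.traces.items():
        io.write_trace(trace, OUT / f"trace_{cond}.tsv")
    io.write_gc_runs(
        {f"{c}_rep{r}": run for (c, r), run in study.gc_runs.items()},
        OUT / "gc_peaks.tsv",
        OUT / "gc_meta.tsv",
    )

    # two array comparisons, as in the study design: N vs C and CN vs C
    for label, seed in (("N_vs_C", SEED + 1), ("CN_vs_C", SEED + 2)):
        arrays, truth = synthetic.simulate_arrays(n_features=5000, seed=seed)
        io.write_arrays(arrays, OUT / f"arrays_{label}.tsv")
        truth.to_csv(OUT / f"arrays_{label}_truth.tsv", sep="\t")
    _, truth_n = synthetic.simulate_arrays(n_features=5000, seed=SEED + 1)
    spots, spot_truth = synthetic.simulate_spots(truth_n, n_spots=74, seed=SEED + 3)
    io.write_spots(spots, OUT / "spots_N_vs_C.tsv")
    spot_truth.to_csv(OUT / "spots_N_vs_C_truth.tsv", sep="\t")

    abundances, level_truth = synthetic.simulate_metabolite_abundances(seed=SEED + 4)
    abundances.to_csv(OUT / "abundances.tsv", sep="\t", index=False)
    peaks = synthetic.simulate_metabolite_peaks(
        abundances[abundances["replicate_class"] == "technical"],
        noise=0.02,
        seed=SEED + 5,
    )
    io.write_peaks(peaks, OUT / "peaks.tsv")
    io.write_ladder(synthetic.default_ladder(), OUT / "ladder.tsv")
    io.write_library(synthetic.default_library(), OUT / "library.tsv")

    truth = {
        "seed": SEED,
        "borders": [study.truth.borders.lower_border,
                    study.truth.borders.upper_border],
        "regimes": dict(study.truth.regimes),
        "q_pha": dict(study.truth.q_pha),
        "co2_share_percent": dict(study.truth.co2_share),
        "level_changes": {m: dict(r) for m, r in level_truth.iterrows()},
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))
    print(f"synthetic study (seed {SEED}) written to {OUT}")
    print(f"planted regimes: {study.truth.regimes}")


if __name__ == "__main__":
    main()
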