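#!/usr/bin/env python
"""Can ratio ranking find genes under planted selection?

Generates the benchmark cohort (1000 genes, 300 patients; 20 genes at
selection factor 0.1, 20 at 10), ranks genes by observed/expected ratio,
and reports how much of each planted set lands in the k=50 tails. An
all-neutral cohort against the same simulation gives the chance-level
null. Writes results/recovery/.
"""

import json
import tempfile
from pathlib import Path

from exomesim import benchmark
from exomesim.ranking import select_tails

OUT = Path(__file__).resolve().parent.parent / "results" / "recovery"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        run = benchmark.planted_recovery(SEED, tmp)
        run.table.sort_values("ratio").to_csv(OUT / "ratio_table.tsv",
                                              sep="\t", float_format="%.6g")
        null_tails = select_tails(run.null_table, 50)
        lo, hi = benchmark.null_overlap_interval(len(run.null_table), 20, 50)
        overlaps = {
            f"{p_name}_in_{t_name}": len(set(p) & set(t))
            for p_name, p in (("planted_low", run.truth.nonmutated_set),
                              ("planted_high", run.truth.mutated_set))
            for t_name, t in (("null_low_tail", null_tails.nonmutated),
                              ("null_high_tail", null_tails.mutated))}
        summary = {
            "nonmutated_recovery": run.recovery_nonmutated,
            "mutated_recovery": run.recovery_mutated,
            "neutral_expected_min": float(
                run.table.drop(run.truth.nonmutated_set + run.truth.mutated_set,
                               errors="ignore")["S_g"].min()),
            "null_overlaps": overlaps,
            "null_chance_interval_95": [lo, hi],
        }
        (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"recovery: {run.recovery_nonmutated:.0%} of planted low-ratio and "
          f"{run.recovery_mutated:.0%} of planted high-ratio genes inside the "
          f"k=50 tails")
    print(f"neutral null: planted-set overlaps {list(overlaps.values())} vs "
          f"95% chance interval [{lo}, {hi}]")


if __name__ == "__main__":
    main()
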