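#!/usr/bin/env python
"""Simulate the study cohort: 14 tumors, 3-5 core biopsies each, five-gene
panel, ~950x coverage, with germline/synonymous/sub-threshold decoy calls.

Writes results/synthetic/: truth.json (ground-truth clonal structure),
calls.tsv (raw per-biopsy variant calls), regions.tsv (biopsy declaration).
"""

from pathlib import Path

from multiregion.io import write_calls_tsv
from multiregion.synthetic_cohort import (
    SimulationConfig,
    regions_by_patient,
    simulate_tumor_truth,
    simulate_variant_calls,
)

SEED = 20140
OUT = Path("results/synthetic")


def main() -> None:
    config = SimulationConfig()  # study defaults: see docs/methods.md
    truth = simulate_tumor_truth(config, seed=SEED)
    calls = simulate_variant_calls(truth, config, seed=SEED + 1)

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "truth.json").write_text(truth.to_json() + "\n")
    write_calls_tsv(calls, OUT / "calls.tsv")
    regions = regions_by_patient(truth)
    lines = ["patient_id\tregion_id"] + [
        f"{p}\t{r}" for p, rs in regions.items() for r in rs
    ]
    (OUT / "regions.tsv").write_text("\n".join(lines) + "\n")

    n_biopsies = sum(len(rs) for rs in regions.values())
    n_truth = sum(len(p.mutations) for p in truth.patients)
    n_truncal = sum(
        1 for p in truth.patients for m in p.mutations if m.classification == "truncal"
    )
    print(f"simulated {config.n_patients} tumors / {n_biopsies} biopsies")
    print(f"ground truth: {n_truth} mutations ({n_truncal} truncal, "
          f"{n_truth - n_truncal} subclonal)")
    print(f"raw call table: {len(calls)} rows -> {OUT / 'calls.tsv'}")


if __name__ == "__main__":
    main()
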