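#!/usr/bin/env python
"""Cohort heterogeneity summaries from the filtered calls.

Per-gene patient-level and biopsy-level mutation rates, the ubiquity
fraction (how often a mutant gene is present in every core), and the
mutations-per-tumor histogram. Writes results/summary/*.tsv.
"""

from pathlib import Path

import pandas as pd

from multiregion.heterogeneity import (
    UndefinedRateError,
    build_cohort,
    cohort_frequencies,
    mutations_per_tumor,
    ubiquity_fraction,
)
from multiregion.io import read_calls_tsv
from multiregion.synthetic_cohort import GENE_PANEL

SYN = Path("results/synthetic")
OUT = Path("results/summary")


def load_cohort():
    retained = read_calls_tsv(SYN / "retained.tsv")
    decl = pd.read_csv(SYN / "regions.tsv", sep="\t", dtype=str)
    regions: dict[str, list[str]] = {}
    for row in decl.itertuples(index=False):
        regions.setdefault(row.patient_id, []).append(row.region_id)
    return build_cohort(retained, regions, GENE_PANEL)


def main() -> None:
    cohort = load_cohort()
    OUT.mkdir(parents=True, exist_ok=True)

    freqs = cohort_frequencies(cohort)
    freqs.to_csv(OUT / "gene_frequencies.tsv", sep="\t")
    print("per-gene mutation rates (patient-level vs biopsy-level):")
    for gene, row in freqs.iterrows():
        print(f"  {gene:6s} {row.n_mutant_patients:2.0f}/{row.n_patients:.0f} patients "
              f"({row.patient_rate:4.0%})   {row.n_positive_biopsies:2.0f}/"
              f"{row.n_biopsies:.0f} biopsies ({row.biopsy_rate:4.0%})")

    rows = []
    for gene in GENE_PANEL:
        try:
            est = ubiquity_fraction(cohort, gene)
            rows.append({"gene": gene, "n_ubiquitous": est.numerator,
                         "n_mutant_tumors": est.denominator, "fraction": est.value})
            print(f"ubiquity {gene}: shared in {est.numerator}/{est.denominator} "
                  f"mutant tumors ({est.value:.0%})")
        except UndefinedRateError:
            print(f"ubiquity {gene}: no mutant tumor")
    pd.DataFrame.from_records(rows).to_csv(OUT / "ubiquity.tsv", sep="\t", index=False)

    hist = mutations_per_tumor(cohort)
    pd.Series(hist, name="n_tumors").rename_axis("n_mutations").to_csv(
        OUT / "mutations_per_tumor.tsv", sep="\t")
    print("mutations per tumor:", dict(hist))


if __name__ == "__main__":
    main()
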