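#!/usr/bin/env python
"""Sampling-design analysis: how many biopsies catch a prognostic mutation?

Three inputs are analyzed with the binomial detection model
P(n) = 1 - (1-p)^n:
  1. prevalences estimated from the simulated cohort,
  2. the published 14-patient multi-region panel prevalences
     (PBRM1 75%, SETD2 70%, BAP1 58%, KDM5C 55%),
  3. the independent 10-patient whole-exome cohort prevalences
     (PBRM1 69%, SETD2 53%, BAP1 41%).
Writes power tables (and plots) under results/power/.
"""

import importlib
from pathlib import Path

from multiregion.biopsy_power import (
    estimate_prevalence,
    min_biopsies,
    min_biopsies_for_gene_set,
    power_curve,
)
from multiregion.heterogeneity import UndefinedRateError

load_cohort = importlib.import_module("03_cohort_summary").load_cohort

OUT = Path("results/power")
OWN_COHORT = {"PBRM1": 0.75, "SETD2": 0.70, "BAP1": 0.58, "KDM5C": 0.55}
INDEPENDENT = {"PBRM1": 0.69, "SETD2": 0.53, "BAP1": 0.41}
TARGET = 0.90


def analyze(name: str, p_by_gene: dict[str, float]) -> None:
    curve = power_curve(p_by_gene, n_max=10)
    (OUT / f"power_{name}.tsv").write_text(curve.to_tsv())
    curve.plot(OUT / f"power_{name}.png")
    n_panel = min_biopsies_for_gene_set(p_by_gene, TARGET)
    per_gene = {g: min_biopsies(p, TARGET) for g, p in p_by_gene.items()}
    print(f"[{name}] prevalences {p_by_gene}")
    print(f"  biopsies for {TARGET:.0%} certainty per gene: {per_gene}")
    print(f"  -> whole panel needs {n_panel} biopsies\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cohort = load_cohort()
    estimated = {}
    for gene in cohort.gene_panel:
        try:
            est = estimate_prevalence(cohort, gene)
        except UndefinedRateError:
            continue
        estimated[gene] = est.p
        print(f"simulated-cohort prevalence {gene}: "
              f"{est.n_positive_biopsies}/{est.n_total_biopsies} = {est.p:.2f} "
              f"({est.n_patients_included} mutant patients)")
    print()
    analyze("simulated", estimated)
    analyze("own_cohort", OWN_COHORT)
    analyze("independent", INDEPENDENT)


if __name__ == "__main__":
    main()
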