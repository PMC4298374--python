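"""Intratumor mutation prevalence and biopsy sampling-design power.

The intratumor prevalence p of a gene's mutation is estimated by pooling
biopsies across mutation-positive patients: the proportion of all biopsies
with a mutation in the gene among patients who have at least one positive
biopsy. Patients with no positive biopsy are assumed to lack the mutation
entirely and are excluded from both numerator and denominator.

Under the model that n biopsies are independent and uniformly placed, the
number of mutation-bearing biopsies is Binomial(n, p), so the probability
that at least one detects the mutation is

    P(detect | n) = 1 - (1 - p)^n.

``min_biopsies`` inverts this for a target certainty (inclusive threshold:
the smallest n with P >= target), and ``min_biopsies_for_gene_set`` takes
the worst case over a gene panel so that every gene individually reaches
the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .heterogeneity import CohortData, UndefinedRateError

__all__ = [
    "PrevalenceEstimate",
    "PowerCurve",
    "estimate_prevalence",
    "detection_probability",
    "min_biopsies",
    "min_biopsies_for_gene_set",
    "power_curve",
]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Pooled intratumor prevalence for one gene with count provenance.

    ``p`` is n_positive_biopsies / n_total_biopsies where the denominator
    counts only biopsies from the ``n_patients_included`` patients that have
    at least one positive biopsy.
    """

    gene: str
    p: float
    n_positive_biopsies: int
    n_total_biopsies: int
    n_patients_included: int

    @property
    def percent(self) -> float:
        """Prevalence in percent, rounded half away from zero to the unit."""
        return math.floor(self.p * 100 + 0.5)


def estimate_prevalence(cohort: CohortData, gene: str) -> PrevalenceEstimate:
    """Pooled prevalence of ``gene`` mutations over mutation-positive patients.

    A biopsy is positive when it carries at least one mutation of the gene
    (a tumor with two distinct same-gene mutations contributes once per
    positive biopsy). Raises :class:`UndefinedRateError` when no patient has
    a positive biopsy.
    """
    if not cohort.profiles:
        raise ValueError("empty cohort")
    num = den = included = 0
    for profile in cohort.profiles:
        positives = sum(gene in profile.genes_in_region(r) for r in profile.regions)
        if positives == 0:
            continue  # assumed truly wild-type; excluded from both counts
        included += 1
        num += positives
        den += profile.n_regions
    if included == 0:
        raise UndefinedRateError(f"{gene}: no patient with a positive biopsy")
    return PrevalenceEstimate(
        gene=gene,
        p=num / den,
        n_positive_biopsies=num,
        n_total_biopsies=den,
        n_patients_included=included,
    )


def detection_probability(p: float, n: int) -> float:
    """P(at least one of n independent biopsies detects the mutation)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"number of biopsies must be >= 0, got {n}")
    return 1.0 - (1.0 - p) ** n


def min_biopsies(p: float, target: float = 0.90) -> int:
    """Smallest n >= 1 with detection_probability(p, n) >= target.

    Uses the closed form ceil(log(1-target) / log(1-p)), then walks to the
    exact boundary to guard against floating-point edge cases; the result
    always satisfies P(n) >= target > P(n-1).
    """
    if not (0.0 < target < 1.0):
        raise ValueError(f"target certainty must be in (0, 1), got {target}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if p == 0.0:
        raise UndefinedRateError("prevalence 0: no number of biopsies attains the target")
    if p == 1.0:
        return 1
    n = max(1, math.ceil(math.log(1.0 - target) / math.log(1.0 - p)))
    while detection_probability(p, n) < target:
        n += 1
    while n > 1 and detection_probability(p, n - 1) >= target:
        n -= 1
    return n


def min_biopsies_for_gene_set(
    p_by_gene: Mapping[str, float], target: float = 0.90
) -> int:
    """Biopsies needed so every gene in the panel reaches the target certainty.

    The answer is the max over genes of :func:`min_biopsies`; the binding
    gene is the one with the lowest prevalence.
    """
    if not p_by_gene:
        raise ValueError("empty prevalence map")
    return max(min_biopsies(p, target) for p in p_by_gene.values())


@dataclass
class PowerCurve:
    """Detection probability per gene tabulated for n = 1..n_max biopsies."""

    p_by_gene: dict[str, float]
    n_max: int
    values: pd.DataFrame  # index n, one column per gene

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t", float_format="%.6f")

    def plot(self, path: str) -> None:
        """Write a detection-power-vs-biopsies line plot to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for gene, p in self.p_by_gene.items():
            ax.plot(self.values.index, self.values[gene], marker="o",
                    label=f"{gene}: {p:.0%}")
        ax.set_xlabel("number of biopsies")
        ax.set_ylabel("probability of detecting the mutation")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def power_curve(p_by_gene: Mapping[str, float], n_max: int = 10) -> PowerCurve:
    """Tabulate detection probability for each gene over 1..n_max biopsies."""
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    for gene, p in p_by_gene.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{gene}: prevalence must be in [0, 1], got {p}")
    n = np.arange(1, n_max + 1)
    values = pd.DataFrame(
        {gene: 1.0 - (1.0 - p) ** n for gene, p in p_by_gene.items()},
        index=pd.Index(n, name="n_biopsies"),
    )
    return PowerCurve(p_by_gene=dict(p_by_gene), n_max=n_max, values=values)
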