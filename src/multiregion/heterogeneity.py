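"""Per-tumor mutation x region presence matrices and cohort summaries.

The sampling unit is a biopsy core (region) from a spatially distinct area
of one tumor. A mutation is *shared* (truncal) when it is detected in every
core of its tumor and *nonshared* (subclonal) when it is absent from at
least one core. Cohort summaries are gene-level: a patient or a biopsy is
positive for a gene when it carries at least one mutation in that gene;
mutation identity (exact chrom:pos:ref:alt) is used only to collapse the
same event across regions and to count unique mutations per tumor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_filter import VariantCall

__all__ = [
    "Mutation",
    "TumorProfile",
    "CohortData",
    "RateEstimate",
    "UndefinedRateError",
    "build_presence_matrix",
    "build_cohort",
    "classify_shared",
    "cohort_frequencies",
    "ubiquity_fraction",
    "mutations_per_tumor",
]


class UndefinedRateError(ValueError):
    """Raised when a ratio has an empty denominator (e.g. a never-mutated gene)."""


@dataclass(frozen=True)
class Mutation:
    gene: str
    variant_key: str
    patient_id: str


@dataclass
class TumorProfile:
    """Binary mutation x region presence matrix for one tumor.

    ``presence`` has one row per unique mutation (``variant_key`` within the
    patient) and one column per declared region, in declaration order. A
    region with no calls is kept as an all-zero column: a fully wild-type
    biopsy is informative. ``labels[i]`` is ``"shared"`` iff row i is
    all-ones.
    """

    patient_id: str
    regions: list[str]
    mutations: list[Mutation]
    presence: np.ndarray  # shape (n_mutations, n_regions), dtype int8
    labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_set(self, i: int) -> frozenset[str]:
        """Set of regions carrying mutation i."""
        return frozenset(r for r, v in zip(self.regions, self.presence[i]) if v)

    def genes_in_region(self, region: str) -> set[str]:
        j = self.regions.index(region)
        return {m.gene for m, row in zip(self.mutations, self.presence) if row[j]}

    def to_frame(self) -> pd.DataFrame:
        """Presence matrix as a DataFrame (variant_key, gene, then regions)."""
        df = pd.DataFrame(self.presence, columns=self.regions)
        df.insert(0, "gene", [m.gene for m in self.mutations])
        df.insert(0, "variant_key", [m.variant_key for m in self.mutations])
        return df

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError(f"{self.patient_id}: at least one region required")
        if self.presence.shape != (len(self.mutations), self.n_regions):
            raise ValueError(f"{self.patient_id}: presence shape mismatch")
        if len(self.mutations) and not self.presence.any(axis=1).all():
            raise ValueError(f"{self.patient_id}: mutation present in no region")
        keys = [m.variant_key for m in self.mutations]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.patient_id}: duplicate variant_key rows")


@dataclass
class CohortData:
    profiles: list[TumorProfile]
    gene_panel: list[str]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.profiles]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_ids must be unique within a cohort")

    @property
    def n_patients(self) -> int:
        return len(self.profiles)

    @property
    def n_biopsies(self) -> int:
        return sum(p.n_regions for p in self.profiles)


@dataclass(frozen=True)
class RateEstimate:
    """A rate carried with its numerator/denominator provenance."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        if self.denominator == 0:
            raise UndefinedRateError("rate with zero denominator")
        return self.numerator / self.denominator


def build_presence_matrix(
    calls: Iterable[VariantCall],
    patient_id: str,
    regions: Sequence[str],
) -> TumorProfile:
    """Aggregate filtered calls of one tumor into a presence matrix.

    Identical ``variant_key``s observed in multiple regions collapse onto a
    single row (mutation identity is the exact position and alleles, not the
    gene: one tumor can carry two distinct mutations of the same gene in
    different cores). Region order follows the ``regions`` declaration; a
    call naming an undeclared region is rejected. Labels are computed
    immediately via :func:`classify_shared`.
    """
    regions = list(regions)
    if not regions:
        raise ValueError(f"{patient_id}: at least one region must be declared")
    col = {r: j for j, r in enumerate(regions)}
    rows: dict[str, set[str]] = {}
    genes: dict[str, str] = {}
    for call in calls:
        if call.patient_id != patient_id:
            raise ValueError(
                f"call for {call.patient_id!r} passed to profile {patient_id!r}"
            )
        if call.region_id not in col:
            raise ValueError(
                f"{patient_id}: unknown region {call.region_id!r} "
                f"(declared: {regions})"
            )
        key = call.variant_key
        rows.setdefault(key, set()).add(call.region_id)
        prev = genes.setdefault(key, call.gene)
        if prev != call.gene:
            raise ValueError(f"{patient_id}: {key} annotated with two genes")
    keys = sorted(rows)  # deterministic regardless of input call order
    presence = np.zeros((len(keys), len(regions)), dtype=np.int8)
    for i, key in enumerate(keys):
        for r in rows[key]:
            presence[i, col[r]] = 1
    profile = TumorProfile(
        patient_id=patient_id,
        regions=regions,
        mutations=[Mutation(genes[k], k, patient_id) for k in keys],
        presence=presence,
    )
    profile.validate()
    classify_shared(profile)
    return profile


def build_cohort(
    calls: Iterable[VariantCall],
    regions_by_patient: Mapping[str, Sequence[str]],
    gene_panel: Sequence[str],
) -> CohortData:
    """Group calls by patient and build one profile per declared patient.

    Patients declared in ``regions_by_patient`` but absent from ``calls``
    get an empty profile (a tumor with no detected mutations counts).
    """
    by_patient: dict[str, list[VariantCall]] = {p: [] for p in regions_by_patient}
    for call in calls:
        if call.patient_id not in by_patient:
            raise ValueError(f"call for undeclared patient {call.patient_id!r}")
        by_patient[call.patient_id].append(call)
    profiles = [
        build_presence_matrix(by_patient[p], p, regions_by_patient[p])
        for p in regions_by_patient
    ]
    return CohortData(profiles=profiles, gene_panel=list(gene_panel))


def classify_shared(profile: TumorProfile) -> list[str]:
    """Label each mutation shared (present in all cores) or nonshared."""
    labels = [
        "shared" if bool(row.all()) else "nonshared" for row in profile.presence
    ]
    profile.labels = labels
    return labels


def cohort_frequencies(cohort: CohortData) -> pd.DataFrame:
    """Per-gene patient-level and biopsy-level mutation rates.

    Patient-level: patients with >=1 mutation in the gene over all patients.
    Biopsy-level: biopsies with >=1 mutation in the gene over all biopsies.
    Returns a DataFrame indexed by gene with numerators, denominators and
    rates.
    """
    if not cohort.profiles:
        raise ValueError("empty cohort")
    n_patients = cohort.n_patients
    n_biopsies = cohort.n_biopsies
    records = []
    for gene in cohort.gene_panel:
        pat = sum(
            any(m.gene == gene for m in p.mutations) for p in cohort.profiles
        )
        biop = sum(
            gene in p.genes_in_region(r)
            for p in cohort.profiles
            for r in p.regions
        )
        records.append(
            {
                "gene": gene,
                "n_mutant_patients": pat,
                "n_patients": n_patients,
                "patient_rate": pat / n_patients,
                "n_positive_biopsies": biop,
                "n_biopsies": n_biopsies,
                "biopsy_rate": biop / n_biopsies,
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene")


def ubiquity_fraction(cohort: CohortData, gene: str) -> RateEstimate:
    """Among tumors mutant for ``gene``, the fraction where every core is positive.

    Gene-level positivity: a core counts as positive when it carries any
    mutation of the gene, so a tumor with two distinct same-gene mutations
    jointly covering all cores is ubiquitous for that gene. Raises
    :class:`UndefinedRateError` when no tumor carries the gene.
    """
    mutant = [p for p in cohort.profiles if any(m.gene == gene for m in p.mutations)]
    if not mutant:
        raise UndefinedRateError(f"{gene}: no mutant tumor in cohort")
    ubiquitous = sum(
        all(gene in p.genes_in_region(r) for r in p.regions) for p in mutant
    )
    return RateEstimate(numerator=ubiquitous, denominator=len(mutant))


def mutations_per_tumor(cohort: CohortData) -> dict[int, int]:
    """Histogram of unique-mutation counts per tumor (variant-level, not gene)."""
    counts = Counter(len(p.mutations) for p in cohort.profiles)
    return dict(sorted(counts.items()))
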