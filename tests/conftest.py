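"""Shared fixtures: hand-built tumor profiles and a 14-tumor cohort whose
gene-level counts reproduce the published cohort summary sentences."""

from __future__ import annotations

import numpy as np
import pytest

from multiregion.heterogeneity import (
    CohortData,
    Mutation,
    TumorProfile,
    classify_shared,
)

GENES = ("VHL", "PBRM1", "SETD2", "BAP1", "KDM5C")


def make_profile(
    patient_id: str,
    regions: list[str],
    rows: dict[str, tuple[str, set[str]]],
) -> TumorProfile:
    """Build a profile from {variant_key: (gene, region_set)}."""
    keys = sorted(rows)
    presence = np.zeros((len(keys), len(regions)), dtype=np.int8)
    for i, key in enumerate(keys):
        gene, region_set = rows[key]
        unknown = region_set - set(regions)
        if unknown:
            raise ValueError(f"unknown regions {unknown}")
        for j, r in enumerate(regions):
            if r in region_set:
                presence[i, j] = 1
    profile = TumorProfile(
        patient_id=patient_id,
        regions=list(regions),
        mutations=[Mutation(rows[k][0], k, patient_id) for k in keys],
        presence=presence,
    )
    profile.validate()
    classify_shared(profile)
    return profile


def _regions(k: int) -> list[str]:
    return [f"R{i + 1}" for i in range(k)]


@pytest.fixture(scope="session")
def paper_counts_cohort() -> CohortData:
    """14 tumors / 47 cores built to satisfy the published sentence counts.

    VHL mutant in 9/14 patients and 29/47 cores, always ubiquitous; PBRM1 in
    5 patients (13 cores, ubiquitous in 3/5), SETD2 in 3 (7 cores, 1/3),
    BAP1 in 3 (6 cores, 1/3), KDM5C in 4 (6 cores, 1/4); branching
    categories 3/4/3/1/3; three tumors with no mutations, four with exactly
    one; one tumor carrying two distinct BAP1 mutations in different cores.
    """
    full3 = {"R1", "R2", "R3"}
    full4 = {"R1", "R2", "R3", "R4"}
    profiles = [
        # three tumors with a single shared VHL mutation
        make_profile("T01", _regions(3), {"VHL:a": ("VHL", full3)}),
        make_profile("T02", _regions(3), {"VHL:b": ("VHL", full3)}),
        make_profile("T03", _regions(3), {"VHL:c": ("VHL", full3)}),
        # four tumors with multiple shared mutations (PBRM1 in 3 of the 4)
        make_profile("T04", _regions(3), {"VHL:d": ("VHL", full3), "PBRM1:a": ("PBRM1", full3)}),
        make_profile("T05", _regions(3), {"VHL:e": ("VHL", full3), "PBRM1:b": ("PBRM1", full3)}),
        make_profile("T06", _regions(3), {"VHL:f": ("VHL", full3), "PBRM1:c": ("PBRM1", full3)}),
        make_profile(
            "T07",
            _regions(3),
            {
                "VHL:g": ("VHL", full3),
                "BAP1:a": ("BAP1", full3),
                "KDM5C:a": ("KDM5C", full3),
            },
        ),
        # three tumors with shared and nonshared mutations
        make_profile(
            "T08",
            _regions(4),
            {
                "VHL:h": ("VHL", full4),
                "PBRM1:d": ("PBRM1", {"R1", "R2"}),
                "SETD2:a": ("SETD2", {"R3", "R4"}),
                "BAP1:b": ("BAP1", {"R1"}),
            },
        ),
        make_profile(
            "T09",
            _regions(4),
            {
                "VHL:i": ("VHL", full4),
                "KDM5C:b": ("KDM5C", {"R1"}),
                "SETD2:b": ("SETD2", {"R2"}),
            },
        ),
        # the most complex tumor: shared SETD2, two distinct BAP1 mutations
        # in different cores, nonshared PBRM1 and KDM5C
        make_profile(
            "T10",
            _regions(4),
            {
                "SETD2:c": ("SETD2", full4),
                "PBRM1:e": ("PBRM1", {"R1", "R2"}),
                "BAP1:c": ("BAP1", {"R1"}),
                "BAP1:d": ("BAP1", {"R3"}),
                "KDM5C:c": ("KDM5C", {"R2"}),
            },
        ),
        # a single tumor with one nonshared KDM5C mutation only
        make_profile("T11", _regions(4), {"KDM5C:d": ("KDM5C", {"R2"})}),
        # three tumors with no mutations
        make_profile("T12", _regions(4), {}),
        make_profile("T13", _regions(3), {}),
        make_profile("T14", _regions(3), {}),
    ]
    return CohortData(profiles=profiles, gene_panel=list(GENES))
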