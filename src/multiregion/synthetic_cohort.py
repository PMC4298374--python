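"""Synthetic multi-region tumor cohorts with known ground truth.

The generator emulates a cohort of primary clear-cell renal carcinomas,
each sampled by 3-5 spatially distinct core biopsies and sequenced on a
five-gene tumor-suppressor panel (VHL, PBRM1, SETD2, BAP1, KDM5C). Each
tumor receives a random clonal structure: truncal mutations carried by
every region and subclonal mutations confined to a proper subset of
regions, where all subsets are drawn from one random hierarchical
partition of the regions so that the family is laminar (pairwise nested or
disjoint) and a perfect phylogeny always exists.

The read-count layer models each biopsy as a pure sample of a single clone
(heterozygous diploid: expected variant allele fraction 0.5 x purity for a
carried mutation), with per-site depth Poisson around the mean panel
coverage, and injects three classes of decoy calls that the inclusion
filter must remove: germline SNPs (dbSNP-flagged, ~50% VAF, present in all
regions), synonymous somatic calls, and sub-threshold artifacts (VAF
strictly below 5%).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .heterogeneity import CohortData, Mutation, TumorProfile, build_presence_matrix
from .variant_filter import VariantCall

__all__ = [
    "GENE_PANEL",
    "GENE_LOCI",
    "DecoyRates",
    "SimulationConfig",
    "TruthMutation",
    "PatientTruth",
    "SyntheticTruth",
    "simulate_bernoulli_cohort",
    "simulate_tumor_truth",
    "simulate_variant_calls",
]

GENE_PANEL = ("VHL", "PBRM1", "SETD2", "BAP1", "KDM5C")

#: coding-region windows (GRCh37) used to draw variant coordinates
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "VHL": ("3", 10_183_319, 10_195_354),
    "PBRM1": ("3", 52_579_368, 52_719_933),
    "SETD2": ("3", 47_057_898, 47_205_467),
    "BAP1": ("3", 52_435_020, 52_444_121),
    "KDM5C": ("X", 53_220_503, 53_254_604),
}

_BASES = ("A", "C", "G", "T")
_CONSEQUENCES = ("missense", "nonsense", "frameshift_indel", "inframe_indel")
_CONSEQUENCE_P = (0.60, 0.20, 0.15, 0.05)

# Default per-gene clonal rates chosen to reproduce the qualitative cohort
# structure of a 14-patient five-gene ccRCC panel: VHL mutations are common
# and always truncal (an initiating event); the chromatin modulators are
# rarer and predominantly subclonal.
_DEFAULT_TRUNCAL = {"VHL": 0.64, "PBRM1": 0.21, "SETD2": 0.07, "BAP1": 0.07, "KDM5C": 0.07}
_DEFAULT_SUBCLONAL = {"VHL": 0.0, "PBRM1": 0.14, "SETD2": 0.14, "BAP1": 0.14, "KDM5C": 0.21}


@dataclass(frozen=True)
class DecoyRates:
    """Expected decoy-call counts (Poisson rates).

    ``germline_snp`` and ``synonymous`` are per patient (a germline SNP is
    carried by every biopsy of its patient); ``subthreshold`` is per biopsy
    (sequencing artifacts are independent across libraries).
    """

    germline_snp: float = 1.0
    synonymous: float = 0.5
    subthreshold: float = 0.5

    def validate(self) -> None:
        for name, rate in dataclasses.asdict(self).items():
            if rate < 0:
                raise ValueError(f"decoy rate {name} must be >= 0, got {rate}")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 14
    biopsies_per_patient: tuple[int, int] = (3, 5)  # inclusive range
    gene_panel: tuple[str, ...] = GENE_PANEL
    truncal_rate_per_gene: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRUNCAL)
    )
    subclonal_rate_per_gene: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBCLONAL)
    )
    #: uniform range for the fraction of regions a subclone occupies
    subclone_region_fraction: tuple[float, float] = (0.25, 0.75)
    #: probability that a subclonal hit is emitted as two distinct mutations
    #: of the same gene in disjoint region-sets
    double_hit_rate: float = 0.0
    mean_depth: float = 950.0
    purity: float = 0.7
    sequencing_error_rate: float = 1e-3
    decoy_rates: DecoyRates = field(default_factory=DecoyRates)
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.biopsies_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"biopsies_per_patient range invalid: {lo}..{hi}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        for name, value in (
            ("purity", self.purity),
            ("sequencing_error_rate", self.sequencing_error_rate),
            ("double_hit_rate", self.double_hit_rate),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for mapping in (self.truncal_rate_per_gene, self.subclonal_rate_per_gene):
            for gene, rate in mapping.items():
                if not (0.0 <= rate <= 1.0):
                    raise ValueError(f"rate for {gene} must be in [0, 1], got {rate}")
        flo, fhi = self.subclone_region_fraction
        if not (0.0 <= flo <= fhi <= 1.0):
            raise ValueError("subclone_region_fraction must be an ordered range in [0, 1]")
        self.decoy_rates.validate()


@dataclass(frozen=True)
class TruthMutation:
    gene: str
    variant_key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    is_indel: bool
    regions: frozenset[str]
    classification: str  # truncal | subclonal


@dataclass
class PatientTruth:
    patient_id: str
    regions: list[str]
    mutations: list[TruthMutation]

    def expected_profile(self) -> TumorProfile:
        """The presence matrix a noise-free pipeline should recover."""
        import numpy as _np

        keys = sorted(m.variant_key for m in self.mutations)
        by_key = {m.variant_key: m for m in self.mutations}
        presence = _np.zeros((len(keys), len(self.regions)), dtype=_np.int8)
        for i, key in enumerate(keys):
            for j, r in enumerate(self.regions):
                if r in by_key[key].regions:
                    presence[i, j] = 1
        profile = TumorProfile(
            patient_id=self.patient_id,
            regions=list(self.regions),
            mutations=[
                Mutation(by_key[k].gene, k, self.patient_id) for k in keys
            ],
            presence=presence,
        )
        from .heterogeneity import classify_shared

        classify_shared(profile)
        return profile


@dataclass
class SyntheticTruth:
    patients: list[PatientTruth]
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "regions": p.regions,
                    "mutations": [
                        {
                            **{
                                k: v
                                for k, v in dataclasses.asdict(m).items()
                                if k != "regions"
                            },
                            "regions": sorted(m.regions),
                        }
                        for m in p.mutations
                    ],
                }
                for p in self.patients
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str, config: SimulationConfig | None = None) -> "SyntheticTruth":
        payload = json.loads(text)
        patients = [
            PatientTruth(
                patient_id=p["patient_id"],
                regions=list(p["regions"]),
                mutations=[
                    TruthMutation(
                        **{**m, "regions": frozenset(m["regions"])}
                    )
                    for m in p["mutations"]
                ],
            )
            for p in payload["patients"]
        ]
        return cls(patients=patients, config=config or SimulationConfig())


# ---------------------------------------------------------------------------
# Bernoulli biopsy model (sampling-design validation)


def simulate_bernoulli_cohort(
    p_by_gene: Mapping[str, float],
    n_patients: int,
    biopsies_per_patient: int,
    seed: int,
    carrier_prob: float = 1.0,
) -> tuple[CohortData, dict[str, dict[str, bool]]]:
    """Cohort under the independent-biopsy detection model.

    Each patient is marked mutant per gene with probability ``carrier_prob``
    (default: every patient carries every gene's mutation); each biopsy of a
    mutant patient is positive independently with probability ``p_by_gene``.
    Returns the cohort (gene-level pseudo-mutations, one per positive gene
    per patient) and the carrier truth map ``{patient: {gene: mutant}}``.
    """
    if n_patients < 1 or biopsies_per_patient < 1:
        raise ValueError("n_patients and biopsies_per_patient must be >= 1")
    if not (0.0 <= carrier_prob <= 1.0):
        raise ValueError(f"carrier_prob must be in [0, 1], got {carrier_prob}")
    for gene, p in p_by_gene.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{gene}: probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    genes = list(p_by_gene)
    profiles = []
    truth: dict[str, dict[str, bool]] = {}
    width = len(str(n_patients))
    for i in range(n_patients):
        pid = f"S{i + 1:0{width}d}"
        regions = [f"R{j + 1}" for j in range(biopsies_per_patient)]
        truth[pid] = {}
        mutations = []
        rows = []
        for gene in genes:
            mutant = bool(rng.random() < carrier_prob)
            truth[pid][gene] = mutant
            if not mutant:
                continue
            hits = rng.random(biopsies_per_patient) < p_by_gene[gene]
            if hits.any():
                mutations.append(Mutation(gene, f"{gene}:detect", pid))
                rows.append(hits.astype(np.int8))
        presence = (
            np.vstack(rows) if rows else np.zeros((0, len(regions)), dtype=np.int8)
        )
        profile = TumorProfile(
            patient_id=pid, regions=regions, mutations=mutations, presence=presence
        )
        from .heterogeneity import classify_shared

        classify_shared(profile)
        profiles.append(profile)
    return CohortData(profiles=profiles, gene_panel=genes), truth


# ---------------------------------------------------------------------------
# clonal truth


def _laminar_blocks(k: int, rng: np.random.Generator) -> list[frozenset[int]]:
    """Proper sub-blocks of one random hierarchical partition of range(k).

    Regions are shuffled once, then the sequence is split recursively at
    random cut points; every emitted block is a node of the resulting
    partition tree, so the family is laminar by construction.
    """
    order = list(rng.permutation(k))
    blocks: list[frozenset[int]] = []

    def _split(seq: list[int]) -> None:
        if len(seq) < 2:
            return
        cut = int(rng.integers(1, len(seq)))
        left, right = seq[:cut], seq[cut:]
        blocks.append(frozenset(left))
        blocks.append(frozenset(right))
        _split(left)
        _split(right)

    _split(order)
    return blocks


def _draw_variant(
    gene: str,
    rng: np.random.Generator,
    used_positions: set[tuple[str, int]],
    consequence: str | None = None,
) -> tuple[str, int, str, str, str, bool]:
    chrom, lo, hi = GENE_LOCI[gene]
    while True:
        pos = int(rng.integers(lo, hi + 1))
        if (chrom, pos) not in used_positions:
            used_positions.add((chrom, pos))
            break
    if consequence is None:
        consequence = str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_P))
    is_indel = consequence in ("frameshift_indel", "inframe_indel")
    ref = str(rng.choice(_BASES))
    if is_indel:
        ins = "".join(rng.choice(_BASES, size=2 if consequence == "inframe_indel" else 1))
        alt = ref + ins
    else:
        alt = str(rng.choice([b for b in _BASES if b != ref]))
    return chrom, pos, ref, alt, consequence, is_indel


def simulate_tumor_truth(config: SimulationConfig, seed: int) -> SyntheticTruth:
    """Draw per-patient clonal ground truth under ``config``.

    Every patient gets a region count uniform over the configured range and,
    per panel gene, a truncal mutation (all regions) with the gene's truncal
    rate, else a subclonal mutation confined to a laminar block whose size
    best matches a fraction drawn from ``subclone_region_fraction``. With
    ``double_hit_rate`` a subclonal hit becomes two distinct mutations of
    the gene in disjoint blocks.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.biopsies_per_patient
    patients = []
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        regions = [f"R{j + 1}" for j in range(k)]
        blocks = _laminar_blocks(k, rng)
        used: set[tuple[str, int]] = set()
        mutations: list[TruthMutation] = []

        def _add(gene: str, idx_set: frozenset[int], classification: str) -> None:
            chrom, pos, ref, alt, consequence, is_indel = _draw_variant(gene, rng, used)
            mutations.append(
                TruthMutation(
                    gene=gene,
                    variant_key=f"{chrom}:{pos}:{ref}:{alt}",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    consequence=consequence,
                    is_indel=is_indel,
                    regions=frozenset(regions[j] for j in idx_set),
                    classification=classification,
                )
            )

        for gene in config.gene_panel:
            if rng.random() < config.truncal_rate_per_gene.get(gene, 0.0):
                _add(gene, frozenset(range(k)), "truncal")
            elif rng.random() < config.subclonal_rate_per_gene.get(gene, 0.0):
                if not blocks:  # single-region tumor has no proper subset
                    continue
                if config.double_hit_rate and rng.random() < config.double_hit_rate:
                    # two same-gene mutations in the two disjoint top blocks
                    sizes = sorted(blocks, key=len, reverse=True)
                    top = sizes[0]
                    disjoint = [b for b in blocks if not (b & top)]
                    if disjoint:
                        _add(gene, top, "subclonal")
                        _add(gene, disjoint[0], "subclonal")
                        continue
                frac = float(rng.uniform(*config.subclone_region_fraction))
                target = min(max(round(frac * k), 1), k - 1)
                best = min(abs(len(b) - target) for b in blocks)
                candidates = [b for b in blocks if abs(len(b) - target) == best]
                _add(gene, candidates[int(rng.integers(len(candidates)))], "subclonal")
        patients.append(PatientTruth(patient_id=pid, regions=regions, mutations=mutations))
    return SyntheticTruth(patients=patients, config=config)


# ---------------------------------------------------------------------------
# read-count layer


def _depth(rng: np.random.Generator, mean_depth: float) -> int:
    return max(1, int(rng.poisson(mean_depth)))


def simulate_variant_calls(
    truth: SyntheticTruth, config: SimulationConfig, seed: int
) -> list[VariantCall]:
    """Emit per-biopsy variant calls for a simulated cohort.

    For a biopsy inside a mutation's region-set the alt-read count is
    Binomial(depth, 0.5 x purity); outside it, Binomial(depth,
    sequencing_error_rate). A row is emitted only when at least one alt
    read is observed (a caller reports no zero-support sites). Decoy calls
    are injected at the configured rates; every decoy violates at least one
    inclusion rule by construction (dbSNP-flagged SNV, synonymous
    consequence, or VAF strictly below 5%).
    """
    rng = np.random.default_rng(seed)
    vaf_true = 0.5 * config.purity
    calls: list[VariantCall] = []
    for patient in truth.patients:
        used = {(m.chrom, m.pos) for m in patient.mutations}

        def _emit(region: str, chrom: str, pos: int, ref: str, alt: str,
                  gene: str, consequence: str, is_indel: bool, in_dbsnp: bool,
                  depth: int, alt_reads: int) -> None:
            if alt_reads >= 1:
                calls.append(
                    VariantCall(
                        patient_id=patient.patient_id,
                        region_id=region,
                        gene=gene,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        depth=depth,
                        alt_reads=alt_reads,
                        consequence=consequence,
                        in_dbsnp=in_dbsnp,
                        is_indel=is_indel,
                    )
                )

        # true somatic mutations
        for m in patient.mutations:
            for region in patient.regions:
                depth = _depth(rng, config.mean_depth)
                p = vaf_true if region in m.regions else config.sequencing_error_rate
                alt_reads = int(rng.binomial(depth, p)) if p > 0 else 0
                _emit(region, m.chrom, m.pos, m.ref, m.alt, m.gene,
                      m.consequence, m.is_indel, False, depth, alt_reads)

        # germline SNP decoys: present in every region at ~50% VAF
        for _ in range(int(rng.poisson(config.decoy_rates.germline_snp))):
            gene = str(rng.choice(config.gene_panel))
            chrom, pos, ref, alt, _, _ = _draw_variant(gene, rng, used, "missense")
            for region in patient.regions:
                depth = _depth(rng, config.mean_depth)
                _emit(region, chrom, pos, ref, alt, gene, "missense", False,
                      True, depth, int(rng.binomial(depth, 0.5)))

        # synonymous somatic decoys in a random nonempty region subset
        for _ in range(int(rng.poisson(config.decoy_rates.synonymous))):
            gene = str(rng.choice(config.gene_panel))
            chrom, pos, ref, alt, _, _ = _draw_variant(gene, rng, used, "missense")
            n_pos = int(rng.integers(1, len(patient.regions) + 1))
            hit = rng.choice(len(patient.regions), size=n_pos, replace=False)
            for j in hit:
                depth = _depth(rng, config.mean_depth)
                _emit(patient.regions[j], chrom, pos, ref, alt, gene,
                      "synonymous", False, False, depth,
                      int(rng.binomial(depth, vaf_true)))

        # sub-threshold artifacts, independent per biopsy, VAF < 5% guaranteed
        for region in patient.regions:
            for _ in range(int(rng.poisson(config.decoy_rates.subthreshold))):
                gene = str(rng.choice(config.gene_panel))
                chrom, pos, ref, alt, _, _ = _draw_variant(gene, rng, used, "missense")
                depth = _depth(rng, config.mean_depth)
                alt_max = int(np.ceil(0.05 * depth)) - 1
                if alt_max < 1:
                    continue  # cannot place a sub-threshold call at this depth
                _emit(region, chrom, pos, ref, alt, gene, "missense", False,
                      False, depth, int(rng.integers(1, alt_max + 1)))
    return calls


def regions_by_patient(truth: SyntheticTruth) -> dict[str, list[str]]:
    """Region declaration map needed to build profiles from calls."""
    return {p.patient_id: list(p.regions) for p in truth.patients}
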