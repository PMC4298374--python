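"""Inclusion/exclusion filtering of raw per-biopsy somatic variant calls.

A call is retained when all of the following hold:

* its consequence class is protein-altering (missense, nonsense, or an
  indel; synonymous and ``other`` calls are dropped),
* sequencing depth at the site is at least ``min_depth`` (default 10 reads),
* the variant allele fraction (alt reads / depth) is at least ``min_vaf``
  (default 5%, boundary inclusive),
* it is not a known germline SNP: single-base substitutions flagged in
  dbSNP are excluded, while indels are never dbSNP-filtered.

Excluded calls are tallied by the *first* failing rule in a fixed order
(consequence, depth, VAF, dbSNP, then the optional min-alt-reads QC rule)
so that tallies are reproducible regardless of call order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CONSEQUENCES",
    "PROTEIN_ALTERING",
    "VariantCall",
    "FilterConfig",
    "FilterResult",
    "filter_variants",
]

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel", "synonymous", "other"}
)
#: consequence classes eligible for inclusion
PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel"}
)

#: fixed attribution order for per-rule exclusion tallies
RULE_ORDER = ("consequence", "depth", "vaf", "dbsnp", "alt_reads")


@dataclass(frozen=True)
class VariantCall:
    """One raw called variant in one biopsy, with read-count evidence.

    Coordinates are 1-based as in VCF. ``consequence`` must be one of
    :data:`CONSEQUENCES`; ``is_indel`` marks insertions/deletions (which are
    exempt from dbSNP exclusion).
    """

    patient_id: str
    region_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    consequence: str
    in_dbsnp: bool = False
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(
                f"malformed call {self.variant_key}: alt_reads={self.alt_reads} "
                f"outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0.0 at zero depth."""
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def variant_key(self) -> str:
        """Identity used to collapse the same event across regions."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches of the inclusion filter.

    Thresholds are inclusive: ``vaf >= min_vaf`` and ``depth >= min_depth``
    are retained. ``min_alt_reads`` is an optional stricter QC knob,
    default 0 (off).
    """

    min_vaf: float = 0.05
    min_depth: int = 10
    exclude_dbsnp_snvs: bool = True
    exclude_synonymous: bool = True
    min_alt_reads: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError(f"min_vaf must be in [0, 1], got {self.min_vaf}")
        if self.min_depth < 0:
            raise ValueError(f"min_depth must be >= 0, got {self.min_depth}")
        if self.min_alt_reads < 0:
            raise ValueError(f"min_alt_reads must be >= 0, got {self.min_alt_reads}")


@dataclass
class FilterResult:
    retained: list[VariantCall]
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.tally.values())


def _first_failing_rule(call: VariantCall, config: FilterConfig) -> str | None:
    if call.consequence == "other":
        return "consequence"
    if call.consequence == "synonymous":
        if config.exclude_synonymous:
            return "consequence"
        # synonymous calls pass the consequence rule when the switch is off
    elif call.consequence not in PROTEIN_ALTERING:  # pragma: no cover - exhausted
        return "consequence"
    if call.depth < config.min_depth:
        return "depth"
    if call.vaf < config.min_vaf:
        return "vaf"
    if config.exclude_dbsnp_snvs and call.in_dbsnp and not call.is_indel:
        return "dbsnp"
    if call.alt_reads < config.min_alt_reads:
        return "alt_reads"
    return None


def filter_variants(
    calls: Iterable[VariantCall], config: FilterConfig | None = None
) -> FilterResult:
    """Apply the inclusion rules, returning retained calls and a per-rule tally.

    The tally maps rule name -> number of calls whose *first* failing rule it
    was (order: consequence, depth, vaf, dbsnp, alt_reads); retained count
    plus tally total always equals the input size. Filtering is idempotent.
    """
    config = config or FilterConfig()
    retained: list[VariantCall] = []
    tally: Counter[str] = Counter()
    for call in calls:
        rule = _first_failing_rule(call, config)
        if rule is None:
            retained.append(call)
        else:
            tally[rule] += 1
    return FilterResult(retained=retained, tally={r: tally[r] for r in RULE_ORDER if tally[r]})
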