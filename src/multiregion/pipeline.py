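"""End-to-end pipeline: filter -> matrices -> labels -> trees -> prevalence -> power.

``run_pipeline`` consumes either raw per-biopsy variant calls (a combined
TSV or a directory of per-biopsy VCFs) or pre-made presence matrices
(skipping the filter stage), and writes a report bundle: per-tumor presence
matrices, clone trees (Newick and DOT), cohort summary tables, prevalence
estimates, the detection-power table, and a JSON manifest with the resolved
configuration, seed, per-stage counters, and package version. Identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .biopsy_power import (
    estimate_prevalence,
    min_biopsies_for_gene_set,
    power_curve,
)
from .clonal_tree import build_clone_tree, classify_topology, render_tree
from .heterogeneity import (
    CohortData,
    TumorProfile,
    UndefinedRateError,
    build_cohort,
    cohort_frequencies,
    mutations_per_tumor,
    ubiquity_fraction,
)
from .io import read_calls_tsv, read_presence_tsv, read_vcf, write_presence_tsv
from .synthetic_cohort import GENE_PANEL
from .variant_filter import FilterConfig, filter_variants

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("multiregion")


class PipelineError(RuntimeError):
    """A stage failure, attributed to the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``calls_tsv``, ``vcf_dir`` or ``presence_dir`` must be
    set; ``regions_tsv`` (columns patient_id, region_id) declares biopsies
    with zero surviving calls and is required for TSV input when such
    biopsies exist (for VCF input every file declares its biopsy).
    """

    calls_tsv: str | None = None
    vcf_dir: str | None = None
    presence_dir: str | None = None
    regions_tsv: str | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    gene_panel: tuple[str, ...] = GENE_PANEL
    power_target: float = 0.90
    n_max: int = 10
    outdir: str = "results/pipeline"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.power_target < 1.0):
            raise ValueError(f"power target must be in (0, 1), got {self.power_target}")
        sources = [self.calls_tsv, self.vcf_dir, self.presence_dir]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one input source (calls_tsv | vcf_dir | presence_dir) required"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_panel"] = list(self.gene_panel)
        return d


def _ingest(config: PipelineConfig):
    """Load input; returns (calls or None, profiles or None, regions_by_patient)."""
    if config.presence_dir is not None:
        root = Path(config.presence_dir)
        files = sorted(root.glob("*.tsv"))
        if not files:
            raise PipelineError("ingest", f"no presence matrices (*.tsv) in {root}")
        profiles = [read_presence_tsv(f) for f in files]
        return None, profiles, None

    regions: dict[str, list[str]] = {}
    if config.vcf_dir is not None:
        root = Path(config.vcf_dir)
        files = sorted(root.glob("*.vcf"))
        if not files:
            raise PipelineError("ingest", f"no VCF files in {root}")
        calls = []
        for f in files:
            biopsy = read_vcf(f)
            pid, _, rid = f.stem.rpartition("_")
            regions.setdefault(pid, []).append(rid)
            calls.extend(biopsy)
    else:
        path = Path(config.calls_tsv)
        if not path.exists():
            raise PipelineError("ingest", f"call table {path} does not exist")
        calls = read_calls_tsv(path)
        for c in calls:
            if c.region_id not in regions.setdefault(c.patient_id, []):
                regions[c.patient_id].append(c.region_id)
    if config.regions_tsv is not None:
        decl = pd.read_csv(config.regions_tsv, sep="\t",
                           dtype={"patient_id": str, "region_id": str})
        regions = {}
        for row in decl.itertuples(index=False):
            regions.setdefault(row.patient_id, []).append(row.region_id)
    if not calls and not regions:
        raise PipelineError("ingest", "no calls and no declared regions")
    return calls, None, regions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle; returns the manifest."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "multiregion",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    calls, profiles, regions = _ingest(config)

    if calls is not None:
        result = filter_variants(calls, config.filter_config)
        manifest["stages"]["filter"] = {
            "n_input": len(calls),
            "n_retained": len(result.retained),
            "excluded_by_rule": result.tally,
        }
        logger.info("filter: %d in, %d retained, excluded %s",
                    len(calls), len(result.retained), result.tally)
        try:
            cohort = build_cohort(result.retained, regions, config.gene_panel)
        except ValueError as exc:
            raise PipelineError("profiles", str(exc)) from exc
    else:
        cohort = CohortData(profiles=profiles, gene_panel=list(config.gene_panel))
        manifest["stages"]["filter"] = {"skipped": "presence-matrix input"}

    profiles_dir = outdir / "profiles"
    trees_dir = outdir / "trees"
    profiles_dir.mkdir(exist_ok=True)
    trees_dir.mkdir(exist_ok=True)

    topology_rows = []
    for profile in cohort.profiles:
        write_presence_tsv(profile, profiles_dir / f"{profile.patient_id}.tsv")
        try:
            tree = build_clone_tree(profile)
        except ValueError as exc:
            raise PipelineError("trees", f"{profile.patient_id}: {exc}") from exc
        (trees_dir / f"{profile.patient_id}.nwk").write_text(render_tree(tree, "newick") + "\n")
        (trees_dir / f"{profile.patient_id}.dot").write_text(render_tree(tree, "dot"))
        topology_rows.append(
            {
                "patient_id": profile.patient_id,
                "n_regions": profile.n_regions,
                "n_mutations": len(profile.mutations),
                "n_shared": sum(1 for l in profile.labels if l == "shared"),
                "category": classify_topology(profile).value,
            }
        )
    topology = pd.DataFrame.from_records(topology_rows)
    topology.to_csv(outdir / "topology.tsv", sep="\t", index=False)
    manifest["stages"]["trees"] = {
        "n_tumors": len(topology_rows),
        "category_counts": topology["category"].value_counts().to_dict()
        if topology_rows
        else {},
    }

    try:
        freqs = cohort_frequencies(cohort)
    except ValueError as exc:
        raise PipelineError("summary", str(exc)) from exc
    freqs.to_csv(outdir / "gene_frequencies.tsv", sep="\t")
    hist = mutations_per_tumor(cohort)
    pd.Series(hist, name="n_tumors").rename_axis("n_mutations").to_csv(
        outdir / "mutations_per_tumor.tsv", sep="\t"
    )
    ubiquity_rows = []
    for gene in config.gene_panel:
        try:
            est = ubiquity_fraction(cohort, gene)
            ubiquity_rows.append(
                {"gene": gene, "n_ubiquitous": est.numerator,
                 "n_mutant_tumors": est.denominator, "fraction": est.value}
            )
        except UndefinedRateError:
            ubiquity_rows.append(
                {"gene": gene, "n_ubiquitous": 0, "n_mutant_tumors": 0,
                 "fraction": float("nan")}
            )
    pd.DataFrame.from_records(ubiquity_rows).to_csv(
        outdir / "ubiquity.tsv", sep="\t", index=False
    )
    manifest["stages"]["summary"] = {
        "mutations_per_tumor": {str(k): v for k, v in hist.items()},
    }

    prevalences: dict[str, float] = {}
    prevalence_rows = []
    for gene in config.gene_panel:
        try:
            est = estimate_prevalence(cohort, gene)
        except UndefinedRateError:
            continue
        prevalences[gene] = est.p
        prevalence_rows.append(dataclasses.asdict(est))
    pd.DataFrame.from_records(prevalence_rows).to_csv(
        outdir / "prevalence.tsv", sep="\t", index=False
    )
    if prevalences:
        curve = power_curve(prevalences, n_max=config.n_max)
        (outdir / "power_curve.tsv").write_text(curve.to_tsv())
        n_needed = min_biopsies_for_gene_set(prevalences, config.power_target)
    else:
        n_needed = None
    manifest["stages"]["power"] = {
        "prevalence": prevalences,
        "target": config.power_target,
        "min_biopsies_for_panel": n_needed,
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d tumors, outputs in %s", cohort.n_patients, outdir)
    return manifest
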