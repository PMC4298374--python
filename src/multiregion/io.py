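"""Readers and writers for the package's on-disk formats.

Variant calls travel either as VCF (one file per biopsy, sample named
``<patient>_R<k>``; depth and alt depth in the DP/AD genotype fields; gene,
consequence class, and dbSNP membership in the GENE/CONSEQ/DBSNP INFO
fields, since no annotation pipeline runs downstream of the caller here) or
as a flat TSV with a header row and columns exactly matching the
:class:`~multiregion.variant_filter.VariantCall` fields. Presence matrices
are TSV with one row per mutation: ``variant_key``, ``gene``, then one 0/1
column per region in declaration order.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .heterogeneity import Mutation, TumorProfile, classify_shared
from .variant_filter import VariantCall

__all__ = [
    "CALL_COLUMNS",
    "calls_to_frame",
    "frame_to_calls",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_vcf",
    "read_vcf",
    "write_presence_tsv",
    "read_presence_tsv",
]

CALL_COLUMNS = [
    "patient_id",
    "region_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "consequence",
    "in_dbsnp",
    "is_indel",
]

_CONTIG_LENGTHS = {"3": 198_022_430, "X": 155_270_560}


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    records = [
        {col: getattr(c, col) for col in CALL_COLUMNS} for c in calls
    ]
    df = pd.DataFrame.from_records(records, columns=CALL_COLUMNS)
    return df.astype({"pos": int, "depth": int, "alt_reads": int,
                      "in_dbsnp": bool, "is_indel": bool})


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    return [
        VariantCall(
            patient_id=str(row.patient_id),
            region_id=str(row.region_id),
            gene=str(row.gene),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            depth=int(row.depth),
            alt_reads=int(row.alt_reads),
            consequence=str(row.consequence),
            in_dbsnp=bool(row.in_dbsnp),
            is_indel=bool(row.is_indel),
        )
        for row in df.itertuples(index=False)
    ]


def write_calls_tsv(calls: Iterable[VariantCall], path: str | os.PathLike) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | os.PathLike) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str,
                                            "region_id": str})
    return frame_to_calls(df)


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(sample: str, contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig, length=_CONTIG_LENGTHS.get(contig))
    header.info.add("GENE", 1, "String", "Gene symbol of the targeted panel region")
    header.info.add("CONSEQ", 1, "String", "Consequence class of the variant")
    header.info.add("DBSNP", 0, "Flag", "Variant present in the germline SNP database")
    header.formats.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    return header


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | os.PathLike,
    patient_id: str | None = None,
    region_id: str | None = None,
) -> None:
    """Write the calls of one biopsy as a VCF with sample ``<patient>_<region>``.

    For a biopsy with no calls (a fully wild-type core is still a biopsy),
    ``patient_id`` and ``region_id`` must be given explicitly.
    """
    ids = {(c.patient_id, c.region_id) for c in calls}
    if patient_id is not None and region_id is not None:
        ids.add((patient_id, region_id))
    if len(ids) != 1:
        raise ValueError(
            f"one VCF per biopsy: got {sorted(ids) or 'no calls and no explicit ids'}"
        )
    patient_id, region_id = next(iter(ids))
    sample = f"{patient_id}_{region_id}"
    contigs = sorted({c.chrom for c in calls})
    header = _vcf_header(sample, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            rec = vcf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            rec.info["GENE"] = call.gene
            rec.info["CONSEQ"] = call.consequence
            if call.in_dbsnp:
                rec.info["DBSNP"] = True
            rec.samples[sample]["DP"] = call.depth
            rec.samples[sample]["AD"] = (call.depth - call.alt_reads, call.alt_reads)
            vcf.write(rec)


def read_vcf(path: str | os.PathLike) -> list[VariantCall]:
    """Read one biopsy's VCF back into calls.

    Patient and region are recovered from the sample name by splitting at
    the last underscore (``<patient>_R<k>``).
    """
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, got {samples}")
        sample = samples[0]
        patient_id, _, region_id = sample.rpartition("_")
        if not patient_id or not region_id:
            raise ValueError(f"{path}: sample name {sample!r} is not <patient>_<region>")
        for rec in vcf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            ref, alt = rec.alleles[0], rec.alleles[1]
            calls.append(
                VariantCall(
                    patient_id=patient_id,
                    region_id=region_id,
                    gene=str(rec.info.get("GENE", "")),
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    depth=int(fmt.get("DP")),
                    alt_reads=int(ad[1]),
                    consequence=str(rec.info.get("CONSEQ", "other")),
                    in_dbsnp=bool(rec.info.get("DBSNP", False)),
                    is_indel=len(ref) != len(alt),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# presence matrices


def write_presence_tsv(profile: TumorProfile, path: str | os.PathLike) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_presence_tsv(
    path: str | os.PathLike, patient_id: str | None = None
) -> TumorProfile:
    """Load a presence matrix; the patient id defaults to the file stem."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["variant_key", "gene"]:
        raise ValueError(f"{path}: first two columns must be variant_key, gene")
    regions = list(df.columns[2:])
    if not regions:
        raise ValueError(f"{path}: no region columns")
    pid = patient_id if patient_id is not None else Path(path).stem
    presence = df[regions].to_numpy(dtype=np.int8)
    profile = TumorProfile(
        patient_id=pid,
        regions=regions,
        mutations=[
            Mutation(gene=str(g), variant_key=str(k), patient_id=pid)
            for k, g in zip(df["variant_key"], df["gene"])
        ],
        presence=presence,
    )
    profile.validate()
    classify_shared(profile)
    return profile
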