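"""Readers for somatic SNV lists in VCF, TSV and multi-sample MAF formats.

All formats funnel into a single record model (:class:`SNVRecord`) with
1-based positions and single-base canonical ref/alt alleles.  Non-SNV rows
(indels, MNVs, symbolic alleles) are skipped and tallied per reason in a
:class:`ReadReport`, never silently dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

__all__ = [
    "SNVRecord",
    "ReadReport",
    "read_vcf",
    "read_tsv",
    "read_maf",
    "check_against_reference",
    "normalize_chrom",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single canonical bases: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt: {self}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1: {self}")


@dataclass
class ReadReport:
    """Row accounting for one read operation: parsed = accepted + skipped."""

    n_parsed: int = 0
    n_accepted: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)

    def skip(self, reason: str) -> None:
        self.n_parsed += 1
        self.n_skipped += 1
        self.skip_reasons[reason] += 1

    def accept(self) -> None:
        self.n_parsed += 1
        self.n_accepted += 1


def _classify_allele_pair(ref: str, alt: str) -> str | None:
    """Skip reason for a REF/ALT pair, or None if it is a valid SNV."""
    if len(ref) != 1 or len(alt) != 1:
        return "not a single base"
    if ref not in _BASES or alt not in _BASES:
        return "non-canonical base"
    if ref == alt:
        return "ref==alt"
    return None


def read_vcf(path, sample_id: str, pass_only: bool = False):
    """Read one sample's somatic SNVs from a VCF 4.x file.

    Multi-allelic ALT fields are split into one record per alternate allele;
    each REF/ALT pair is counted as one parsed row.  ``pass_only`` restricts
    to rows whose FILTER is PASS or missing; by default FILTER is ignored.

    Returns ``(records, report)``.
    """
    path = str(path)
    report = ReadReport()
    records: list[SNVRecord] = []
    seen: set[tuple] = set()
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for row in vcf:
            if pass_only and row.filter.keys() not in ([], ["PASS"]):
                for _ in row.alts or (None,):
                    report.skip("filtered (not PASS)")
                continue
            alts = row.alts or ()
            if not alts:
                report.skip("no ALT allele")
                continue
            for alt in alts:
                ref = (row.ref or "").upper()
                alt = (alt or "").upper()
                reason = _classify_allele_pair(ref, alt)
                if reason is not None:
                    report.skip(reason)
                    continue
                key = (row.chrom, row.pos, ref, alt)
                if key in seen:
                    report.skip("duplicate variant")
                    continue
                seen.add(key)
                records.append(SNVRecord(sample_id, row.chrom, row.pos, ref, alt))
                report.accept()
    return records, report


def read_tsv(path, sample_id: str):
    """Read SNVs from a headered TSV with chrom/pos/ref/alt columns.

    Column names are matched case-insensitively; ``chromosome`` and
    ``position`` synonyms are accepted, in any column order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    synonyms = {
        "chrom": ("chrom", "chromosome", "chr"),
        "pos": ("pos", "position"),
        "ref": ("ref", "reference", "reference_allele"),
        "alt": ("alt", "alternative", "alternate", "alt_allele"),
    }
    lower = {c.lower(): c for c in df.columns}
    colmap = {}
    for canon, names in synonyms.items():
        found = next((lower[n] for n in names if n in lower), None)
        if found is None:
            raise ValueError(
                f"{path}: missing column {canon!r}; accepted names: {list(names)}"
            )
        colmap[canon] = found
    report = ReadReport()
    records: list[SNVRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        ref = str(row[colmap["ref"]]).upper()
        alt = str(row[colmap["alt"]]).upper()
        reason = _classify_allele_pair(ref, alt)
        if reason is not None:
            report.skip(reason)
            continue
        try:
            pos = int(row[colmap["pos"]])
        except (TypeError, ValueError):
            report.skip("non-integer position")
            continue
        if pos < 1:
            report.skip("position < 1")
            continue
        key = (str(row[colmap["chrom"]]), pos, ref, alt)
        if key in seen:
            report.skip("duplicate variant")
            continue
        seen.add(key)
        records.append(SNVRecord(sample_id, str(row[colmap["chrom"]]), pos, ref, alt))
        report.accept()
    return records, report


_MAF_REQUIRED = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
    "Variant_Type",
)


def read_maf(path):
    """Read a multi-sample MAF (GDC dialect), keeping Variant_Type == SNP rows.

    Extra columns (e.g. a full MuTect2 export) are ignored.  Returns
    ``(mapping sample_id -> records, report)``; the report pools all samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF column(s) {missing}")
    report = ReadReport()
    by_sample: dict[str, list[SNVRecord]] = {}
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        if str(row["Variant_Type"]).upper() != "SNP":
            report.skip(f"variant type {row['Variant_Type']}")
            continue
        ref = str(row["Reference_Allele"]).upper()
        alt = str(row["Tumor_Seq_Allele2"]).upper()
        reason = _classify_allele_pair(ref, alt)
        if reason is not None:
            report.skip(reason)
            continue
        try:
            pos = int(row["Start_Position"])
        except (TypeError, ValueError):
            report.skip("non-integer position")
            continue
        sample = str(row["Tumor_Sample_Barcode"])
        key = (sample, str(row["Chromosome"]), pos, ref, alt)
        if key in seen:
            report.skip("duplicate variant")
            continue
        seen.add(key)
        by_sample.setdefault(sample, []).append(
            SNVRecord(sample, str(row["Chromosome"]), pos, ref, alt)
        )
        report.accept()
    return by_sample, report


def normalize_chrom(chrom: str, available) -> str | None:
    """Resolve a chromosome name against a reference's contig names.

    Tries the name as-is, with the ``chr`` prefix stripped/added, and the
    MT <-> chrM alias.  Returns the matching contig name or None.
    """
    available = set(available)
    candidates = [chrom]
    if chrom.startswith("chr"):
        candidates.append(chrom[3:])
    else:
        candidates.append("chr" + chrom)
    aliases = {"MT": "chrM", "chrM": "MT", "M": "chrM", "chrMT": "chrM"}
    if chrom in aliases:
        candidates.append(aliases[chrom])
    for cand in candidates:
        if cand in available:
            return cand
    return None


def check_against_reference(records, reference: Fasta):
    """Split records into (accepted, rejected) by reference-base agreement.

    A record is accepted iff the reference base at its position equals its
    ref allele (case-insensitive), after chromosome-name normalization.
    Mismatches are rejected with the observed base; an unresolvable
    chromosome raises.
    """
    contigs = set(reference.keys())
    accepted: list[SNVRecord] = []
    rejected: list[tuple[SNVRecord, str]] = []
    for rec in records:
        chrom = normalize_chrom(rec.chrom, contigs)
        if chrom is None:
            raise KeyError(
                f"chromosome {rec.chrom!r} not found in reference "
                f"(contigs: {sorted(contigs)[:5]}...)"
            )
        contig = reference[chrom]
        if rec.pos > len(contig):
            rejected.append((rec, f"position {rec.pos} beyond contig end"))
            continue
        observed = str(contig[rec.pos - 1]).upper()
        if observed == rec.ref:
            if chrom == rec.chrom:
                accepted.append(rec)
            else:
                accepted.append(
                    SNVRecord(rec.sample_id, chrom, rec.pos, rec.ref, rec.alt)
                )
        else:
            reason = f"reference mismatch: expected {rec.ref}, genome has {observed}"
            rejected.append((rec, reason))
            logger.warning("%s at %s:%d dropped (%s)", rec.sample_id, rec.chrom, rec.pos, reason)
    return accepted, rejected
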