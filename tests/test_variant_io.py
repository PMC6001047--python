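"""SNV readers (VCF/TSV/MAF), reference checking, and row accounting."""

import pandas as pd
import pytest
from pyfaidx import Fasta

from mutsig96 import (
    SNVRecord,
    build_profile,
    check_against_reference,
    read_maf,
    read_tsv,
    read_vcf,
)
from mutsig96.variant_io import normalize_chrom
from conftest import write_vcf


def _base_at(reference, pos):
    contig = list(reference.keys())[0]
    return contig, str(reference[contig][pos - 1]).upper()


def _snv_rows(reference, positions):
    """(pos, ref, alt) rows that agree with the reference sequence."""
    rows = []
    for pos in positions:
        _, ref = _base_at(reference, pos)
        alt = next(b for b in "ACGT" if b != ref)
        rows.append((pos, ref, alt))
    return rows


class TestReadVcf:
    def test_snvs_kept_indels_skipped(self, tmp_path, reference):
        rows = _snv_rows(reference, [100, 200, 300])
        rows.append((400, "C", "CA"))  # insertion
        path = write_vcf(tmp_path / "a.vcf", rows)
        records, report = read_vcf(path, "s1")
        assert len(records) == 3
        assert (report.n_parsed, report.n_accepted, report.n_skipped) == (4, 3, 1)
        assert report.skip_reasons["not a single base"] == 1

    def test_multiallelic_alt_split(self, tmp_path, reference):
        contig, ref = _base_at(reference, 150)
        alts = ",".join(b for b in "ACGT" if b != ref)[:3]  # two alts "X,Y"
        path = write_vcf(tmp_path / "m.vcf", [(150, ref, alts)])
        records, report = read_vcf(path, "s1")
        assert len(records) == 2
        assert {r.alt for r in records} == set(alts.split(","))
        assert all(r.pos == 150 and r.ref == ref for r in records)

    def test_header_only_vcf(self, tmp_path):
        path = write_vcf(tmp_path / "empty.vcf", [])
        records, report = read_vcf(path, "s1")
        assert records == [] and report.n_parsed == 0

    def test_pass_only_filtering(self, tmp_path, reference):
        rows = _snv_rows(reference, [100, 200])
        rows = [rows[0] + ("PASS",), rows[1] + ("germline_risk",)]
        path = write_vcf(tmp_path / "f.vcf", rows)
        assert len(read_vcf(path, "s1")[0]) == 2  # FILTER ignored by default
        records, report = read_vcf(path, "s1", pass_only=True)
        assert len(records) == 1
        assert report.skip_reasons["filtered (not PASS)"] == 1

    def test_duplicate_rows_counted_once(self, tmp_path, reference):
        rows = _snv_rows(reference, [100]) * 2
        path = write_vcf(tmp_path / "d.vcf", rows)
        records, report = read_vcf(path, "s1")
        assert len(records) == 1
        assert report.skip_reasons["duplicate variant"] == 1


class TestReadTsv:
    def test_basic_rows(self, tmp_path):
        path = tmp_path / "a.tsv"
        df = pd.DataFrame(
            {"chrom": ["1"] * 5, "pos": range(100, 105),
             "ref": list("CCTTC"), "alt": list("AGGCA")}
        )
        df.to_csv(path, sep="\t", index=False)
        records, report = read_tsv(path, "s1")
        assert len(records) == 5 and report.n_skipped == 0

    def test_multibase_ref_skipped(self, tmp_path):
        path = tmp_path / "b.tsv"
        pd.DataFrame(
            {"chrom": ["1"], "pos": [100], "ref": ["AT"], "alt": ["A"]}
        ).to_csv(path, sep="\t", index=False)
        records, report = read_tsv(path, "s1")
        assert records == []
        assert report.skip_reasons["not a single base"] == 1

    def test_column_order_and_synonyms_irrelevant(self, tmp_path):
        canonical, scrambled = tmp_path / "c.tsv", tmp_path / "d.tsv"
        df = pd.DataFrame(
            {"chrom": ["1", "2"], "pos": [5, 7], "ref": ["C", "T"], "alt": ["A", "G"]}
        )
        df.to_csv(canonical, sep="\t", index=False)
        df.rename(columns={"chrom": "Chromosome", "pos": "Position"})[
            ["alt", "Position", "ref", "Chromosome"]
        ].to_csv(scrambled, sep="\t", index=False)
        assert read_tsv(canonical, "s1")[0] == read_tsv(scrambled, "s1")[0]

    def test_missing_header_names_synonyms(self, tmp_path):
        path = tmp_path / "e.tsv"
        pd.DataFrame({"chrom": ["1"], "pos": [5], "ref": ["C"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="alt"):
            read_tsv(path, "s1")


def _maf_frame(rows, extra_cols=False):
    df = pd.DataFrame(
        rows,
        columns=["Chromosome", "Start_Position", "Reference_Allele",
                 "Tumor_Seq_Allele2", "Tumor_Sample_Barcode", "Variant_Type"],
    )
    if extra_cols:  # MuTect2-export-like superset
        df["Hugo_Symbol"] = "GENE"
        df["t_depth"] = 100
        df["FILTER"] = "PASS"
    return df


class TestReadMaf:
    def test_groups_by_barcode_and_filters_variant_type(self, tmp_path):
        rows = [
            ("1", 100, "C", "A", "TCGA-01", "SNP"),
            ("1", 200, "T", "G", "TCGA-01", "SNP"),
            ("2", 300, "C", "T", "TCGA-02", "snp"),
            ("2", 400, "CA", "-", "TCGA-02", "DEL"),
        ]
        path = tmp_path / "a.maf"
        _maf_frame(rows).to_csv(path, sep="\t", index=False)
        by_sample, report = read_maf(path)
        assert set(by_sample) == {"TCGA-01", "TCGA-02"}
        assert sum(len(v) for v in by_sample.values()) == 3
        assert report.n_skipped == 1

    def test_ref_equals_alt_skipped(self, tmp_path):
        path = tmp_path / "b.maf"
        _maf_frame([("1", 100, "C", "C", "TCGA-01", "SNP")]).to_csv(
            path, sep="\t", index=False
        )
        by_sample, report = read_maf(path)
        assert by_sample == {}
        assert report.skip_reasons["ref==alt"] == 1

    def test_column_superset_parses(self, tmp_path):
        path = tmp_path / "c.maf"
        _maf_frame([("1", 100, "C", "A", "TCGA-01", "SNP")], extra_cols=True).to_csv(
            path, sep="\t", index=False
        )
        by_sample, _ = read_maf(path)
        assert by_sample["TCGA-01"][0] == SNVRecord("TCGA-01", "1", 100, "C", "A")

    def test_missing_required_column_named(self, tmp_path):
        path = tmp_path / "d.maf"
        _maf_frame([("1", 100, "C", "A", "TCGA-01", "SNP")]).drop(
            columns="Variant_Type"
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="Variant_Type"):
            read_maf(path)


class TestReferenceCheck:
    def test_matching_base_accepted_mismatch_rejected(self, reference):
        contig, ref = _base_at(reference, 500)
        alt = next(b for b in "ACGT" if b != ref)
        wrong_ref = next(b for b in "ACGT" if b not in (ref, alt))
        good = SNVRecord("s", contig, 500, ref, alt)
        bad = SNVRecord("s", contig, 501, wrong_ref, alt if alt != wrong_ref else ref)
        accepted, rejected = check_against_reference([good, bad], reference)
        assert accepted == [good]
        assert len(rejected) == 1 and "expected" in rejected[0][1]

    def test_chr_prefix_normalization(self, reference):
        contig, ref = _base_at(reference, 500)  # contig is "chrS"
        alt = next(b for b in "ACGT" if b != ref)
        rec = SNVRecord("s", contig.removeprefix("chr"), 500, ref, alt)
        accepted, rejected = check_against_reference([rec], reference)
        assert len(accepted) == 1 and accepted[0].chrom == contig

    def test_unknown_chromosome_raises(self, reference):
        rec = SNVRecord("s", "chr99", 10, "C", "A")
        with pytest.raises(KeyError, match="chr99"):
            check_against_reference([rec], reference)

    def test_mt_alias(self):
        assert normalize_chrom("MT", {"chrM", "chr1"}) == "chrM"
        assert normalize_chrom("chrM", {"MT", "1"}) == "MT"


class TestFormatEquivalence:
    def test_same_mutations_via_vcf_tsv_maf_give_identical_profiles(
        self, tmp_path, reference, reference_path
    ):
        positions = [120, 340, 560, 780, 1200, 3400]
        rows = _snv_rows(reference, positions)
        contig = list(reference.keys())[0]

        vcf_path = write_vcf(tmp_path / "s.vcf", rows)
        vcf_records, _ = read_vcf(vcf_path, "s1")

        tsv_path = tmp_path / "s.tsv"
        pd.DataFrame(
            [{"chrom": contig, "pos": p, "ref": r, "alt": a} for p, r, a in rows]
        ).to_csv(tsv_path, sep="\t", index=False)
        tsv_records, _ = read_tsv(tsv_path, "s1")

        maf_path = tmp_path / "s.maf"
        _maf_frame(
            [(contig, p, r, a, "s1", "SNP") for p, r, a in rows]
        ).to_csv(maf_path, sep="\t", index=False)
        maf_records = read_maf(maf_path)[0]["s1"]

        assert set(vcf_records) == set(tsv_records) == set(maf_records)
        profiles = [
            build_profile(check_against_reference(recs, reference)[0], reference)[0]
            for recs in (vcf_records, tsv_records, maf_records)
        ]
        assert (profiles[0].counts == profiles[1].counts).all()
        assert (profiles[0].counts == profiles[2].counts).all()
        assert profiles[0].total == len(positions)

    def test_conservation_invariant_across_readers(self, tmp_path, reference):
        rows = _snv_rows(reference, [100, 200]) + [(300, "C", "CAT"), (400, "N", "A")]
        path = write_vcf(tmp_path / "cons.vcf", rows)
        _, report = read_vcf(path, "s1")
        assert report.n_parsed == report.n_accepted + report.n_skipped
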