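"""VCF and table I/O: splitting rules, skip counters, round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recurvar import (
    AnnotationRecord,
    VariantKey,
    read_annotation_table,
    read_panel,
    read_reference_af_table,
    read_sample_vcf,
    read_variant_table,
    write_variant_table,
)
from recurvar.model import chrom_sort_key

from conftest import write_vcf


class TestReadSampleVcf:
    def test_biallelic_snv_field_mapping(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", [("chr1", 100, "G", "A", 250, "0/1", (20, 15), 35)])
        result = read_sample_vcf(path)
        assert len(result) == 1
        key, call = result.pairs[0]
        assert key == VariantKey("chr1", 100, "G", "A")
        assert call.qual == 250 and call.dp == 35 and call.ad == (20, 15)
        assert call.gt_alleles == (0, 1) and call.sample_id == "S01"

    def test_multiallelic_record_splits_per_alt(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", [("chr1", 500, "G", "A,T", 300, "1/2", (5, 12, 13), 30)])
        result = read_sample_vcf(path)
        assert [k.alt for k, _ in result.pairs] == ["A", "T"]
        (k1, c1), (k2, c2) = result.pairs
        assert (k1.chrom, k1.pos, k1.ref) == (k2.chrom, k2.pos, k2.ref)
        # full AD preserved on both halves; alt_index distinguishes them
        assert c1.ad == c2.ad == (5, 12, 13)
        assert (c1.alt_index, c2.alt_index) == (1, 2)
        assert c1.carries_alt() and c2.carries_alt()

    def test_symbolic_alts_skipped_and_counted(self, tmp_path):
        rows = [
            ("chr1", 100, "G", "A", 200, "0/1", (10, 10), 20),
            ("chr1", 200, "C", "T", 200, "0/1", (10, 10), 20),
            ("chr1", 300, "T", "<NON_REF>", 200, "0/1", (10, 10), 20),
            ("chr1", 400, "A", "G", 200, "0/1", (10, 10), 20),
            ("chr1", 500, "G", "C", 200, "0/1", (10, 10), 20),
        ]
        result = read_sample_vcf(write_vcf(tmp_path / "s.vcf", rows))
        assert len(result.pairs) == 4
        assert result.n_symbolic_skipped == 1

    def test_split_conserves_alt_count(self, tmp_path):
        rows = [
            ("chr1", 100, "G", "A", 200, "0/1", (10, 10), 20),
            ("chr1", 200, "C", "T,G,A", 200, "1/2", (5, 5, 5, 5), 20),
            ("chr2", 300, "T", "C,*", 200, "0/1", (10, 5, 5), 20),
        ]
        result = read_sample_vcf(write_vcf(tmp_path / "s.vcf", rows))
        assert len(result.pairs) == 1 + 3 + 1  # '*' is excluded
        assert result.n_symbolic_skipped == 1

    def test_missing_sample_is_fatal(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", [("chr1", 100, "G", "A", 200, "0/1", (10, 10), 20)])
        with pytest.raises(ValueError, match="not in header"):
            read_sample_vcf(path, "NOPE")

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises((FileNotFoundError, OSError)):
            read_sample_vcf(str(tmp_path / "absent.vcf"))


class TestAnnotationTable:
    def _write(self, tmp_path, rows, columns):
        path = tmp_path / "ann.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return str(path)

    BASE_COLS = [
        "Chr", "Start", "Ref", "Alt", "Func.refGene", "Gene.refGene", "ExonicFunc.refGene",
        "SIFT_pred", "Polyphen2_HDIV_pred", "Polyphen2_HVAR_pred", "LRT_pred",
        "MutationTaster_pred", "MutationAssessor_pred", "FATHMM_pred",
        "MetaSVM_pred", "MetaLR_pred", "SnpEff_impact",
        "1000g2015aug_all", "gnomAD_genome_ALL", "Epi25_AF",
    ]

    def _row(self, **over):
        base = {
            "Chr": "chr1", "Start": 100, "Ref": "G", "Alt": "A",
            "Func.refGene": "exonic", "Gene.refGene": "GENE1",
            "ExonicFunc.refGene": "nonsynonymous SNV",
            "SIFT_pred": ".", "Polyphen2_HDIV_pred": ".", "Polyphen2_HVAR_pred": ".",
            "LRT_pred": ".", "MutationTaster_pred": ".", "MutationAssessor_pred": ".",
            "FATHMM_pred": ".", "MetaSVM_pred": ".", "MetaLR_pred": ".",
            "SnpEff_impact": "MODERATE",
            "1000g2015aug_all": ".", "gnomAD_genome_ALL": ".", "Epi25_AF": ".",
        }
        base.update(over)
        return base

    def test_single_predictor_call_kept_verbatim(self, tmp_path):
        path = self._write(tmp_path, [self._row(SIFT_pred="D")], self.BASE_COLS)
        (rec,) = read_annotation_table(path)
        non_missing = [c for c in rec.predictor_calls.values() if c != "."]
        assert non_missing == ["D"]
        assert len(rec.predictor_calls) == 9

    def test_reference_af_parsed(self, tmp_path):
        path = self._write(tmp_path, [self._row(gnomAD_genome_ALL="0.4132")], self.BASE_COLS)
        (rec,) = read_annotation_table(path)
        assert rec.ref_afs == {"gnomad": 0.4132}

    def test_missing_afs_yield_empty_mapping(self, tmp_path):
        rows = [self._row(Start=100 + i, **{"1000g2015aug_all": "0.1"}) for i in range(8)]
        rows += [self._row(Start=900 + i) for i in range(2)]
        path = self._write(tmp_path, rows, self.BASE_COLS)
        records = read_annotation_table(path)
        assert len(records) == 10
        assert sum(1 for r in records if not r.ref_afs) == 2

    def test_unparsable_af_becomes_missing(self, tmp_path):
        path = self._write(tmp_path, [self._row(Epi25_AF="n/a")], self.BASE_COLS)
        (rec,) = read_annotation_table(path)
        assert "epi25" not in rec.ref_afs

    def test_unmapped_mandatory_column_is_fatal(self, tmp_path):
        cols = [c for c in self.BASE_COLS if c != "Func.refGene"]
        row = {k: v for k, v in self._row().items() if k != "Func.refGene"}
        path = self._write(tmp_path, [row], cols)
        with pytest.raises(ValueError, match="mandatory column"):
            read_annotation_table(path)


class TestVariantTable:
    def test_empty_frame_writes_header_only(self, tmp_path):
        path = str(tmp_path / "out.tsv")
        write_variant_table(pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]), path)
        with open(path) as fh:
            lines = fh.read().splitlines()
        assert lines == ["chrom\tpos\tref\talt"]

    def test_natural_chromosome_order(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["chr2", "chr10", "chr1"], "pos": [5, 5, 5], "ref": ["A"] * 3, "alt": ["T"] * 3}
        )
        path = str(tmp_path / "out.tsv")
        write_variant_table(df, path)
        assert list(read_variant_table(path)["chrom"]) == ["chr1", "chr2", "chr10"]

    def test_round_trip_identity_on_random_records(self, tmp_path):
        rng = np.random.default_rng(42)
        chroms = [f"chr{c}" for c in rng.choice(["1", "2", "10", "X"], size=50)]
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": rng.choice(np.arange(1, 10_000), size=50, replace=False),
                "ref": rng.choice(list("ACGT"), size=50),
                "alt": rng.choice(list("ACGT"), size=50),
                "gene": [f"G{i}" for i in range(50)],
                "votes": rng.integers(0, 10, size=50),
            }
        )
        path = str(tmp_path / "out.tsv")
        write_variant_table(df, path)
        back = read_variant_table(path)
        expected = df.iloc[
            df.apply(lambda r: (chrom_sort_key(r["chrom"]), r["pos"], r["ref"], r["alt"]), axis=1)
            .argsort(kind="stable")
            .to_numpy()
        ].reset_index(drop=True)
        pd.testing.assert_frame_equal(back, expected, check_dtype=False)

    def test_rewrite_is_idempotent(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["chr2", "chr1"], "pos": [7, 9], "ref": ["A", "C"], "alt": ["G", "T"]}
        )
        p1, p2 = str(tmp_path / "a.tsv"), str(tmp_path / "b.tsv")
        write_variant_table(df, p1)
        write_variant_table(read_variant_table(p1), p2)
        assert open(p1).read() == open(p2).read()


def test_read_panel_skips_comments_and_blanks(tmp_path):
    path = tmp_path / "panel.txt"
    path.write_text("# header\nSCN1A\n\nVDR  # trailing comment\n  KMT2C\n")
    assert read_panel(str(path)) == ["SCN1A", "VDR", "KMT2C"]


def test_reference_af_table_round_trip(tmp_path):
    path = tmp_path / "ref.tsv"
    pd.DataFrame(
        {"chrom": ["chr1"], "pos": [10], "ref": ["A"], "alt": ["T"], "af": [0.25]}
    ).to_csv(path, sep="\t", index=False)
    assert read_reference_af_table(str(path)) == {VariantKey("chr1", 10, "A", "T"): 0.25}
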