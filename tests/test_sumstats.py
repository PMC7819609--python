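"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pytest

from neurotarget.sumstats import (
    HarmonizeAction,
    SumstatsFormatError,
    harmonize,
    read_ld_matrix,
    read_ld_triplets,
    read_sumstats,
    write_ld_matrix,
    write_sumstats,
)
from neurotarget.synth import simulate_ld

from conftest import make_record, random_records


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -0.01},
            {"eaf": 1.2},
            {"eaf": -0.1},
            {"ea": "A", "oa": "A"},
            {"p": 0.0},
            {"p": 1.5},
            {"n": 0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_record(**kwargs)

    def test_z_and_maf(self):
        rec = make_record(beta=0.1, se=0.02, eaf=0.7)
        assert rec.z == pytest.approx(5.0)
        assert rec.maf == pytest.approx(0.3)


class TestTsvRoundTrip:
    def test_three_row_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "chrom\tpos\trsid\tea\toa\teaf\tbeta\tse\tp\tn\n"
            "1\t100\trs1\tA\tG\t0.3\t0.1\t0.02\t1e-6\t1000\n"
            "1\t200\trs2\tC\tT\t0.5\t-0.2\t0.05\t1e-4\t1000\n"
            "2\t300\trs3\tA\tC\t0.1\t0.0\t0.01\t1.0\t1000\n"
        )
        records = read_sumstats(path)
        assert len(records) == 3
        assert records[0].variant_id == "rs1"
        assert records[1].beta == -0.2

    def test_zero_se_row_rejected_with_warning(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "chrom\tpos\trsid\tea\toa\teaf\tbeta\tse\tp\tn\n"
            "1\t100\trs1\tA\tG\t0.3\t0.1\t0.02\t1e-6\t1000\n"
            "1\t200\trs2\tC\tT\t0.5\t0.2\t0\t1e-4\t1000\n"
            "2\t300\trs3\tA\tC\t0.1\t0.1\t0.01\t1e-8\t1000\n"
        )
        with pytest.warns(UserWarning, match="line 3"):
            records = read_sumstats(path)
        assert [r.variant_id for r in records] == ["rs1", "rs3"]

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("chrom\tpos\trsid\tea\toa\teaf\tbeta\tp\tn\n")
        with pytest.raises(SumstatsFormatError, match="se"):
            read_sumstats(path)

    def test_study_n_fallback(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "chrom\tpos\trsid\tea\toa\teaf\tbeta\tse\tp\n"
            "1\t100\trs1\tA\tG\t0.3\t0.1\t0.02\t1e-6\n"
        )
        assert read_sumstats(path, study_n=1286)[0].n == 1286
        with pytest.raises(SumstatsFormatError):
            read_sumstats(path)

    def test_write_read_is_identity(self, tmp_path, rng):
        records = random_records(rng, 25)
        path = tmp_path / "rt.tsv"
        write_sumstats(records, path)
        assert read_sumstats(path) == records
        # fixed point: a second round trip writes byte-identical content
        path2 = tmp_path / "rt2.tsv"
        write_sumstats(read_sumstats(path), path2)
        assert path.read_text() == path2.read_text()

    def test_custom_dialect(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "CHR\tBP\tSNP\tA1\tA2\tFRQ\tB\tSE\tP\tN\n"
            "1\t100\trs1\ta\tg\t0.3\t0.1\t0.02\t1e-6\t1000\n"
        )
        dialect = {
            "chrom": "CHR", "pos": "BP", "variant_id": "SNP",
            "effect_allele": "A1", "other_allele": "A2", "eaf": "FRQ",
            "beta": "B", "se": "SE", "p": "P", "n": "N",
        }
        rec = read_sumstats(path, dialect)[0]
        assert rec.effect_allele == "A"  # upper-cased


class TestLdIo:
    def test_matrix_round_trip(self, tmp_path):
        ld, _ = simulate_ld(5, 0.8, seed=1)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r_matrix, ld.r_matrix, atol=1e-12)

    def test_triplet_densification(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("rsA\trsB\t0.5\nrsA\trsC\t-0.2\n")
        ld = read_ld_triplets(path)
        assert ld.r("rsA", "rsB") == 0.5
        assert ld.r("rsB", "rsA") == 0.5
        assert ld.r("rsB", "rsC") == 0.0
        assert ld.r("rsC", "rsC") == 1.0

    def test_asymmetric_matrix_rejected(self):
        from neurotarget.sumstats import LdReference

        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            LdReference(["a", "b"], bad)


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        e = make_record(ea="A", oa="G", beta=0.2)
        o = make_record(ea="A", oa="G", beta=0.1, trait_id="disease")
        pair = harmonize(e, o)
        assert pair.action_taken is HarmonizeAction.UNCHANGED
        assert pair.outcome.beta == 0.1

    def test_swapped_alleles_sign_flip(self):
        e = make_record(ea="A", oa="G", eaf=0.3, beta=0.2)
        o = make_record(ea="G", oa="A", eaf=0.7, beta=0.1, trait_id="disease")
        pair = harmonize(e, o)
        assert pair.action_taken is HarmonizeAction.SIGN_FLIPPED
        assert pair.outcome.beta == pytest.approx(-0.1)
        assert pair.outcome.eaf == pytest.approx(0.3)
        assert pair.outcome.effect_allele == "A"

    def test_strand_complement_resolved(self):
        e = make_record(ea="A", oa="G", eaf=0.3, beta=0.2)
        o = make_record(ea="T", oa="C", eaf=0.3, beta=0.1, trait_id="disease")
        pair = harmonize(e, o)
        assert pair.action_taken is HarmonizeAction.STRAND_FLIPPED
        assert pair.outcome.beta == 0.1
        assert pair.outcome.effect_allele == "A"

    def test_palindromic_near_half_dropped(self):
        e = make_record(ea="A", oa="T", eaf=0.50)
        o = make_record(ea="A", oa="T", eaf=0.30, trait_id="disease")
        assert harmonize(e, o, 0.08).action_taken is HarmonizeAction.DROPPED_PALINDROMIC

    def test_palindromic_inferred_by_frequency(self):
        e = make_record(ea="A", oa="T", eaf=0.10, beta=0.2)
        o = make_record(ea="A", oa="T", eaf=0.88, beta=0.1, trait_id="disease")
        pair = harmonize(e, o, 0.08)
        assert pair.action_taken is HarmonizeAction.SIGN_FLIPPED
        assert pair.outcome.beta == pytest.approx(-0.1)

    def test_irreconcilable_alleles_dropped(self):
        e = make_record(ea="A", oa="G")
        o = make_record(ea="A", oa="C", trait_id="disease")
        assert harmonize(e, o).action_taken is HarmonizeAction.DROPPED_UNMATCHED

    def test_different_variants_error(self):
        with pytest.raises(ValueError):
            harmonize(make_record(variant_id="rs1"), make_record(variant_id="rs2"))

    def test_idempotent(self, rng):
        for e, o in zip(random_records(rng, 40), random_records(rng, 40, "disease")):
            pair = harmonize(e, o)
            if pair.dropped:
                continue
            again = harmonize(e, pair.outcome)
            assert again.action_taken is HarmonizeAction.UNCHANGED
            assert again.outcome == pair.outcome

    def test_double_sign_flip_restores(self, rng):
        from dataclasses import replace

        from neurotarget.sumstats import _sign_flip

        for rec in random_records(rng, 30):
            back = _sign_flip(_sign_flip(rec))
            # beta negation and allele swap are exact; eaf goes through
            # 1-(1-x), which is within one ulp of x
            assert back.eaf == pytest.approx(rec.eaf, abs=1e-15)
            assert replace(back, eaf=rec.eaf) == rec
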