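"""Summary-statistic IO and allele harmonization."""
import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate.errors import ConfigurationError, DataError
from mrmediate.gwas_io import (SummaryStatRecord, flip_record, harmonize,
                               read_summary_stats, write_summary_stats)

from conftest import make_record


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        records = [
            make_record("rs1", "A", "G", eaf=0.25, beta=0.12, se=0.03),
            make_record("rs2", "C", "T", eaf=0.4, beta=-0.05, se=0.01),
            make_record("rs3", "G", "A", eaf=0.1, beta=0.0, se=0.02),
        ]
        path = tmp_path / "stats.tsv"
        write_summary_stats(records, path)
        result = read_summary_stats(path)
        assert len(result.records) == 3
        assert not result.rejects
        for orig, back in zip(records, result.records):
            assert back.variant_id == orig.variant_id
            assert back.effect_allele == orig.effect_allele
            assert back.eaf == pytest.approx(orig.eaf)
            assert back.beta == pytest.approx(orig.beta)
            assert back.se == pytest.approx(orig.se)

    def test_eaf_out_of_range_rejected_with_reason(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n"
            "rs2\tA\tG\t1.2\t0.1\t0.02\t1e-6\t5000\n"
        )
        result = read_summary_stats(path)
        assert len(result.records) == 1
        assert len(result.rejects) == 1
        assert result.rejects[0].line == 2
        assert "eaf out of range" in result.rejects[0].reason

    def test_unparsable_numeric_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\tA\tG\t0.3\tnot_a_number\t0.02\t1e-6\t5000\n"
        )
        result = read_summary_stats(path)
        assert not result.records
        assert result.rejects[0].line == 1
        assert "unparsable" in result.rejects[0].reason

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tEA\tOA\tEAF\tBETA\tSE\tP\nrs1\tA\tG\t0.3\t0.1\t0.02\t1e-6\n")
        with pytest.raises(ConfigurationError, match="n"):
            read_summary_stats(path)

    def test_column_map_resolves_nonstandard_headers(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text(
            "marker\tallele_eff\tallele_other\tfrq\tlogOR\tstderr_logOR\tp_assoc\tsize\n"
            "rs9\tT\tC\t0.2\t0.3\t0.1\t0.0027\t800\n"
        )
        result = read_summary_stats(path, column_map={
            "variant_id": "marker", "effect_allele": "allele_eff",
            "other_allele": "allele_other", "eaf": "frq", "beta": "logOR",
            "se": "stderr_logOR", "pval": "p_assoc", "n": "size",
        })
        assert result.records[0].variant_id == "rs9"

    def test_generator_output_round_trips_with_full_count(self, tmp_path):
        from mrmediate.synthetic import TripletConfig, simulate_triplet

        data = simulate_triplet(TripletConfig(n_snps_exposure=25, n_null_snps=15,
                                              n_snps_mediator=0, seed=3))
        path = tmp_path / "exp.tsv"
        write_summary_stats(data.exposure, path)
        result = read_summary_stats(path)
        assert len(result.records) == 40
        assert not result.rejects

    def test_pval_inconsistency_is_warning_not_rejection(self, tmp_path):
        path = tmp_path / "warn.tsv"
        path.write_text(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\tA\tG\t0.3\t0.5\t0.02\t0.9\t5000\n"  # |z|=25 but p=0.9
        )
        result = read_summary_stats(path)
        assert len(result.records) == 1
        assert result.warnings and "inconsistent" in result.warnings[0]


class TestHarmonize:
    def test_same_orientation_kept(self):
        exp = [make_record("rs1", "A", "G", beta=0.1)]
        out = [make_record("rs1", "A", "G", beta=-0.2, eaf=0.35)]
        (pair,) = harmonize(exp, out)
        assert pair.action == "kept"
        assert pair.beta_out == pytest.approx(-0.2)
        assert pair.eaf_out == pytest.approx(0.35)

    def test_swapped_alleles_flipped_with_sign_and_frequency(self):
        exp = [make_record("rs1", "A", "G", beta=0.1)]
        out = [make_record("rs1", "G", "A", beta=-0.2, eaf=0.35)]
        (pair,) = harmonize(exp, out)
        assert pair.action == "flipped"
        assert pair.beta_out == pytest.approx(0.2)
        assert pair.eaf_out == pytest.approx(0.65)
        assert pair.effect_allele == "A"

    def test_strand_complement_resolved_before_incompatibility(self):
        # T/C on the other strand reads A/G: complement, then align
        exp = [make_record("rs1", "A", "G", beta=0.1)]
        out = [make_record("rs1", "T", "C", beta=0.15, eaf=0.4)]
        (pair,) = harmonize(exp, out)
        assert pair.action == "kept"
        assert pair.beta_out == pytest.approx(0.15)

    def test_palindromic_dropped_by_default(self):
        exp = [make_record("rs1", "A", "T", beta=0.1)]
        out = [make_record("rs1", "A", "T", beta=0.1)]
        (pair,) = harmonize(exp, out)
        assert pair.action == "dropped"
        assert pair.drop_reason == "palindromic"

    def test_palindromic_kept_outside_eaf_window_when_enabled(self):
        exp = [make_record("rs1", "A", "T", beta=0.1, eaf=0.1)]
        out = [make_record("rs1", "A", "T", beta=0.2, eaf=0.12)]
        (pair,) = harmonize(exp, out, drop_all_palindromic=False)
        assert pair.action in ("kept", "flipped")
        exp2 = [make_record("rs2", "A", "T", beta=0.1, eaf=0.5)]
        out2 = [make_record("rs2", "A", "T", beta=0.2, eaf=0.5)]
        (pair2,) = harmonize(exp2, out2, drop_all_palindromic=False)
        assert pair2.drop_reason == "palindromic"

    def test_incompatible_alleles_dropped(self):
        exp = [make_record("rs1", "A", "G", beta=0.1)]
        out = [make_record("rs1", "A", "C", beta=0.1)]
        (pair,) = harmonize(exp, out)
        assert pair.drop_reason == "incompatible_alleles"

    def test_missing_in_outcome(self):
        exp = [make_record("rs1"), make_record("rs2")]
        out = [make_record("rs1")]
        pairs = harmonize(exp, out)
        assert pairs[1].drop_reason == "missing_in_outcome"

    def test_duplicate_variant_id_is_data_error(self):
        exp = [make_record("rs1"), make_record("rs1")]
        with pytest.raises(DataError, match="duplicate"):
            harmonize(exp, [make_record("rs1")])

    def test_count_conservation_and_drop_reason_iff_dropped(self):
        exp = [
            make_record("rs1", "A", "G"),
            make_record("rs2", "A", "T"),
            make_record("rs3", "C", "A"),
            make_record("rs4", "G", "T"),
        ]
        out = [
            make_record("rs1", "G", "A"),
            make_record("rs2", "A", "T"),
            make_record("rs3", "C", "A"),
        ]
        pairs = harmonize(exp, out)
        assert len(pairs) == len(exp)
        for p in pairs:
            assert (p.action == "dropped") == (p.drop_reason is not None)

    def test_idempotent_on_already_harmonized_pairs(self):
        exp = [make_record("rs1", "A", "G", beta=0.1),
               make_record("rs2", "C", "T", beta=-0.3, eaf=0.2)]
        out = [make_record("rs1", "G", "A", beta=-0.2, eaf=0.3),
               make_record("rs2", "C", "T", beta=0.4, eaf=0.25)]
        first = harmonize(exp, out)
        # rebuild outcome records as aligned by the first pass
        realigned = [
            dataclasses.replace(e, beta=p.beta_out, se=p.se_out, eaf=p.eaf_out)
            for e, p in zip(exp, first)
        ]
        second = harmonize(exp, realigned)
        for p1, p2 in zip(first, second):
            assert p2.action == "kept"
            assert p2.beta_out == pytest.approx(p1.beta_out)
            assert p2.eaf_out == pytest.approx(p1.eaf_out)


@given(
    beta=st.floats(-2, 2, allow_nan=False),
    eaf=st.floats(0.01, 0.99),
    ea=st.sampled_from("ACGT"),
)
def test_flip_is_involution(beta, eaf, ea):
    oa = {"A": "G", "C": "T", "G": "A", "T": "C"}[ea]
    rec = make_record("rs1", ea, oa, eaf=eaf, beta=beta)
    twice = flip_record(flip_record(rec))
    assert twice.effect_allele == rec.effect_allele
    assert twice.other_allele == rec.other_allele
    assert twice.beta == pytest.approx(rec.beta)
    assert twice.eaf == pytest.approx(rec.eaf)
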