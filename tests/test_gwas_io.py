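"""Summary-statistic IO and allele harmonisation."""

import numpy as np
import pytest

from summarymr import gwas_io, synthetic_data
from summarymr.gwas_io import ConfigurationError, Dialect, harmonise
from summarymr.types import LDMatrix, ValidationError, VariantAssociation


def _write(tmp_path, text, name="sumstats.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


WELL_FORMED = """SNP A1 A2 freq b se p N
rs1 A G 0.3 0.10 0.01 1e-10 50000
rs2 t c 0.5 -0.05 0.02 1e-9 50000
rs3 C G 0.1 0.02 0.005 0.04 50000
"""


class TestReadGwasSummary:
    def test_well_formed_table_preserves_rows_and_order(self, tmp_path):
        records, rejected = gwas_io.read_gwas_summary(_write(tmp_path, WELL_FORMED))
        assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]
        assert rejected == []
        assert records[0].beta == pytest.approx(0.10)
        assert records[0].n == 50000

    def test_alleles_are_uppercased(self, tmp_path):
        records, _ = gwas_io.read_gwas_summary(_write(tmp_path, WELL_FORMED))
        assert records[1].alleles == ("T", "C")

    def test_invalid_row_rejected_with_row_index(self, tmp_path):
        bad = WELL_FORMED + "rs4 A G 0.3 0.1 0.0 1e-10 50000\n"
        records, rejected = gwas_io.read_gwas_summary(
            _write(tmp_path, bad), on_invalid="report"
        )
        assert [r.snp_id for r in records] == ["rs1", "rs2", "rs3"]
        assert len(rejected) == 1
        idx, reason = rejected[0]
        assert idx == 3 and "se" in reason

    def test_invalid_rows_raise_by_default(self, tmp_path):
        bad = WELL_FORMED + "rs4 A G 0.3 0.1 notanumber 1e-10 50000\n"
        with pytest.raises(ValidationError, match="row 3"):
            gwas_io.read_gwas_summary(_write(tmp_path, bad))

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, "SNP A1 A2 freq se p N\nrs1 A G 0.3 0.01 1e-10 50000\n")
        with pytest.raises(ConfigurationError, match="b"):
            gwas_io.read_gwas_summary(path)

    def test_dialect_remaps_column_names(self, tmp_path):
        path = _write(
            tmp_path,
            "rsid ea oa beta stderr pval\nrs1 A G 0.1 0.01 1e-10\n",
        )
        dialect = Dialect(
            snp_id="rsid", effect_allele="ea", other_allele="oa",
            beta="beta", se="stderr", pvalue="pval", eaf=None, n=None,
        )
        records, _ = gwas_io.read_gwas_summary(path, dialect)
        assert records[0].snp_id == "rs1" and records[0].eaf is None

    def test_write_read_round_trip_is_exact(self, tmp_path):
        study = synthetic_data.simulate_two_sample(
            synthetic_data.SimulationConfig(n_snps=12, seed=5)
        )
        path = tmp_path / "rt.tsv"
        gwas_io.write_gwas_summary(study.exposure, path)
        records, _ = gwas_io.read_gwas_summary(path)
        assert records == study.exposure


class TestReadLDMatrix:
    def test_identity_matrix(self, tmp_path):
        path = _write(tmp_path, "\ts1\ts2\ns1\t1\t0\ns2\t0\t1\n", "ld.tsv")
        ld = gwas_io.read_ld_matrix(path)
        assert ld.snp_ids == ["s1", "s2"]
        assert ld.r2("s1", "s2") == 0.0

    def test_symmetric_offdiagonal_accepted(self, tmp_path):
        path = _write(tmp_path, "\ts1\ts2\ns1\t1\t0.7\ns2\t0.7\t1\n", "ld.tsv")
        ld = gwas_io.read_ld_matrix(path)
        assert ld.r("s1", "s2") == pytest.approx(0.7)

    def test_asymmetric_matrix_rejected(self, tmp_path):
        path = _write(tmp_path, "\ts1\ts2\ns1\t1\t0.7\ns2\t0.2\t1\n", "ld.tsv")
        with pytest.raises(ValidationError, match="asymmetric"):
            gwas_io.read_ld_matrix(path)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValidationError, match="exceeds 1"):
            LDMatrix(["s1", "s2"], np.array([[1.0, 1.5], [1.5, 1.0]]))

    def test_nonsquare_rejected(self, tmp_path):
        path = _write(tmp_path, "\ts1\ts2\ts3\ns1\t1\t0\t0\ns2\t0\t1\t0\n", "ld.tsv")
        with pytest.raises(ValidationError):
            gwas_io.read_ld_matrix(path)

    def test_ld_round_trip(self, tmp_path):
        study = synthetic_data.simulate_two_sample(
            synthetic_data.SimulationConfig(n_snps=6, ld_blocks=((3, 0.5), (3, 0.2)), seed=2)
        )
        path = tmp_path / "ld.tsv"
        gwas_io.write_ld_matrix(study.ld, path)
        back = gwas_io.read_ld_matrix(path)
        assert back.snp_ids == study.ld.snp_ids
        np.testing.assert_allclose(back.r_matrix, study.ld.r_matrix, atol=1e-12)


class TestHarmonise:
    def test_same_alleles_keep_outcome_effect(self, make_record):
        exp = [make_record("rs1", beta=0.1)]
        out = [make_record("rs1", beta=0.05, se=0.02)]
        instruments, excluded = harmonise(exp, out)
        assert excluded == []
        assert instruments[0].b_zy == pytest.approx(0.05)
        assert instruments[0].b_xy == pytest.approx(0.5)

    def test_swapped_alleles_flip_sign(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="G", beta=0.1)]
        out = [make_record("rs1", effect_allele="G", other_allele="A", beta=0.05, eaf=0.7)]
        instruments, _ = harmonise(exp, out)
        assert instruments[0].b_zy == pytest.approx(-0.05)

    def test_strand_flip_resolved_by_complementing(self, make_record):
        # exposure A/G; outcome reported on the other strand as T/C
        exp = [make_record("rs1", effect_allele="A", other_allele="G", beta=0.1)]
        out = [make_record("rs1", effect_allele="T", other_allele="C", beta=0.05)]
        instruments, _ = harmonise(exp, out)
        assert instruments[0].b_zy == pytest.approx(0.05)

    def test_missing_outcome_snp_excluded_with_reason(self, make_record):
        exp = [make_record("rs1"), make_record("rs1530559")]
        out = [make_record("rs1", beta=0.05)]
        instruments, excluded = harmonise(exp, out)
        assert [i.snp_id for i in instruments] == ["rs1"]
        assert excluded[0].snp_id == "rs1530559"
        assert "missing" in excluded[0].reason

    def test_irreconcilable_alleles_dropped(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="G")]
        out = [make_record("rs1", effect_allele="A", other_allele="C", beta=0.05)]
        instruments, excluded = harmonise(exp, out)
        assert instruments == []
        assert excluded[0].reason == "allele mismatch"

    def test_palindromic_resolved_by_concordant_frequency(self, make_record):
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.22, beta=0.05)]
        instruments, _ = harmonise(exp, out)
        assert instruments[0].b_zy == pytest.approx(0.05)

    def test_palindromic_other_strand_inferred_from_frequency(self, make_record):
        # outcome labels the same variant from the opposite strand: its
        # "A" is the exposure's "T", betrayed by the mirrored frequency
        exp = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)]
        out = [make_record("rs1", effect_allele="A", other_allele="T", eaf=0.81, beta=0.05)]
        instruments, _ = harmonise(exp, out)
        assert instruments[0].b_zy == pytest.approx(-0.05)
        assert instruments[0].b_xy == pytest.approx(-0.5)

    @pytest.mark.parametrize("eaf_exp,eaf_out", [(0.45, 0.45), (0.2, None)])
    def test_palindromic_uninformative_frequency_dropped(self, make_record, eaf_exp, eaf_out):
        exp = [make_record("rs1", effect_allele="C", other_allele="G", eaf=eaf_exp)]
        out = [make_record("rs1", effect_allele="C", other_allele="G", eaf=eaf_out, beta=0.05)]
        instruments, excluded = harmonise(exp, out)
        assert instruments == []
        assert "palindromic" in excluded[0].reason

    def test_harmonise_is_idempotent(self, make_record):
        exp = [make_record("rs1", beta=0.1)]
        out = [make_record("rs1", effect_allele="G", other_allele="A", beta=0.05, eaf=0.7)]
        first, _ = harmonise(exp, out)
        # re-express the harmonised outcome as association records and redo
        realigned = [
            VariantAssociation(
                snp_id=i.snp_id,
                effect_allele=exp[0].effect_allele,
                other_allele=exp[0].other_allele,
                beta=i.b_zy,
                se=i.se_zy,
                pvalue=i.p_zy,
                eaf=exp[0].eaf,
            )
            for i in first
        ]
        second, _ = harmonise(exp, realigned)
        assert second == first

    def test_flipping_every_outcome_record_leaves_ratios_unchanged(self):
        study = synthetic_data.simulate_two_sample(
            synthetic_data.SimulationConfig(n_snps=15, true_b_xy=0.3, seed=7)
        )
        base, _ = harmonise(study.exposure, study.outcome)
        flipped_outcome = [gwas_io._flip(r) for r in study.outcome]
        flipped, _ = harmonise(study.exposure, flipped_outcome)
        assert [i.b_xy for i in flipped] == pytest.approx([i.b_xy for i in base])
        assert [i.se_xy for i in flipped] == pytest.approx([i.se_xy for i in base])
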