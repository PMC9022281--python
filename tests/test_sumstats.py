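"""Summary-statistic records: I/O round trips, conversions, harmonization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triangulate.config import ConfigurationError
from triangulate.sumstats import (
    GwasRecord,
    HarmonizationDrop,
    QtlRecord,
    ValidationError,
    Variant,
    harmonize,
    or_ci_from_beta,
    p_from_z,
    read_summary_table,
    write_summary_table,
    z_from_p,
)


def make_variant(id="rs1", a1="A", a2="G", pos=100):
    return Variant(id=id, chrom="1", pos=pos, effect_allele=a1, other_allele=a2)


class TestVariant:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValidationError):
            make_variant(a1="A", a2="A")

    def test_rejects_non_acgt(self):
        with pytest.raises(ValidationError, match="non-ACGT"):
            make_variant(a1="AT")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValidationError):
            make_variant(pos=0)


class TestConversions:
    def test_p_from_z_zero(self):
        assert p_from_z(0.0) == 1.0

    def test_p_from_z_reference_quantile(self):
        assert p_from_z(1.959964) == pytest.approx(0.05, abs=5e-7)

    def test_p_from_z_stable_in_far_tail(self):
        p37 = p_from_z(37.0)
        assert 0 < p37 < 1e-290
        assert p_from_z(37.0, log=True) == pytest.approx(math.log(p37), rel=1e-9)
        # log-space tail keeps decreasing far beyond double underflow
        assert p_from_z(60.0, log=True) < p_from_z(37.0, log=True)

    @given(st.floats(0.01, 36.0), st.floats(0.01, 1.0))
    def test_p_from_z_strictly_decreasing(self, z, dz):
        assert p_from_z(z + dz) < p_from_z(z)

    @given(st.floats(1e-10, 1.0, exclude_min=True))
    def test_z_p_round_trip(self, p):
        assert p_from_z(z_from_p(p)) == pytest.approx(p, rel=1e-9)

    def test_or_ci_null_effect_symmetric(self):
        odds, lo, hi = or_ci_from_beta(0.0, 0.1)
        assert odds == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_or_ci_rejects_bad_se(self):
        with pytest.raises(ValidationError):
            or_ci_from_beta(0.1, 0.0)


class TestRecords:
    def test_z_recomputed_from_beta_se(self):
        rec = GwasRecord(variant=make_variant(), beta=0.639, se=0.150)
        assert rec.z == pytest.approx(4.26, abs=1e-12)
        assert rec.p == pytest.approx(p_from_z(4.26))

    def test_inconsistent_z_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            GwasRecord(variant=make_variant(), beta=0.5, se=0.1, z=-5.0)

    def test_inconsistent_p_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            GwasRecord(variant=make_variant(), beta=0.5, se=0.1, p=0.9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            QtlRecord(gene_id="G", variant=make_variant(), beta=0.1, se=-1.0)


class TestTableIo:
    def _write(self, path, lines):
        path.write_text("\n".join(["\t".join(map(str, l)) for l in lines]) + "\n")

    HEADER = ["SNP", "CHR", "POS", "A1", "A2", "FRQ", "BETA", "SE", "Z", "P", "N"]

    def test_well_formed_rows_round_trip(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        self._write(
            f,
            [
                self.HEADER,
                ["rs1", "1", "100", "A", "G", "0.3", "0.2", "0.1", "2.0", str(p_from_z(2.0)), "5000"],
                ["rs2", "1", "200", "C", "T", "0.4", "-0.1", "0.05", "-2.0", str(p_from_z(2.0)), "5000"],
                ["rs3", "2", "300", "G", "C", "0.25", "0.0", "0.2", "0.0", "1.0", "5000"],
            ],
        )
        result = read_summary_table(f)
        assert len(result.records) == 3 and not result.errors
        out = tmp_path / "out.tsv"
        write_summary_table(result.records, out)
        again = read_summary_table(out).records
        for a, b in zip(result.records, again):
            for field in ("beta", "se", "z", "p", "eaf"):
                assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)
            assert a.variant == b.variant and a.n == b.n

    def test_missing_z_and_p_recomputed(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        self._write(
            f,
            [
                ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE"],
                ["rs1", "1", "100", "A", "G", "0.639", "0.150"],
            ],
        )
        (rec,) = read_summary_table(f).records
        assert rec.z == pytest.approx(4.26)
        assert rec.p == pytest.approx(p_from_z(4.26))

    def test_bad_allele_reported_with_row_index(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        self._write(
            f,
            [
                ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE"],
                ["rs1", "1", "100", "A", "G", "0.2", "0.1"],
                ["rs2", "1", "200", "AT", "G", "0.2", "0.1"],
            ],
        )
        result = read_summary_table(f)
        assert len(result.records) == 1
        assert len(result.errors) == 1
        assert result.errors[0].row == 1
        assert "non-ACGT" in result.errors[0].message

    def test_missing_required_column_raises(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        self._write(f, [["SNP", "CHR", "POS", "A1", "BETA"], ["rs1", "1", "1", "A", "0.1"]])
        with pytest.raises(ConfigurationError, match="required column"):
            read_summary_table(f)

    def test_gene_column_yields_qtl_records(self, tmp_path):
        f = tmp_path / "qtl.tsv"
        self._write(
            f,
            [
                ["GENE", "SNP", "CHR", "POS", "A1", "A2", "BETA", "SE"],
                ["G1", "rs1", "1", "100", "A", "G", "0.5", "0.1"],
            ],
        )
        (rec,) = read_summary_table(f).records
        assert isinstance(rec, QtlRecord) and rec.gene_id == "G1"

    def test_custom_layout_mapping(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        self._write(
            f,
            [
                ["variant", "chrom", "bp", "ea", "oa", "b", "stderr"],
                ["rs1", "1", "100", "A", "G", "0.2", "0.1"],
            ],
        )
        layout = {"id": "variant", "chrom": "chrom", "pos": "bp", "effect_allele": "ea",
                  "other_allele": "oa", "beta": "b", "se": "stderr"}
        assert len(read_summary_table(f, layout).records) == 1


def qtl(a1="A", a2="G", beta=0.2, eaf=0.3, id="rs1"):
    return QtlRecord(gene_id="G", variant=make_variant(id=id, a1=a1, a2=a2),
                     beta=beta, se=0.05, eaf=eaf, n=1000)


def gwas(a1="A", a2="G", beta=0.1, eaf=0.3, id="rs1"):
    return GwasRecord(variant=make_variant(id=id, a1=a1, a2=a2),
                      beta=beta, se=0.05, eaf=eaf, n=1000)


class TestHarmonize:
    def test_matching_alleles_no_op(self):
        e, o = harmonize(qtl(), gwas())
        assert o == gwas()

    def test_swapped_alleles_flip_sign_and_eaf(self):
        e, o = harmonize(qtl(a1="A", a2="G", beta=0.2), gwas(a1="G", a2="A", beta=-0.15, eaf=0.7))
        assert o.beta == pytest.approx(0.15)
        assert o.eaf == pytest.approx(0.3)
        assert o.variant.effect_allele == "A"

    def test_strand_complement_matches_unchanged(self):
        e, o = harmonize(qtl(a1="A", a2="G"), gwas(a1="T", a2="C", beta=0.3))
        assert o.beta == pytest.approx(0.3)
        assert o.variant.effect_allele == "A"

    def test_strand_complement_swapped_flips(self):
        e, o = harmonize(qtl(a1="A", a2="G"), gwas(a1="C", a2="T", beta=0.3, eaf=0.6))
        assert o.beta == pytest.approx(-0.3)
        assert o.eaf == pytest.approx(0.4)

    def test_palindrome_with_intermediate_eaf_dropped(self):
        drop = harmonize(qtl(a1="A", a2="T", eaf=0.50), gwas(a1="A", a2="T", eaf=0.2))
        assert isinstance(drop, HarmonizationDrop)
        assert drop.reason == "ambiguous palindrome"

    def test_palindrome_concordant_freq_kept(self):
        e, o = harmonize(qtl(a1="A", a2="T", eaf=0.2), gwas(a1="A", a2="T", beta=0.1, eaf=0.25))
        assert o.beta == pytest.approx(0.1)

    def test_palindrome_discordant_freq_flips(self):
        e, o = harmonize(qtl(a1="C", a2="G", eaf=0.2), gwas(a1="C", a2="G", beta=0.1, eaf=0.8))
        assert o.beta == pytest.approx(-0.1)
        assert o.eaf == pytest.approx(0.2)

    def test_irreconcilable_alleles_dropped(self):
        drop = harmonize(qtl(a1="A", a2="G"), gwas(a1="A", a2="C"))
        assert isinstance(drop, HarmonizationDrop)
        assert drop.reason == "allele mismatch"

    @given(
        a=st.sampled_from([("A", "G"), ("A", "C"), ("T", "G"), ("A", "T"), ("C", "G")]),
        swap=st.booleans(),
        complement=st.booleans(),
        eaf_e=st.floats(0.05, 0.95),
        eaf_o=st.floats(0.05, 0.95),
        beta=st.floats(-1.0, 1.0),
    )
    def test_harmonize_is_idempotent(self, a, swap, complement, eaf_e, eaf_o, beta):
        from triangulate.sumstats import COMPLEMENT

        a1, a2 = a
        o1, o2 = (a2, a1) if swap else (a1, a2)
        if complement:
            o1, o2 = COMPLEMENT[o1], COMPLEMENT[o2]
        exposure = qtl(a1=a1, a2=a2, eaf=eaf_e)
        outcome = gwas(a1=o1, a2=o2, beta=beta, eaf=eaf_o)
        first = harmonize(exposure, outcome)
        if isinstance(first, HarmonizationDrop):
            return
        again = harmonize(first[0], first[1])
        assert not isinstance(again, HarmonizationDrop)
        assert again[1] == first[1]
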