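"""Instrument selection, clumping, Wald/IVW estimation, Steiger filtering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triangulate.ld import LdMatrix
from triangulate.mr import (
    Instrument,
    MrError,
    ivw,
    ld_clump,
    mr_gene_screen,
    select_instruments,
    steiger_test,
    wald_ratio,
)
from triangulate.simulate import ScenarioSpec, simulate_locus, spawn_seeds
from triangulate.sumstats import QtlRecord, Variant


def qtl_at(id, p, gene="G"):
    z = -float(__import__("scipy").stats.norm.ppf(p / 2))
    return QtlRecord(gene_id=gene, variant=Variant(id, "1", 100, "A", "G"),
                     beta=z * 0.05, se=0.05, n=1000)


class TestSelect:
    def test_threshold_is_strict(self):
        records = [qtl_at("rs1", 1e-9), qtl_at("rs2", 1e-7), qtl_at("rs3", 1e-4)]
        kept = select_instruments(records)
        assert [r.variant.id for r in kept] == ["rs1"]

    def test_nothing_significant_gives_empty_list(self):
        assert select_instruments([qtl_at("rs1", 1e-4)]) == []

    def test_ties_ordered_by_variant_id(self):
        records = [qtl_at("rsB", 1e-9), qtl_at("rsA", 1e-9)]
        kept = select_instruments(records)
        assert [r.variant.id for r in kept] == ["rsA", "rsB"]


def ld_from_r2(ids, r2):
    n = len(ids)
    r = np.eye(n)
    for (i, j), v in r2.items():
        r[i, j] = r[j, i] = math.sqrt(v)
    return LdMatrix(ids, r)


class TestClump:
    def test_hand_run_greedy_example(self):
        # index rs1 removes rs2 (r2=0.5); rs3 (r2=1e-4) survives
        records = [qtl_at("rs1", 1e-10), qtl_at("rs2", 1e-9), qtl_at("rs3", 1e-8)]
        ld = ld_from_r2(["rs1", "rs2", "rs3"], {(0, 1): 0.5, (0, 2): 0.0001, (1, 2): 0.0001})
        kept = ld_clump(records, ld)
        assert [r.variant.id for r in kept] == ["rs1", "rs3"]

    def test_independent_snps_all_retained(self):
        records = [qtl_at(f"rs{i}", 10**-(9 + i)) for i in range(4)]
        kept = ld_clump(records, ld_from_r2([f"rs{i}" for i in range(4)], {}))
        assert len(kept) == 4

    def test_perfect_ld_keeps_only_strongest(self):
        ids = ["rs1", "rs2", "rs3"]
        ld = LdMatrix(ids, np.ones((3, 3)))
        records = [qtl_at("rs2", 1e-9), qtl_at("rs1", 1e-12), qtl_at("rs3", 1e-8)]
        kept = ld_clump(records, ld)
        assert [r.variant.id for r in kept] == ["rs1"]

    def test_result_invariant_to_input_order(self):
        ids = [f"rs{i}" for i in range(5)]
        ld = ld_from_r2(ids, {(0, 1): 0.3, (2, 3): 0.9, (1, 4): 0.002})
        records = [qtl_at(ids[i], p) for i, p in enumerate([1e-9, 1e-10, 1e-11, 1e-8, 1e-12])]
        forward = [r.variant.id for r in ld_clump(records, ld)]
        backward = [r.variant.id for r in ld_clump(records[::-1], ld)]
        assert forward == backward

    def test_candidate_missing_from_ld_is_named(self):
        with pytest.raises(Exception, match="rs9"):
            ld_clump([qtl_at("rs9", 1e-9)], ld_from_r2(["rs1"], {}))


class TestWald:
    def test_exact_division(self):
        beta, se = wald_ratio(Instrument("rs1", 0.5, 0.05, 0.25, 0.05))
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_sign_follows_exposure(self):
        beta, _ = wald_ratio(Instrument("rs1", -0.5, 0.05, 0.25, 0.05))
        assert beta == pytest.approx(-0.5)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MrError, match="beta_exp"):
            wald_ratio(Instrument("rs1", 0.0, 0.05, 0.25, 0.05))

    def test_first_order_se_close_to_second_order_for_strong_instruments(self):
        # |beta_exp/se_exp| > 10: the exposure-uncertainty term is negligible
        inst = Instrument("rs1", 0.5, 0.04, 0.10, 0.05)
        _, first = wald_ratio(inst)
        _, second = wald_ratio(inst, second_order=True)
        assert first == pytest.approx(second, rel=0.02)

    def test_second_order_se_matches_ratio_distribution(self, rng):
        # Monte-Carlo sd of the ratio of two normals vs the delta method
        inst = Instrument("rs1", 0.5, 0.04, 0.10, 0.05)
        num = rng.normal(inst.beta_out, inst.se_out, 200_000)
        den = rng.normal(inst.beta_exp, inst.se_exp, 200_000)
        _, second = wald_ratio(inst, second_order=True)
        assert np.std(num / den) == pytest.approx(second, rel=0.05)


class TestIvw:
    def test_duplicated_instrument_equals_its_wald_ratio(self):
        inst = Instrument("rs1", 0.5, 0.05, 0.25, 0.05)
        res = ivw([inst, inst])
        assert res.beta == pytest.approx(wald_ratio(inst)[0])

    def test_two_instrument_hand_example(self):
        # ratios 0.5 (se 0.1) and 0.6 (se 0.2): weights 100 and 25
        a = Instrument("rs1", 1.0, 0.0, 0.5, 0.1)
        b = Instrument("rs2", 1.0, 0.0, 0.6, 0.2)
        res = ivw([a, b])
        assert res.beta == pytest.approx(0.52)
        assert res.se == pytest.approx(1 / math.sqrt(125), rel=1e-9)
        assert res.method == "ivw_fixed"

    def test_single_instrument_rejected(self):
        with pytest.raises(MrError, match=">= 2"):
            ivw([Instrument("rs1", 0.5, 0.05, 0.25, 0.05)])

    def test_heterogeneity_triggers_random_effects(self):
        # four instruments with wildly discordant ratios
        insts = [Instrument(f"rs{i}", 1.0, 0.01, b, 0.02)
                 for i, b in enumerate([0.1, 0.9, -0.5, 1.5])]
        res = ivw(insts)
        assert res.method == "ivw_random"
        assert res.q_p < 0.05
        fixed_se = 1 / math.sqrt(sum(1 / 0.02**2 for _ in insts))
        assert res.se > fixed_se


class TestSteiger:
    def test_exposure_dominant_direction(self):
        # exposure r2 ~ 0.04 at n=1000, outcome r2 ~ 0.0004 at n=10000
        z_exp = math.sqrt(0.04 * 1000 / (1 - 0.04))
        z_out = math.sqrt(0.0004 * 10_000 / (1 - 0.0004))
        inst = Instrument("rs1", z_exp * 0.03, 0.03, z_out * 0.01, 0.01,
                          n_exp=1000, n_out=10_000)
        correct, p = steiger_test([inst])
        assert correct is True
        assert p < 0.01

    def test_symmetric_inputs_tie_breaks_conservatively(self):
        inst = Instrument("rs1", 0.2, 0.05, 0.2, 0.05, n_exp=1000, n_out=1000)
        correct, p = steiger_test([inst])
        assert correct is False
        assert p == pytest.approx(1.0)

    def test_missing_sample_size_rejected(self):
        with pytest.raises(MrError, match="sample size"):
            steiger_test([Instrument("rs1", 0.2, 0.05, 0.1, 0.05)])

    def test_mediation_direction_recovered(self):
        hits = 0
        for seed in spawn_seeds(301, 40):
            sim = simulate_locus(ScenarioSpec(scenario="mediation", n_snps=20, n_qtl=5000,
                                              n_gwas=5000, cis_h2=0.1, gamma=0.3,
                                              ld_decay=0.0, n_causal_qtl=1, seed=seed))
            res = mr_gene_screen({"G1": sim.qtl_records}, sim.gwas_records, sim.ld, 1)[0]
            hits += bool(res.steiger_correct)
        assert hits >= 38  # >= 95% of replicates


class TestScreen:
    def test_bonferroni_gate_printed_value(self):
        assert 0.05 / 608 == pytest.approx(8.224e-5, rel=1e-4)

    def test_gene_without_instruments_reported_not_dropped(self):
        sim = simulate_locus(ScenarioSpec(scenario="null", n_snps=15, n_qtl=300,
                                          n_gwas=300, seed=8))
        (res,) = mr_gene_screen({"G1": sim.qtl_records}, sim.gwas_records, sim.ld, 10)
        assert res.reason == "no significant instruments"
        assert math.isnan(res.beta)

    def test_gene_with_unharmonizable_instrument_reported(self):
        sim = simulate_locus(ScenarioSpec(scenario="qtl_only", n_snps=15, n_qtl=3000,
                                          n_gwas=300, cis_h2=0.4, n_causal_qtl=1, seed=8))
        # outcome table with clashing alleles at every variant
        from dataclasses import replace

        broken = [
            replace(r, variant=replace(r.variant, effect_allele="A", other_allele="C"))
            for r in sim.gwas_records
        ]
        (res,) = mr_gene_screen({"G1": sim.qtl_records}, broken, sim.ld, 10)
        assert res.reason == "no valid instruments"

    def test_wald_used_for_single_instrument(self):
        sim = simulate_locus(ScenarioSpec(scenario="mediation", n_snps=15, n_qtl=5000,
                                          n_gwas=5000, cis_h2=0.1, gamma=0.4,
                                          ld_decay=0.0, n_causal_qtl=1, seed=13))
        (res,) = mr_gene_screen({"G1": sim.qtl_records}, sim.gwas_records, sim.ld, 1)
        assert res.n_instruments == 1
        assert res.method == "wald"
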