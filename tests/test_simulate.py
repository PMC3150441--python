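"""Determinism and statistical structure of the synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from evoscan.errors import ConfigError
from evoscan.fitness import competition_coefficient
from evoscan.genome import coding_fraction
from evoscan.simulate import (
    PlantedCnv,
    PlantedVariant,
    ScenarioConfig,
    default_scenario,
    expected_test_fraction,
    simulate_competition,
    simulate_coverage_pair,
    simulate_genome,
    simulate_growth_curve,
    simulate_pileup_pair,
    simulate_qpcr,
    write_scenario,
)

SMALL = dict(genome_length=4000, n_genes=3)


class TestDeterminism:
    def test_genome_bytes_stable(self, tmp_path):
        from evoscan.genome import write_fasta
        for k in (1, 2):
            g, _ = simulate_genome(ScenarioConfig(seed=5, **SMALL))
            write_fasta(g, tmp_path / f"g{k}.fasta")
        assert (tmp_path / "g1.fasta").read_bytes() == \
            (tmp_path / "g2.fasta").read_bytes()

    def test_pileups_stable(self):
        cfg = ScenarioConfig(seed=5, **SMALL)
        g, _ = simulate_genome(cfg)
        a1, e1 = simulate_pileup_pair(g, cfg)
        a2, e2 = simulate_pileup_pair(g, cfg)
        assert a1.drop(columns="indels").equals(a2.drop(columns="indels"))
        assert e1.drop(columns="indels").equals(e2.drop(columns="indels"))

    def test_coverage_competition_qpcr_stable(self):
        cfg = ScenarioConfig(seed=9, planted_cnvs=[PlantedCnv("chrI", 10, 30, 1.0)])
        e1, a1 = simulate_coverage_pair(cfg)
        e2, a2 = simulate_coverage_pair(cfg)
        assert e1.equals(e2) and a1.equals(a2)
        s1 = simulate_competition(cfg)
        s2 = simulate_competition(cfg)
        assert [x.count_test for x in s1.samples] == \
            [x.count_test for x in s2.samples]
        assert [r.ct_target for r in simulate_qpcr(cfg)] == \
            [r.ct_target for r in simulate_qpcr(cfg)]

    def test_different_seeds_differ(self):
        g1, _ = simulate_genome(ScenarioConfig(seed=1, **SMALL))
        g2, _ = simulate_genome(ScenarioConfig(seed=2, **SMALL))
        assert g1.sequences != g2.sequences


class TestSimulateGenome:
    def test_no_genes(self):
        g, genes = simulate_genome(ScenarioConfig(seed=0, genome_length=2000,
                                                  n_genes=0))
        assert genes == []
        assert coding_fraction(g, genes) == 0.0

    def test_requested_coding_fraction_achieved(self):
        cfg = ScenarioConfig(seed=3, genome_length=100_000, n_genes=30,
                             coding_fraction=0.72)
        g, genes = simulate_genome(cfg)
        assert coding_fraction(g, genes) == pytest.approx(0.72, abs=0.02)

    def test_orfs_have_valid_structure(self):
        from evoscan.genome import STANDARD_CODE, extract_cds
        g, genes = simulate_genome(ScenarioConfig(seed=4, **SMALL))
        for gene in genes:
            codons = extract_cds(g, gene)
            assert codons[0] == "ATG"
            assert STANDARD_CODE.is_stop(codons[-1])
            assert not any(STANDARD_CODE.is_stop(c) for c in codons[:-1])

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genome(ScenarioConfig(seed=0, genome_length=100,
                                           n_genes=40))


class TestSimulatePileups:
    def test_planted_het_fraction_in_binomial_band(self):
        cfg = ScenarioConfig(seed=21, genome_length=2000, n_genes=1,
                             depth_mean=50)
        g, _ = simulate_genome(cfg)
        ref = g.fetch("chrI", 1000, 1000)
        alt = [b for b in "ACGT" if b != ref][0]
        cfg.planted_variants = [PlantedVariant("chrI", 1000, alt, 0.5)]
        _, evo = simulate_pileup_pair(g, cfg)
        row = evo[evo["pos"] == 1000].iloc[0]
        support = int(row[f"{alt}+"] + row[f"{alt}-"])
        depth = int(sum(row[f"{b}{s}"] for b in "ACGT" for s in "+-"))
        lo, hi = sps.binom.ppf([0.005, 0.995], depth, 0.5)
        assert lo <= support <= hi

    def test_error_free_pair_has_identical_allele_content(self):
        cfg = ScenarioConfig(seed=8, genome_length=2000, n_genes=1,
                             error_rate=0.0, ambiguous_rate=0.0,
                             del_marker_rate=0.0)
        g, _ = simulate_genome(cfg)
        anc, evo = simulate_pileup_pair(g, cfg)
        for table in (anc, evo):
            for b in "ACGT":
                support = table[f"{b}+"] + table[f"{b}-"]
                assert ((support == 0) | (table["ref"] == b)).all()

    def test_planted_outside_genome_rejected(self):
        cfg = ScenarioConfig(seed=0, genome_length=1000, n_genes=0,
                             planted_variants=[
                                 PlantedVariant("chrI", 5000, "A", 0.5)])
        g, _ = simulate_genome(cfg)
        with pytest.raises(ConfigError):
            simulate_pileup_pair(g, cfg)


class TestSimulateCoverage:
    def test_no_cnv_centered_track(self):
        from evoscan.cnv import log_ratio, noise_sd
        cfg = ScenarioConfig(seed=2, n_coverage_bins=300)
        evo, anc = simulate_coverage_pair(cfg)
        lr = log_ratio(evo, anc)
        assert abs(lr["value"].mean()) < 1e-9
        # mean bin depth 50x over 1 kb: log2-ratio sd ~ sqrt(2/50000)/ln2
        expected_sd = math.sqrt(2 / 50_000) / math.log(2)
        assert noise_sd(lr["value"].to_numpy()) == pytest.approx(
            expected_sd, rel=0.35)

    def test_overlapping_cnvs_rejected(self):
        cfg = ScenarioConfig(seed=0, planted_cnvs=[
            PlantedCnv("chrI", 10, 30, 1.0), PlantedCnv("chrI", 25, 40, -1.0)])
        with pytest.raises(ConfigError):
            simulate_coverage_pair(cfg)

    def test_planted_shift_recovered_end_to_end(self):
        from evoscan.cnv import CbsParams, log_ratio, segment, smooth_outliers
        cfg = ScenarioConfig(seed=6, planted_cnvs=[PlantedCnv("chrI", 40, 89, 1.0)])
        evo, anc = simulate_coverage_pair(cfg)
        segs = segment(smooth_outliers(log_ratio(evo, anc)),
                       CbsParams(nperm=1000, seed=6))
        amplified = [s for s in segs if s.mean > 0.4]
        assert len(amplified) == 1
        assert abs(amplified[0].first_bin - 40) <= 2
        assert abs(amplified[0].last_bin - 89) <= 2


class TestSimulateCompetitionGrowthQpcr:
    def test_neutral_strain_stays_at_p0(self):
        g = np.arange(0, 21, 3)
        frac = expected_test_fraction(0.0, g, 0.5)
        assert np.allclose(frac, 0.5)

    def test_closed_form_final_fraction(self):
        frac = expected_test_fraction(0.28, np.array([20.0]), 0.5)
        assert frac[0] == pytest.approx(math.exp(5.6) / (math.exp(5.6) + 1))

    def test_estimator_recovers_planted_s(self):
        cfg = ScenarioConfig(seed=3, competition_s=0.28)
        est = competition_coefficient(simulate_competition(cfg))
        assert est.s == pytest.approx(0.28, abs=3 * est.se)

    def test_growth_curve_early_slope_matches_analytic_limit(self):
        # d ln(OD)/dt = mu * (1 - OD/K); at the start OD ~ od0
        cfg = ScenarioConfig(growth_mu=0.4)
        t, od = simulate_growth_curve(cfg)
        early = slice(0, 4)
        slope = np.polyfit(t[early], np.log(od[early]), 1)[0]
        expected = cfg.growth_mu * (1 - cfg.growth_od0 / cfg.growth_capacity)
        assert slope == pytest.approx(expected, rel=0.02)

    def test_qpcr_zero_noise_inverts_exactly(self):
        from evoscan.fitness import ddct_copy_number
        cfg = ScenarioConfig(seed=0, true_copy_numbers=(1.0, 2.0, 0.5),
                             ct_noise_sd=0.0)
        recs = simulate_qpcr(cfg)
        values = [ddct_copy_number(r, recs[0]) for r in recs]
        assert values == pytest.approx([1.0, 2.0, 0.5])


def test_write_scenario_produces_all_inputs(tmp_path):
    cfg = default_scenario(2)
    cfg.genome_length, cfg.n_genes = 3000, 3
    cfg.planted_variants = cfg.planted_variants[:0]  # positions beyond 3 kb
    manifest = write_scenario(cfg, tmp_path)
    for name in ("genome.fasta", "genes.tsv", "ancestor.pileup.tsv",
                 "evolved.pileup.tsv", "ancestor.bedgraph",
                 "evolved.bedgraph", "competition.tsv", "growth.tsv",
                 "qpcr.tsv", "truth.json"):
        assert (tmp_path / name).exists(), name
    assert manifest["seed"] == 2
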