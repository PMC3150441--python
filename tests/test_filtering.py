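"""Ancestor-vs-evolved SNP/indel filter rules and the whole-pileup scan."""

import numpy as np
import pytest

from evoscan.errors import PairingError
from evoscan.filtering import (
    FilterParams,
    IndelCall,
    SnpCall,
    classify_zygosity,
    indel_filter,
    scan_pair,
    snp_filter,
)
from evoscan.pileup import PairedSite, site_from_row
from evoscan.simulate import (
    PlantedVariant,
    ScenarioConfig,
    simulate_genome,
    simulate_pileup_pair,
)

P = FilterParams()


def paired(factory, anc_row, evo_row):
    anc = site_from_row(factory([anc_row]).iloc[0])
    evo = site_from_row(factory([evo_row]).iloc[0])
    return PairedSite(anc, evo)


class TestClassifyZygosity:
    @pytest.mark.parametrize("af,expected", [
        (0.0, "hom_ref"), (0.10, "hom_ref"), (0.2, "ambiguous"),
        (0.30, "het"), (0.5, "het"), (0.79, "het"),
        (0.80, "hom_alt"), (1.0, "hom_alt"),
    ])
    def test_thresholds(self, af, expected):
        assert classify_zygosity(af, P) == expected


class TestSnpFilter:
    def anc(self, **kw):
        row = {"chrom": "c", "pos": 7, "ref": "A", "A+": 15, "A-": 15}
        row.update(kw)
        return row

    def evo(self, **kw):
        row = {"chrom": "c", "pos": 7, "ref": "A", "A+": 9, "A-": 9,
               "T+": 6, "T-": 6}
        row.update(kw)
        return row

    def test_rule_a_new_het(self, site_table_factory):
        call = snp_filter(paired(site_table_factory, self.anc(), self.evo()),
                          "T", P)
        assert call is not None
        assert call.rule == "A_new_het"
        assert call.zygosity_transition == "hom (Ref)->het"
        assert call.af_evo == pytest.approx(0.40)

    def test_fails_both_rules(self, site_table_factory):
        anc = self.anc(**{"A+": 13, "A-": 13, "T+": 2, "T-": 2})  # af_anc 0.13
        assert snp_filter(paired(site_table_factory, anc, self.evo()), "T", P) is None

    def test_rule_b_het_to_hom(self, site_table_factory):
        anc = self.anc(**{"A+": 9, "A-": 9, "T+": 11, "T-": 11})  # 0.55
        evo = self.evo(**{"A+": 1, "A-": 1, "T+": 9, "T-": 9})  # 0.90
        call = snp_filter(paired(site_table_factory, anc, evo), "T", P)
        assert call is not None
        assert call.rule == "B_loss_of_het"
        assert call.zygosity_transition == "het->hom (Alt)"

    def test_min_depth_in_ancestor(self, site_table_factory):
        anc = self.anc(**{"A+": 2, "A-": 2})  # depth 4 < 5
        assert snp_filter(paired(site_table_factory, anc, self.evo()), "T", P) is None

    def test_strand_confirmation_required(self, site_table_factory):
        evo = self.evo(**{"T+": 12, "T-": 0})
        assert snp_filter(paired(site_table_factory, self.anc(), evo), "T", P) is None

    def test_ambiguity_budget_per_strain(self, site_table_factory):
        evo = self.evo(N=1, **{"*": 1})  # N + * = 2 > 1
        assert snp_filter(paired(site_table_factory, self.anc(), evo), "T", P) is None

    def test_emitted_call_satisfies_rule_inequalities(self, site_table_factory):
        call = snp_filter(paired(site_table_factory, self.anc(), self.evo()),
                          "T", P)
        assert_rule_inequalities(call)


def assert_rule_inequalities(call):
    if isinstance(call, SnpCall):
        if call.rule == "A_new_het":
            assert call.af_evo >= 0.30 and call.af_anc <= 0.10
        else:
            assert call.af_evo >= 0.80 and call.af_anc < 0.80
    else:
        assert abs(call.delta_af) >= 0.30


class TestIndelFilter:
    # indel-bearing reads are among the base-counted reads, so the allele
    # frequency denominator is the site's total depth

    def test_delta_af_call(self, site_table_factory):
        pair = paired(
            site_table_factory,
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 20, "G-": 20,
             "indels": {"+A": 2}},  # af 2/40
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 20, "G-": 20,
             "indels": {"+A": 18}})  # af 18/40
        calls = indel_filter(pair, P)
        assert len(calls) == 1
        assert calls[0].delta_af == pytest.approx(0.40)

    def test_small_delta_no_call(self, site_table_factory):
        pair = paired(
            site_table_factory,
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 20, "G-": 20,
             "indels": {"+A": 8}},  # 8/40 = 0.20
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 20, "G-": 20,
             "indels": {"+A": 14}})  # 14/40 = 0.35
        assert indel_filter(pair, P) == []

    def test_top2_rule_blocks_noisy_site(self, site_table_factory):
        # three indel strings whose top two hold well under 80% of the
        # covering reads at the position
        pair = paired(
            site_table_factory,
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 10, "G-": 10,
             "indels": {"+A": 1, "-G": 1, "+T": 1}},
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 10, "G-": 10,
             "indels": {"+A": 8, "-G": 3, "+T": 3}})
        assert indel_filter(pair, P) == []

    def test_min_depth(self, site_table_factory):
        pair = paired(
            site_table_factory,
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 4, "G-": 4},
            {"chrom": "c", "pos": 3, "ref": "G", "G+": 5, "G-": 5,
             "indels": {"+A": 6}})
        assert indel_filter(pair, P) == []  # ancestor depth 8 < 10


class TestScanPair:
    def simulate(self, seed, planted=(), length=3000):
        cfg = ScenarioConfig(seed=seed, genome_length=length, n_genes=2,
                             planted_variants=list(planted))
        genome, _ = simulate_genome(cfg)
        return genome, simulate_pileup_pair(genome, cfg)

    def test_planted_hets_recovered(self):
        genome, _ = self.simulate(5)
        planted = []
        rng = np.random.default_rng(5)
        for pos in rng.choice(np.arange(1, 3001), size=8, replace=False):
            ref = genome.fetch("chrI", int(pos), int(pos))
            alt = [b for b in "ACGT" if b != ref][0]
            planted.append(PlantedVariant("chrI", int(pos), alt, 0.5))
        cfg = ScenarioConfig(seed=5, genome_length=3000, n_genes=2,
                             planted_variants=planted)
        genome2, _ = simulate_genome(cfg)
        anc, evo = simulate_pileup_pair(genome2, cfg)
        calls = scan_pair(anc, evo)
        assert {(c.chrom, c.pos) for c in calls} == \
            {(v.chrom, v.pos) for v in planted}
        for c in calls:
            assert_rule_inequalities(c)

    def test_mutation_free_pair_is_silent(self):
        _, (anc, evo) = self.simulate(7)
        assert scan_pair(anc, evo) == []

    def test_deterministic(self):
        _, (anc, evo) = self.simulate(9)
        assert scan_pair(anc, evo) == scan_pair(anc, evo)

    def test_length_mismatch_is_pairing_error(self):
        _, (anc, evo) = self.simulate(9)
        with pytest.raises(PairingError):
            scan_pair(anc.iloc[:-5], evo)

    def test_depth_threshold_monotonicity(self):
        genome, (anc, evo) = self.simulate(5)
        planted = [PlantedVariant("chrI", 100, "T" if genome.fetch("chrI", 100, 100) != "T" else "C", 0.5)]
        cfg = ScenarioConfig(seed=5, genome_length=3000, n_genes=2,
                             planted_variants=planted)
        genome2, _ = simulate_genome(cfg)
        anc, evo = simulate_pileup_pair(genome2, cfg)
        previous = None
        for depth in (5, 20, 40, 60):
            calls = scan_pair(anc, evo, FilterParams(min_depth_snp=depth))
            keys = {(c.chrom, c.pos, getattr(c, "alt", "")) for c in calls}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_vectorized_scan_matches_scalar_filter(self):
        _, (anc, evo) = self.simulate(13)
        calls = scan_pair(anc, evo)
        # re-evaluate every *site* with the scalar path
        for i in range(0, len(anc), 37):
            pair = PairedSite(site_from_row(anc.iloc[i]),
                              site_from_row(evo.iloc[i]))
            for alt in "ACGT":
                if alt == pair.evolved.ref:
                    continue
                scalar = snp_filter(pair, alt, P)
                vector = [c for c in calls if isinstance(c, SnpCall)
                          and c.pos == pair.evolved.pos and c.alt == alt]
                assert (scalar is None) == (len(vector) == 0)
                if scalar is not None:
                    assert vector[0] == scalar
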