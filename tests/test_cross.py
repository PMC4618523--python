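import numpy as np
import pytest
from scipy import stats

import bsacross as b


class TestMeiosis:
    def test_identical_parents_give_identical_gamete(self, small_map, rng):
        p = b.s3_parent(small_map)
        g = b.simulate_meiosis(p, p, small_map, rng)
        assert np.array_equal(g.origins, p.origins)

    def test_zero_recombination_transmits_intact_chromosomes(self, rng):
        m = b.build_marker_map(320, cm_per_kb=0.0, seed=2)
        a, c = b.by_parent(m), b.s3_parent(m)
        g = b.simulate_meiosis(a, c, m, rng)
        for sl in m.chrom_slices.values():
            assert len(np.unique(g.origins[sl])) == 1

    def test_gamete_origins_are_parental(self, mid_map, rng):
        """Conservation: every origin comes from one of the two parents."""
        a, c = b.by_parent(mid_map), b.s3_parent(mid_map)
        for _ in range(5):
            g = b.simulate_meiosis(a, c, mid_map, rng)
            assert np.isin(g.origins, [0, 1]).all()

    def test_length_mismatch_rejected(self, small_map, tiny_map, rng):
        with pytest.raises(ValueError):
            b.simulate_meiosis(b.by_parent(small_map), b.s3_parent(small_map),
                               tiny_map, rng)

    def test_mendelian_segregation_at_every_marker(self, tiny_map, rules):
        """Unselected BY x 3S gametes carry 3S at ~50% per marker; the
        chi-square over markers should reject at alpha=0.01 for roughly 1%
        of markers."""
        rng = np.random.default_rng(7)
        n = 10_000
        a, c = b.by_parent(tiny_map), b.s3_parent(tiny_map)
        counts = np.zeros(tiny_map.n_markers)
        for _ in range(n):
            counts += b.simulate_meiosis(a, c, tiny_map, rng).origins
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(counts / n - 0.5) < 4 * se)
        chi2 = ((counts - n / 2) ** 2) / (n * 0.25)
        rejected = np.mean(chi2 > stats.chi2.ppf(0.99, df=1))
        assert rejected <= 0.13  # ~1% expected; 16 markers give coarse granularity

    def test_linkage_decays_with_genetic_distance(self, mid_map):
        """Adjacent markers co-inherit; covariance falls with cM distance."""
        rng = np.random.default_rng(3)
        a, c = b.by_parent(mid_map), b.s3_parent(mid_map)
        gametes = np.stack([b.simulate_meiosis(a, c, mid_map, rng).origins
                            for _ in range(600)]).astype(float)
        sl = mid_map.chrom_slices["IV"]
        i = sl.start
        near, far = i + 1, sl.stop - 1
        r_near = np.corrcoef(gametes[:, i], gametes[:, near])[0, 1]
        r_far = np.corrcoef(gametes[:, i], gametes[:, far])[0, 1]
        assert r_near > r_far

    def test_engineered_state_rides_its_marker(self, small_map, rules):
        """ira2-D2933 is inherited exactly when the gamete takes the mutant
        parent's strand at the IRA2 marker."""
        rng = np.random.default_rng(9)
        a = b.by_parent(small_map)
        c = b.s3_parent(small_map, ira2_state="D2933")
        idx = small_map.causal_index["IRA2"]
        for _ in range(200):
            g = b.simulate_meiosis(a, c, small_map, rng)
            assert (g.ira2_state == "D2933") == (g.origins[idx] == 1)


class TestCrossScheme:
    def test_backcross_requires_founder(self):
        with pytest.raises(ValueError, match="founder"):
            b.CrossScheme("BACKCROSS_BY")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            b.CrossScheme("F2_INTERCROSS")

    def test_ira2mut_scheme_places_lesion_on_3s(self, small_map):
        a, c = b.CrossScheme.byx3s_ira2mut().parents(small_map)
        assert a.ira2_state == "WT" and c.ira2_state == "D2933"

    def test_sfl1del_scheme_deletes_both_parents(self, small_map):
        sch = b.CrossScheme.byx3s_sfl1del()
        a, c = sch.parents(small_map)
        assert a.sfl1_state == c.sfl1_state == "DELETED"
        assert sch.engineered_segregating(small_map)["SFL1"] is False

    def test_transmission_probabilities(self, small_map, rng):
        tr = b.CrossScheme.byx3s_ira2mut().transmission()
        assert all(p == 0.5 for p in tr.p_3s.values())
        assert tr.p_ira2_mut == 0.5 and tr.p_sfl1_del == 0.0
        founder = b.simulate_meiosis(b.by_parent(small_map),
                                     b.s3_parent(small_map, ira2_state="D2933"),
                                     small_map, rng)
        tr_bc = b.CrossScheme.backcross_by(founder).transmission()
        for g, origin in founder.causal_origins().items():
            assert tr_bc.p_3s[g] == (0.5 if origin == "3S" else 0.0)


class TestSimulateCross:
    def test_empty_population(self, small_map, rules, rng):
        assert b.simulate_cross(b.CrossScheme.byx3s_wt(), 0, small_map, rules, rng) == []

    def test_wild_type_cross_is_all_smooth(self, small_map, rules, rng):
        pop = b.simulate_cross(b.CrossScheme.byx3s_wt(), 300, small_map, rules, rng)
        assert all(s.phenotype == "SMOOTH" for s in pop)

    def test_backcross_monomorphic_where_founder_matches_recurrent(self, small_map,
                                                                   rules, rng):
        founder = b.simulate_meiosis(b.by_parent(small_map),
                                     b.s3_parent(small_map, ira2_state="D2933"),
                                     small_map, rng)
        pop = b.simulate_cross(b.CrossScheme.backcross_3s(founder), 50,
                               small_map, rules, rng)
        monomorphic = founder.origins == 1   # founder 3S = recurrent 3S
        for s in pop:
            assert np.all(s.haplotype.origins[monomorphic] == 1)

    def test_simulate_until_respects_filter(self, small_map, rules):
        rng = np.random.default_rng(1)
        pool = b.simulate_until(b.CrossScheme.byx3s_ira2mut(), small_map, rules,
                                10, rng, allele_filter={"END3": "BY"})
        assert len(pool) == 10
        assert all(s.phenotype == "ROUGH" for s in pool)
        assert all(s.haplotype.origin_at("END3") == "BY" for s in pool)

    def test_viability_bias_skews_allele_frequency(self, small_map, rules):
        """A survival disadvantage for one END3 allele depletes it from the
        surviving population while unlinked markers stay Mendelian."""
        rng = np.random.default_rng(6)
        pop = b.simulate_cross(b.CrossScheme.byx3s_wt(), 600, small_map, rules,
                               rng, viability_bias={"END3": {"3S": 0.2}})
        end3 = np.mean([s.haplotype.origin_at("END3") == "3S" for s in pop])
        flo8 = np.mean([s.haplotype.origin_at("FLO8") == "3S" for s in pop])
        # expected 3S share = 0.2 / 1.2
        assert abs(end3 - 0.2 / 1.2) < 0.06
        assert abs(flo8 - 0.5) < 0.08

    def test_simulate_until_raises_when_impossible(self, small_map, rules):
        rng = np.random.default_rng(1)
        with pytest.raises(RuntimeError):
            b.simulate_until(b.CrossScheme.byx3s_wt(), small_map, rules, 5, rng,
                             max_attempts=200)
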