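import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bsacross as b


def _counts(marker_map, count_by, count_3s, count_other=None):
    count_by = np.asarray(count_by)
    count_3s = np.asarray(count_3s)
    count_other = np.zeros_like(count_by) if count_other is None \
        else np.asarray(count_other)
    depth = count_by + count_3s + count_other
    return b.AlleleCountTable(marker_map, depth, count_by, count_3s, count_other)


def _track(marker_map, values, **kw):
    return b.FrequencyTrack(marker_map, np.asarray(values, dtype=float), **kw)


class TestFrequenciesFromCounts:
    @pytest.mark.parametrize("by,s3,other,expected", [
        (0, 50, 0, 1.0),
        (25, 25, 0, 0.5),
        (30, 60, 10, 60 / 90),     # other-base reads leave the denominator
    ])
    def test_frequency_arithmetic(self, tiny_map, by, s3, other, expected):
        n = tiny_map.n_markers
        t = _counts(tiny_map, np.full(n, by), np.full(n, s3), np.full(n, other))
        track = b.frequencies_from_counts(t)
        assert track.values[0] == pytest.approx(expected)

    def test_zero_depth_marker_missing(self, tiny_map):
        n = tiny_map.n_markers
        by = np.full(n, 10); by[3] = 0
        s3 = np.full(n, 10); s3[3] = 0
        track = b.frequencies_from_counts(_counts(tiny_map, by, s3))
        assert np.isnan(track.values[3])
        assert np.isfinite(np.delete(track.values, 3)).all()

    def test_min_depth_masks_shallow_markers(self, tiny_map):
        n = tiny_map.n_markers
        track = b.frequencies_from_counts(
            _counts(tiny_map, np.full(n, 2), np.full(n, 2)),
            b.MappingParams(min_depth=5))
        assert np.isnan(track.values).all()


class TestSlidingWindows:
    def test_window_means_on_one_chromosome(self):
        m = b.build_marker_map(320, seed=1)
        vals = np.full(m.n_markers, np.nan)
        sl = m.chrom_slices["IV"]
        n_chrom = sl.stop - sl.start
        chrom_vals = np.ones(n_chrom)
        chrom_vals[9] = 0.0          # one discordant marker inside first window
        vals[sl] = chrom_vals
        w = b.sliding_windows(_track(m, vals), m, b.MappingParams())
        assert len(w) == n_chrom - 9
        assert w.mean[0] == pytest.approx(0.9)   # nine 1.0s and one 0.0
        assert w.mean[-1] == pytest.approx(1.0)

    def test_chromosome_below_window_size_yields_no_windows(self, tiny_map):
        vals = np.full(tiny_map.n_markers, 0.8)
        w = b.sliding_windows(_track(tiny_map, vals), tiny_map,
                              b.MappingParams(window_snps=10))
        assert len(w) == 0

    def test_windows_skip_missing_markers(self):
        m = b.build_marker_map(160, seed=2)
        vals = np.full(m.n_markers, 0.5)
        vals[::2] = np.nan
        w = b.sliding_windows(_track(m, vals), m, b.MappingParams(window_snps=3))
        for first, last in zip(w.first, w.last):
            member = np.arange(first, last + 1)
            assert np.isfinite(vals[member]).sum() == 3

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=30, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_window_means_bounded_by_member_range(self, freqs):
        m = b.build_marker_map(30, chrom_lengths_bp=[10_000] + [10] * 15, seed=0)
        vals = np.full(m.n_markers, np.nan)
        sl = m.chrom_slices["I"]
        k = sl.stop - sl.start
        vals[sl] = freqs[:k]
        w = b.sliding_windows(_track(m, vals), m, b.MappingParams(window_snps=5))
        for first, last, mean in zip(w.first, w.last, w.mean):
            member = vals[first:last + 1]
            member = member[np.isfinite(member)]
            assert member.min() - 1e-12 <= mean <= member.max() + 1e-12


class TestCallFixedLoci:
    def test_flat_half_track_yields_no_calls(self, mid_map):
        vals = np.full(mid_map.n_markers, 0.5)
        w = b.sliding_windows(_track(mid_map, vals), mid_map)
        assert b.call_fixed_loci(w, mid_map) == []

    def test_fixed_block_is_called_and_delimited(self):
        m = b.build_marker_map(320, seed=4)
        vals = np.full(m.n_markers, 0.5)
        sl = m.chrom_slices["IV"]
        hot = np.arange(sl.start + 5, sl.start + 25)
        vals[hot] = 1.0
        w = b.sliding_windows(_track(m, vals), m)
        calls = b.call_fixed_loci(w, m)
        assert len(calls) == 1
        c = calls[0]
        assert c.fixed_allele == "3S"
        assert c.first_idx <= hot[0] and c.last_idx >= hot[-1]
        d = b.delimit_interval(c, w, m)
        assert (d.start_bp, d.end_bp) == (c.start_bp, c.end_bp)

    def test_two_overlapping_windows_span_eleven_markers(self):
        """Two qualifying windows sharing 9 markers delimit an 11-marker
        interval."""
        m = b.build_marker_map(320, seed=4)
        params = b.MappingParams(merge_gap_cm=0.0)
        vals = np.full(m.n_markers, 0.0)
        sl = m.chrom_slices["IV"]
        vals[sl.start:sl.start + 11] = 1.0
        # windows: [0..9] mean 1.0, [1..10] mean 1.0, [2..11] mean 10/11... < 1
        vals[sl.start + 11:sl.stop] = 0.0
        w = b.sliding_windows(_track(m, vals), m, params)
        qualifying = w.mean >= params.fix_threshold
        assert qualifying.sum() == 2
        calls = [c for c in b.call_fixed_loci(w, m, params) if c.fixed_allele == "3S"]
        assert len(calls) == 1
        assert calls[0].last_idx - calls[0].first_idx + 1 == 11

    def test_by_fixation_called_below_complement_threshold(self):
        m = b.build_marker_map(320, seed=4)
        vals = np.full(m.n_markers, 0.5)
        sl = m.chrom_slices["IV"]
        vals[sl.start + 10:sl.start + 30] = 0.01
        calls = b.call_fixed_loci(b.sliding_windows(_track(m, vals), m), m)
        assert len(calls) == 1 and calls[0].fixed_allele == "BY"
        assert calls[0].mean_freq >= 0.95     # frequency of the fixed BY allele

    def test_calls_invariant_to_flat_chromosomes(self):
        m = b.build_marker_map(480, seed=6)
        vals = np.full(m.n_markers, 0.5)
        sl = m.chrom_slices["V"]
        vals[sl.start + 3:sl.start + 20] = 1.0
        base = b.call_fixed_loci(b.sliding_windows(_track(m, vals), m), m)
        # blank out two other chromosomes entirely: calls unchanged
        vals2 = vals.copy()
        vals2[m.chrom_slices["I"]] = 0.5
        vals2[m.chrom_slices["XVI"]] = 0.5
        again = b.call_fixed_loci(b.sliding_windows(_track(m, vals2), m), m)
        assert [(c.chrom, c.start_bp, c.end_bp) for c in base] == \
            [(c.chrom, c.start_bp, c.end_bp) for c in again]

    def test_segregating_engineered_site_promotes_to_mutant(self, mid_map):
        vals = np.full(mid_map.n_markers, 0.5)
        idx = mid_map.causal_index["IRA2"]
        vals[idx - 15:idx + 15] = 1.0
        track = _track(mid_map, vals, mutant_frac={"IRA2": 1.0})
        calls = b.call_fixed_loci(b.sliding_windows(track, mid_map), mid_map)
        assert any(c.fixed_allele == "MUTANT" and c.contains_marker(idx)
                   for c in calls)

    def test_non_segregating_engineered_site_ignored(self, mid_map):
        vals = np.full(mid_map.n_markers, 0.5)
        track = _track(mid_map, vals, mutant_frac={"SFL1": 1.0},
                       engineered_segregating={"SFL1": False})
        assert b.call_fixed_loci(b.sliding_windows(track, mid_map), mid_map) == []

    def test_masked_engineered_site_emits_single_marker_call(self, mid_map):
        """A fixed lesion whose surrounding SNPs are uninformative is still
        reported, as a one-marker MUTANT locus."""
        vals = np.full(mid_map.n_markers, 0.5)
        vals[mid_map.chrom_slices["XV"]] = np.nan
        track = _track(mid_map, vals, mutant_frac={"IRA2": 0.99})
        calls = b.call_fixed_loci(b.sliding_windows(track, mid_map), mid_map)
        assert len(calls) == 1
        c = calls[0]
        idx = mid_map.causal_index["IRA2"]
        assert c.fixed_allele == "MUTANT" and (c.first_idx, c.last_idx) == (idx, idx)


class TestEndToEndRecovery:
    def test_causal_marker_always_inside_called_interval(self, mid_map, rules):
        """Six-way backcross pools: every merged locus contains its causal
        marker across seeded replicates."""
        from bsacross.popstats import classify_interaction
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            sch = b.CrossScheme.byx3s_ira2mut()
            founder = None
            for _ in range(3000):
                s = b.simulate_cross(sch, 1, mid_map, rules, rng)[0]
                if s.phenotype == "ROUGH" and \
                        classify_interaction(s.haplotype) == "SIX_WAY":
                    founder = s.haplotype
                    break
            pool_by = b.simulate_until(b.CrossScheme.backcross_by(founder), mid_map,
                                       rules, 63, rng, allele_filter={"END3": "3S"})
            pool_3s = b.simulate_until(b.CrossScheme.backcross_3s(founder), mid_map,
                                       rules, 88, rng, allele_filter={"END3": "3S"})
            p = b.PoolSeqParams(100)
            t_by = b.simulate_pool_counts(b.pool_true_frequencies(pool_by, mid_map),
                                          p, rng=rng)
            t_3s = b.simulate_pool_counts(b.pool_true_frequencies(pool_3s, mid_map),
                                          p, rng=rng)
            rep = b.map_backcross_pools(t_by, t_3s, mid_map, founder=founder)
            genes = set(g for gg in rep["genes"] for g in gg.split(",") if g)
            if genes >= {"END3", "FLO8", "MGA1", "MSS11", "SFL1", "IRA2"}:
                hits += 1
        assert hits >= n_rep - 1

    def test_map_mismatch_rejected(self, small_map, mid_map):
        zeros = np.zeros(small_map.n_markers, dtype=np.int64)
        t1 = b.AlleleCountTable(small_map, zeros, zeros, zeros, zeros)
        zeros2 = np.zeros(mid_map.n_markers, dtype=np.int64)
        t2 = b.AlleleCountTable(mid_map, zeros2, zeros2, zeros2, zeros2)
        with pytest.raises(ValueError):
            b.map_backcross_pools(t1, t2)
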