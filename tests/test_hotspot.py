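import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapsomatic.config import RunConfig
from hapsomatic.hotspot import (
    BIASED,
    ENRICHED,
    ENRICHED_PHASED,
    extract_biased_regions,
    hypergeom_upper_tail,
    scan_enriched_windows,
    scan_genome,
)
from hapsomatic.intervals import GenomicInterval, tile_windows
from hapsomatic.phasing import HP1, HP2, UNASSIGNED, HaplotypeCall
from hapsomatic.variants import SomaticMutation

from .oracles import hypergeom_upper_tail_exact


def muts_at(positions, chrom="chr1", vaf=0.3):
    return [SomaticMutation(chrom, p, "A", "C", vaf) for p in positions]


class TestHypergeomUpperTail:
    def test_zero_count_is_certain(self):
        assert hypergeom_upper_tail(0, 50, 10, 1000) == 1.0

    def test_hand_enumerated_value(self):
        # both of 2 mutations in a 50-bp window of a 100-bp genome:
        # C(50,2)/C(100,2) = 1225/4950
        assert hypergeom_upper_tail(2, 2, 50, 100) == pytest.approx(
            1225 / 4950, abs=1e-12
        )

    def test_window_equal_to_genome(self):
        for k in range(4):
            assert hypergeom_upper_tail(k, 3, 60, 60) == pytest.approx(1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 10, 100)   # k > M
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 5, 0, 100)    # empty window
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 200, 10, 100)  # M > G

    def test_numerically_stable_at_genome_scale(self):
        # 5000 mutations on a 3-Gb genome put ~0.17 in a 100-kb window;
        # ten observed is a ~1e-15 tail that must not underflow to 0
        p = hypergeom_upper_tail(10, 5000, 100_000, 3_000_000_000)
        assert 0.0 < p < 1e-12

    @given(G=st.integers(1, 40), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, G, data):
        w = data.draw(st.integers(1, G))
        M = data.draw(st.integers(0, G))
        k = data.draw(st.integers(0, M))
        exact = float(hypergeom_upper_tail_exact(k, M, w, G))
        assert hypergeom_upper_tail(k, M, w, G) == pytest.approx(exact, abs=1e-12)

    def test_non_increasing_in_k(self):
        ps = [hypergeom_upper_tail(k, 20, 100, 10_000) for k in range(21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScan:
    def test_planted_cluster_window_is_flagged(self):
        windows = tile_windows({"chr1": 10_000_000, "chr2": 10_000_000}, 100_000)
        cluster = muts_at(range(500_010, 500_110, 10))       # 10 in one window
        background = muts_at(range(1_000_000, 6_000_000, 100_000))  # 50 spread out
        tests = scan_enriched_windows(cluster + background, windows, alpha=0.1)
        flagged = [t for t in tests if t.flagged]
        assert len(flagged) == 1
        assert flagged[0].window.contains("chr1", 500_010)
        assert flagged[0].k == 10
        assert flagged[0].p_adj == pytest.approx(
            min(1.0, flagged[0].p_raw * len(windows))
        )

    def test_single_mutation_never_flags(self):
        windows = tile_windows({"chr1": 10_000_000}, 100_000)
        tests = scan_enriched_windows(muts_at([5]), windows, alpha=0.1)
        assert not any(t.flagged for t in tests)
        # p_raw for k=1 is 1-(1-w/G choose ...) = w/G; adjusted by n it is ~1
        hit = [t for t in tests if t.k == 1][0]
        assert hit.p_raw == pytest.approx(100_000 / 10_000_000)
        assert hit.p_adj == pytest.approx(1.0)

    def test_no_mutations_means_nothing_flagged(self):
        windows = tile_windows({"chr1": 1_000_000}, 100_000)
        tests = scan_enriched_windows([], windows)
        assert all(t.p_raw == 1.0 and not t.flagged for t in tests)

    def test_result_invariant_to_mutation_order(self):
        windows = tile_windows({"chr1": 2_000_000}, 100_000)
        muts = muts_at([10, 150_000, 150_010, 150_020, 900_000])
        a = scan_enriched_windows(muts, windows)
        b = scan_enriched_windows(list(reversed(muts)), windows)
        assert [(t.k, t.p_raw) for t in a] == [(t.k, t.p_raw) for t in b]


class TestBiasedRegions:
    def _scan_one_window(self, mutations, calls, blocks):
        windows = tile_windows({"chr1": 2_000_000}, 100_000)
        tests = scan_enriched_windows(mutations, windows, alpha=0.99)
        # force exactly the cluster window flagged for the step-3/4 check
        for t in tests:
            t.flagged = t.k >= 4
        return extract_biased_regions(tests, blocks, mutations, calls, RunConfig())

    def test_nine_of_ten_on_one_haplotype_is_biased(self):
        muts = muts_at(range(100_100, 100_200, 10))
        calls = {m.id: HaplotypeCall(m.id, HP1) for m in muts[:9]}
        calls[muts[9].id] = HaplotypeCall(muts[9].id, UNASSIGNED)
        block = GenomicInterval("chr1", 0, 2_000_000)
        regions = self._scan_one_window(muts, calls, [block])
        assert len(regions) == 1
        r = regions[0]
        assert r.status == BIASED
        assert (r.n_hp1, r.n_hp2, r.n_phased, r.n_mutations) == (9, 0, 9, 10)
        assert r.bias_fraction == pytest.approx(1.0)

    def test_sixty_percent_bias_is_not_biased(self):
        muts = muts_at(range(100_100, 100_200, 10))
        calls = {}
        for m in muts[:3]:
            calls[m.id] = HaplotypeCall(m.id, HP1)
        for m in muts[3:5]:
            calls[m.id] = HaplotypeCall(m.id, HP2)
        for m in muts[5:]:
            calls[m.id] = HaplotypeCall(m.id, UNASSIGNED)
        regions = self._scan_one_window(muts, calls, [GenomicInterval("chr1", 0, 2_000_000)])
        assert regions[0].status == ENRICHED_PHASED
        assert regions[0].bias_fraction == pytest.approx(0.6)

    def test_three_phased_is_below_count_floor(self):
        muts = muts_at(range(100_100, 100_200, 10))
        calls = {m.id: HaplotypeCall(m.id, HP1 if i < 3 else UNASSIGNED)
                 for i, m in enumerate(muts)}
        regions = self._scan_one_window(muts, calls, [GenomicInterval("chr1", 0, 2_000_000)])
        assert regions[0].status == ENRICHED

    def test_counting_restricted_to_window_block_overlap(self):
        muts = muts_at(range(100_100, 100_200, 10))
        calls = {m.id: HaplotypeCall(m.id, HP1) for m in muts}
        # block covers only the first five mutations
        block = GenomicInterval("chr1", 100_000, 100_145)
        regions = self._scan_one_window(muts, calls, [block])
        assert len(regions) == 1
        assert regions[0].n_mutations == 5
        assert regions[0].region == GenomicInterval("chr1", 100_000, 100_145)


class TestFwerControl:
    def test_uniform_mutations_rarely_flag_any_window(self):
        """Bonferroni keeps the family-wise error rate at or below alpha
        under the uniform null (Monte Carlo check at reduced replication;
        the full-size run lives in the acceptance suite)."""
        rng = np.random.default_rng(1234)
        windows = tile_windows({"chr1": 10_000_000, "chr2": 10_000_000}, 100_000)
        n_sims, hits = 60, 0
        for _ in range(n_sims):
            positions = rng.integers(0, 10_000_000, size=200)
            chroms = rng.integers(0, 2, size=200)
            muts = [SomaticMutation(f"chr{c + 1}", int(p), "A", "C", 0.3)
                    for c, p in zip(chroms, positions)]
            tests = scan_enriched_windows(muts, windows, alpha=0.1)
            hits += any(t.flagged for t in tests)
        rate = hits / n_sims
        assert rate <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / n_sims)


class TestEndToEndRecovery:
    def test_planted_cluster_recovered_as_biased_region(self, clean_case, run_cfg):
        from hapsomatic.phasing import assign_all_snvs

        calls = assign_all_snvs(clean_case.observations, clean_case.mutations,
                                run_cfg)
        tests, regions = scan_genome(clean_case.mutations,
                                     clean_case.chrom_lengths,
                                     clean_case.phased_blocks, calls, run_cfg)
        biased = [r for r in regions if r.status == BIASED]
        assert biased, "planted cluster not recovered"
        cluster_muts = [m for m in clean_case.mutations
                        if clean_case.truth.mutations[m.id].in_planted_cluster]
        win = clean_case.config.planted_cluster.window_index
        assert all(win * 100_000 <= m.pos < (win + 1) * 100_000
                   for m in cluster_muts)
        assert any(r.region.chrom == "chr1"
                   and r.window.start == win * 100_000 for r in biased)
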