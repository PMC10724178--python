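import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hapsomatic.config import RunConfig
from hapsomatic.ordering import (
    CONSISTENT,
    DISCREPANT,
    SAME_CLONE,
    EqualVAFError,
    PairReadClassification,
    classify_pair_reads,
    clone_consistency,
    order_all_pairs,
    resolve_order,
)
from hapsomatic.simulate import SimConfig, simulate_cohort, simulate_nested_clone_pair
from hapsomatic.variants import SomaticMutation

MUT_HIGH = SomaticMutation("chr1", 1_000, "A", "C", 0.4)
MUT_LOW = SomaticMutation("chr1", 2_000, "G", "T", 0.2)


def obs_table(rows):
    return pd.DataFrame(rows, columns=["read_id", "haplotype_tag", "chrom",
                                       "pos", "allele"])


def make_obs(n_double=0, n_single_high=0, n_single_low=0, n_wild=0,
             extra_rows=()):
    rows, i = [], 0
    for count, (hi, lo) in [(n_double, ("A", "A")), (n_single_high, ("A", "R")),
                            (n_single_low, ("R", "A")), (n_wild, ("R", "R"))]:
        for _ in range(count):
            rows.append((f"r{i}", "1", "chr1", 1_000, hi))
            rows.append((f"r{i}", "1", "chr1", 2_000, lo))
            i += 1
    rows.extend(extra_rows)
    return obs_table(rows)


class TestClassifyPairReads:
    def test_direct_tally(self):
        obs = make_obs(n_double=3, n_single_high=4, n_single_low=0, n_wild=10)
        c = classify_pair_reads(MUT_HIGH, MUT_LOW, obs)
        assert (c.n_double, c.n_single_high, c.n_single_low, c.n_wild) == (3, 4, 0, 10)
        assert c.mut_high is MUT_HIGH

    def test_reads_covering_one_site_are_excluded(self):
        obs = make_obs(n_double=2, extra_rows=[("lone", "1", "chr1", 1_000, "A")])
        c = classify_pair_reads(MUT_HIGH, MUT_LOW, obs)
        assert c.n_double == 2 and c.n_single_high == 0

    def test_missing_observations_excluded(self):
        obs = make_obs(n_double=1, extra_rows=[
            ("rx", "1", "chr1", 1_000, "A"), ("rx", "1", "chr1", 2_000, "N")])
        c = classify_pair_reads(MUT_HIGH, MUT_LOW, obs)
        assert c.n_double == 1

    def test_equal_vafs_are_skipped(self):
        with pytest.raises(EqualVAFError):
            classify_pair_reads(MUT_HIGH,
                                SomaticMutation("chr1", 2_000, "G", "T", 0.4),
                                make_obs(n_double=3))

    def test_nested_fixture_never_shows_inconsistent_reads(self):
        for seed in range(5):
            obs = simulate_nested_clone_pair(0.4, 0.2, depth=50, seed=seed)
            high = SomaticMutation("chr1", 1_000, "A", "C", 0.4)
            low = SomaticMutation("chr1", 2_000, "G", "T", 0.2)
            c = classify_pair_reads(high, low, obs)
            assert c.n_single_low == 0


class TestResolveOrder:
    @pytest.mark.parametrize(
        "n_double, n_high, n_low, resolved",
        [
            (3, 3, 0, True),     # rule boundary
            (3, 3, 1, False),    # inconsistency
            (2, 5, 0, False),    # double-mutant floor
            (5, 2, 0, False),    # single-high floor
            (10, 10, 0, True),
        ],
    )
    def test_rule_boundaries(self, n_double, n_high, n_low, resolved):
        c = PairReadClassification(MUT_HIGH, MUT_LOW, n_double, n_high, n_low, 0)
        call = resolve_order(c)
        assert call.resolved is resolved
        assert call.first == (MUT_HIGH.id if resolved else None)

    @given(n_double=st.integers(0, 10), n_high=st.integers(0, 10))
    def test_monotone_in_supporting_reads(self, n_double, n_high):
        base = resolve_order(
            PairReadClassification(MUT_HIGH, MUT_LOW, n_double, n_high, 0, 0))
        more_double = resolve_order(
            PairReadClassification(MUT_HIGH, MUT_LOW, n_double + 1, n_high, 0, 0))
        more_high = resolve_order(
            PairReadClassification(MUT_HIGH, MUT_LOW, n_double, n_high + 1, 0, 0))
        one_low = resolve_order(
            PairReadClassification(MUT_HIGH, MUT_LOW, n_double, n_high, 1, 0))
        if base.resolved:
            assert more_double.resolved and more_high.resolved
        assert not one_low.resolved


class TestCloneConsistency:
    def _order_call(self):
        c = PairReadClassification(MUT_HIGH, MUT_LOW, 5, 5, 0, 0)
        return resolve_order(c)

    def _clone_table(self, ccf_high, ccf_low, same=False):
        return pd.DataFrame({
            "mutation_id": [MUT_HIGH.id, MUT_LOW.id],
            "clone_id": ["c1", "c1" if same else "c2"],
            "ccf": [ccf_high, ccf_low],
        })

    def test_higher_prevalence_first_is_consistent(self):
        rows, summary = clone_consistency([self._order_call()],
                                          self._clone_table(0.9, 0.4))
        assert rows[0]["status"] == CONSISTENT
        assert summary[CONSISTENT] == 1

    def test_lower_prevalence_first_is_discrepant(self):
        rows, _ = clone_consistency([self._order_call()],
                                    self._clone_table(0.3, 0.8))
        assert rows[0]["status"] == DISCREPANT

    def test_shared_clone(self):
        rows, _ = clone_consistency([self._order_call()],
                                    self._clone_table(0.9, 0.9, same=True))
        assert rows[0]["status"] == SAME_CLONE

    def test_equal_prevalence_across_clones_is_flagged_ambiguous(self):
        rows, _ = clone_consistency([self._order_call()],
                                    self._clone_table(0.5, 0.5))
        assert rows[0]["status"] == DISCREPANT and rows[0]["ambiguous"]

    def test_missing_mutation_drops_pair(self):
        table = self._clone_table(0.9, 0.4).iloc[:1]
        rows, summary = clone_consistency([self._order_call()], table)
        assert rows == [] and summary["dropped"] == 1


class TestTruthConsistency:
    def test_no_false_orders_on_error_free_cohorts(self, run_cfg):
        """Resolved order calls never contradict the simulated lineage, and
        deeper sequencing resolves at least as many pairs."""
        resolved_by_depth = {}
        for depth in (12, 24, 48):
            case = simulate_cohort(SimConfig(
                seed=21, n_chromosomes=1, chrom_length_bp=1_000_000,
                mutation_rate_per_mb=150.0, read_depth=float(depth),
                tag_dropout_rate=0.0, methylation_depth=0.0, n_svs=0))
            calls = order_all_pairs(case.mutations, case.observations, run_cfg)
            n_false = 0
            for call in calls:
                if not call.resolved:
                    continue
                hi, lo = call.pair_ids
                t_hi = case.truth.mutations[hi]
                t_lo = case.truth.mutations[lo]
                assert t_hi.haplotype == t_lo.haplotype
                if t_hi.order_index > t_lo.order_index:
                    n_false += 1
            assert n_false == 0
            resolved_by_depth[depth] = sum(c.resolved for c in calls)
        assert resolved_by_depth[48] >= resolved_by_depth[12]

    def test_truth_clone_table_yields_zero_discrepant(self, run_cfg):
        case = simulate_cohort(SimConfig(
            seed=22, n_chromosomes=1, chrom_length_bp=1_000_000,
            mutation_rate_per_mb=150.0, read_depth=48.0,
            tag_dropout_rate=0.0, methylation_depth=0.0, n_svs=0))
        calls = order_all_pairs(case.mutations, case.observations, run_cfg)
        _, summary = clone_consistency(calls, case.clone_table)
        assert summary[DISCREPANT] == 0
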