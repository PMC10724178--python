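import numpy as np
import pandas as pd
import pytest

from hapsomatic.intervals import GenomicInterval
from hapsomatic.methylation import (
    annotation_rates,
    genome_median,
    site_rates,
    tumor_normal_delta,
    window_rates,
)
from hapsomatic.simulate import SimConfig, simulate_cohort


def calls(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "state"])


class TestSiteRates:
    def test_three_of_four_methylated(self):
        df = calls([("r1", "chr1", 10, "M"), ("r2", "chr1", 10, "M"),
                    ("r3", "chr1", 10, "M"), ("r4", "chr1", 10, "U")])
        rates = site_rates(df)
        assert len(rates) == 1
        assert rates.iloc[0]["rate"] == pytest.approx(0.75)
        assert rates.iloc[0]["n_calls"] == 4

    def test_uncovered_sites_absent(self):
        assert site_rates(calls([])).empty

    def test_duplicated_table_gives_identical_rates(self):
        df = calls([("r1", "chr1", 10, "M"), ("r2", "chr1", 10, "U"),
                    ("r1", "chr1", 30, "M")])
        a = site_rates(df)
        b = site_rates(pd.concat([df, df], ignore_index=True))
        pd.testing.assert_series_equal(a["rate"], b["rate"])


class TestWindowRates:
    def test_unweighted_mean_of_site_rates(self):
        # site 10 fully methylated (depth 2), site 30 half (depth 4):
        # the window mean is (1.0 + 0.5)/2, not call-pooled 4/6
        df = calls([("a", "chr1", 10, "M"), ("b", "chr1", 10, "M"),
                    ("a", "chr1", 30, "M"), ("b", "chr1", 30, "M"),
                    ("c", "chr1", 30, "U"), ("d", "chr1", 30, "U")])
        wins = window_rates(site_rates(df), {"chr1": 50_000}, 50_000)
        assert len(wins) == 1
        assert wins[0].mean_rate == pytest.approx(0.75)
        assert wins[0].n_cpgs_covered == 2

    def test_empty_window_carries_null_rate(self):
        df = calls([("a", "chr1", 10, "M")])
        wins = window_rates(site_rates(df), {"chr1": 100_000}, 50_000)
        assert wins[0].mean_rate == pytest.approx(1.0)
        assert wins[1].mean_rate is None

    def test_window_means_invariant_to_call_order_and_chunking(self):
        rng = np.random.default_rng(0)
        df = calls([(f"r{i}", "chr1", int(p), s)
                    for i, (p, s) in enumerate(zip(
                        rng.integers(0, 100_000, 500),
                        rng.choice(["M", "U"], 500)))])
        base = window_rates(site_rates(df), {"chr1": 100_000}, 50_000)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        chunked = pd.concat([shuffled.iloc[:100], shuffled.iloc[100:]],
                            ignore_index=True)
        other = window_rates(site_rates(chunked), {"chr1": 100_000}, 50_000)
        assert [w.mean_rate for w in base] == pytest.approx(
            [w.mean_rate for w in other])

    def test_genome_median(self):
        df = calls([("a", "chr1", 10, "M"),
                    ("a", "chr1", 60_000, "U"),
                    ("a", "chr1", 110_000, "M"), ("b", "chr1", 110_000, "U")])
        wins = window_rates(site_rates(df), {"chr1": 150_000}, 50_000)
        assert genome_median(wins) == pytest.approx(0.5)
        assert genome_median([]) is None


class TestTumorNormalDelta:
    def test_identical_samples_have_zero_delta(self):
        df = calls([("a", "chr1", 10, "M"), ("b", "chr1", 60_000, "U")])
        wins = window_rates(site_rates(df), {"chr1": 100_000}, 50_000)
        deltas = tumor_normal_delta(wins, wins)
        assert all(w.delta_vs_normal == 0.0 for w in deltas)

    def test_uncovered_side_gives_null_delta(self):
        t = window_rates(site_rates(calls([("a", "chr1", 10, "M")])),
                         {"chr1": 100_000}, 50_000)
        n = window_rates(site_rates(calls([("a", "chr1", 60_000, "M")])),
                         {"chr1": 100_000}, 50_000)
        deltas = tumor_normal_delta(t, n)
        assert all(w.delta_vs_normal is None for w in deltas)


class TestAnnotationRates:
    def test_cpg_contributes_to_every_containing_class(self):
        df = calls([("a", "chr1", 100, "M"), ("b", "chr1", 100, "M"),
                    ("a", "chr1", 900, "U")])
        rates = site_rates(df)
        annos = {
            "LINE1": [GenomicInterval("chr1", 0, 500)],
            "promoter": [GenomicInterval("chr1", 50, 150),
                         GenomicInterval("chr1", 800, 1_000)],
            "empty": [GenomicInterval("chr2", 0, 100)],
        }
        out = annotation_rates(rates, annos)
        assert out["LINE1"] == pytest.approx(1.0)
        assert out["promoter"] == pytest.approx(0.5)
        assert out["empty"] is None

    def test_overlapping_features_count_site_once(self):
        df = calls([("a", "chr1", 100, "M"), ("b", "chr1", 100, "U")])
        out = annotation_rates(site_rates(df), {
            "dup": [GenomicInterval("chr1", 0, 200),
                    GenomicInterval("chr1", 50, 150)]})
        assert out["dup"] == pytest.approx(0.5)


class TestPlantedRateRecovery:
    def test_planted_window_rates_recovered(self):
        """Window means land within 3 binomial standard deviations of the
        planted rates for at least 99% of windows (small-genome version of
        the acceptance-scale run)."""
        case = simulate_cohort(SimConfig(
            seed=13, n_chromosomes=1, chrom_length_bp=2_000_000,
            mutation_rate_per_mb=0.0, n_svs=0,
            cpg_spacing_bp=100, methylation_depth=20.0,
            methylation_profile=((0, 0.3), (10, 0.9))))
        rates = site_rates(case.methylation_calls)
        wins = window_rates(rates, case.chrom_lengths, 50_000)
        ok = 0
        for w in wins:
            widx = w.window.start // 50_000
            truth = case.truth.window_methylation[(w.window.chrom, widx)]
            n_calls = len(case.methylation_calls[
                (case.methylation_calls["chrom"] == w.window.chrom)
                & (case.methylation_calls["pos"] >= w.window.start)
                & (case.methylation_calls["pos"] < w.window.end)])
            sd = np.sqrt(truth * (1 - truth) / n_calls)
            ok += abs(w.mean_rate - truth) <= 3 * sd + 1e-9
        assert ok / len(wins) >= 0.99
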