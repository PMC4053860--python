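import numpy as np
import pandas as pd
import pytest

from epitwin.integration import (
    assign_probes_to_tss,
    binned_mean_ci,
    count_fragments,
    expression_ratio_series,
    expression_shift_test,
    normalize_counts,
    promoter_window,
    spearman,
)
from epitwin.types import CountTrack, DeltaTrack, GenomicInterval, ProbeRecord


class TestPromoterWindow:
    def test_symmetric_window(self):
        w = promoter_window(GenomicInterval("chr1", 5000, 5001))
        assert (w.start, w.end) == (4000, 6000)

    def test_clipped_at_zero(self):
        w = promoter_window(GenomicInterval("chr1", 300, 301))
        assert (w.start, w.end) == (0, 1300)

    def test_minus_strand_anchor_is_interval_end(self):
        w = promoter_window(GenomicInterval("chr1", 2000, 9000, strand="-"))
        assert (w.start, w.end) == (8999 - 1000, 8999 + 1000)


class TestAssignProbes:
    tss = [
        GenomicInterval("chr1", 1000, 1001, name="T1"),
        GenomicInterval("chr1", 2000, 2001, name="T2"),
    ]

    def test_probe_at_anchor(self):
        probes = [ProbeRecord("p", "chr1", 1000)]
        assert assign_probes_to_tss(probes, self.tss) == {"p": "T1"}

    def test_too_far_unassigned(self):
        probes = [ProbeRecord("p", "chr1", 4000)]
        assert assign_probes_to_tss(probes, self.tss) == {}

    def test_equidistant_tie_goes_to_smaller_coordinate(self):
        probes = [ProbeRecord("p", "chr1", 1500)]
        assert assign_probes_to_tss(probes, self.tss) == {"p": "T1"}

    def test_nearest_wins(self):
        probes = [ProbeRecord("p", "chr1", 1800)]
        assert assign_probes_to_tss(probes, self.tss) == {"p": "T2"}

    def test_chromosome_must_match(self):
        probes = [ProbeRecord("p", "chr9", 1000)]
        assert assign_probes_to_tss(probes, self.tss) == {}


class TestCountFragments:
    def test_partial_overlap_counts(self):
        track = count_fragments(
            [GenomicInterval("chr1", 90, 190)],
            [GenomicInterval("chr1", 100, 150, name="r")],
        )
        assert track.raw_counts[0] == 1

    def test_half_open_adjacency_does_not_count(self):
        track = count_fragments(
            [GenomicInterval("chr1", 150, 200)],
            [GenomicInterval("chr1", 100, 150, name="r")],
        )
        assert track.raw_counts[0] == 0

    def test_containing_fragment_counts_once(self):
        track = count_fragments(
            [GenomicInterval("chr1", 0, 1000)],
            [GenomicInterval("chr1", 100, 150, name="r")],
        )
        assert track.raw_counts[0] == 1

    def test_matches_quadratic_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            frags = [
                GenomicInterval(
                    rng.choice(["chr1", "chr2"]), int(s), int(s) + int(l)
                )
                for s, l in zip(
                    rng.integers(0, 5000, 1000), rng.integers(50, 400, 1000)
                )
            ]
            regions = [
                GenomicInterval("chr1" if i % 2 else "chr2", int(s), int(s) + 120,
                                name=f"r{i}")
                for i, s in enumerate(rng.integers(0, 5000, 50))
            ]
            track = count_fragments(frags, regions)
            for region, got in zip(regions, track.raw_counts):
                expected = sum(1 for f in frags if f.overlaps(region))
                assert got == expected


class TestNormalize:
    def track(self, counts):
        return CountTrack(
            region_ids=np.array([f"r{i}" for i in range(len(counts))], dtype=object),
            raw_counts=np.array(counts), mark="H2A.Z", sample_id="s",
        )

    def test_identity_at_matching_scale(self):
        t = normalize_counts(self.track([50, 0]), library_total=10_000_000)
        assert list(t.norm_scores) == [50.0, 0.0]

    def test_linearity_in_library_total(self):
        a = normalize_counts(self.track([40]), library_total=1_000_000)
        b = normalize_counts(self.track([40]), library_total=2_000_000)
        assert a.norm_scores[0] == pytest.approx(2 * b.norm_scores[0])

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            normalize_counts(self.track([1]), library_total=0)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3]).statistic == -1.0

    def test_rank_formula_example(self):
        # ranks y = (2,1,4,3,5); sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, 3, np.nan], [1, 2, 3, 100])
        assert res.statistic == 1.0 and res.extras["n"] == 3

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestBinnedMeanCI:
    def test_constant_response_degenerate_ci(self):
        d = np.linspace(-0.2, 0.2, 50)
        series = binned_mean_ci(d, np.full(50, 3.0), seed=1)
        for b in range(len(series.n)):
            if series.has_ci[b]:
                assert series.ci_low[b] == series.ci_high[b] == 3.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        d, r = rng.uniform(-0.3, 0.3, 200), rng.normal(size=200)
        a = binned_mean_ci(d, r, seed=9)
        b = binned_mean_ci(d, r, seed=9)
        assert np.array_equal(a.ci_low, b.ci_low, equal_nan=True)

    def test_small_bins_flagged_without_interval(self):
        d = np.array([0.01, 0.02, 0.30])
        r = np.array([1.0, 2.0, 3.0])
        series = binned_mean_ci(d, r, bin_width=0.05, min_bin_n=3)
        assert not series.has_ci[-1] and np.isnan(series.ci_low[-1])

    def test_matches_independent_bootstrap_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5.0, 2.0, 80)
        d = np.zeros(80)  # single bin
        series = binned_mean_ci(d, vals, bin_width=0.05, n_boot=2000, seed=4)

        # independent percentile-bootstrap re-implementation (loop form)
        oracle_rng = np.random.default_rng(99)
        means = []
        for _ in range(4000):
            means.append(np.mean(oracle_rng.choice(vals, size=len(vals))))
        lo, hi = np.percentile(means, [2.5, 97.5])
        b = int(np.flatnonzero(series.n)[0])
        mc_tol = 3.0 * np.std(means) / np.sqrt(len(vals))
        assert series.ci_low[b] == pytest.approx(lo, abs=mc_tol)
        assert series.ci_high[b] == pytest.approx(hi, abs=mc_tol)

    def test_interval_coverage_near_nominal(self):
        # empirical coverage of the true bin mean across simulated datasets
        rng = np.random.default_rng(8)
        hits = 0
        n_sets = 200
        for _ in range(n_sets):
            vals = rng.normal(1.0, 1.0, 60)
            series = binned_mean_ci(np.zeros(60), vals, n_boot=500,
                                    seed=int(rng.integers(2**31)))
            b = int(np.flatnonzero(series.n)[0])
            if series.ci_low[b] <= 1.0 <= series.ci_high[b]:
                hits += 1
        assert hits / n_sets >= 0.90

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            binned_mean_ci(np.array([]), np.array([]))


class TestExpressionAnalyses:
    def delta_track(self, ids, deltas):
        n = len(ids)
        return DeltaTrack(
            probe_ids=np.array(ids, dtype=object),
            chromosomes=np.array(["chr1"] * n, dtype=object),
            positions=np.arange(n, dtype=np.int64) * 100,
            deltas=np.asarray(deltas, dtype=float),
        )

    def test_equal_expression_gives_zero_ratio(self):
        ids = [f"p{i}" for i in range(40)]
        track = self.delta_track(ids, np.linspace(-0.2, 0.2, 40))
        expr = pd.Series(np.linspace(0.5, 8, 40), index=[f"T{i}" for i in range(40)])
        assignment = {f"p{i}": f"T{i}" for i in range(40)}
        series = expression_ratio_series(track, expr, expr, assignment, seed=0)
        assert np.allclose(series.mean[series.n > 0], 0.0)

    def test_empty_assignment_is_error(self):
        track = self.delta_track(["p0"], [0.1])
        with pytest.raises(ValueError):
            expression_ratio_series(track, pd.Series(dtype=float),
                                    pd.Series(dtype=float), {})

    def test_shift_detected_when_dmr_genes_low(self):
        rng = np.random.default_rng(5)
        low = {f"L{i}" for i in range(60)}
        high = {f"H{i}" for i in range(60)}
        expr = pd.Series(
            {**{t: rng.uniform(0.01, 0.9) for t in low},
             **{t: rng.uniform(2, 50) for t in high}}
        )
        res = expression_shift_test(low, low | high, expr)
        assert res.p_value < 0.01
        assert res.extras["frac_low_expression_dmr"] > \
            res.extras["frac_low_expression_other"]

    def test_constant_expression_no_shift(self):
        expr = pd.Series({t: 2.0 for t in ("a", "b", "c", "d")})
        res = expression_shift_test({"a"}, {"a", "b", "c", "d"}, expr)
        assert res.p_value == 1.0

    def test_set_validation(self):
        expr = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            expression_shift_test(set(), {"a"}, expr)
        with pytest.raises(ValueError):
            expression_shift_test({"z"}, {"a"}, expr)
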