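"""Generator contracts: determinism, planted structure, couplings."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from epitwin.enrichment import classify_chromatin_states
from epitwin.qc import filter_probes
from epitwin.simulate import (
    SimulationConfig,
    generate_age_correlations,
    generate_chip_counts,
    generate_cohort,
    generate_expression,
)


def small_config(**kw):
    base = dict(seed=3, n_probes=4000, n_pairs=2, n_tech_replicates=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminismAndConservation:
    def test_identical_seed_identical_output(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        for key in a.matrices:
            assert a.matrices[key].values.equals(b.matrices[key].values)
        assert a.truth.epialleles.equals(b.truth.epialleles)
        assert [r.probe_id for r in a.manifest] == [r.probe_id for r in b.manifest]

    def test_different_seed_different_output(self):
        a = generate_cohort(small_config(seed=3))
        b = generate_cohort(small_config(seed=4))
        assert not a.matrix(2, "dense").values.equals(b.matrix(2, "dense").values)

    def test_each_epiallele_planted_once(self):
        c = generate_cohort(small_config(epiallele_rate=0.2))
        e = c.truth.epialleles
        assert not e.duplicated(subset=["probe_id", "individual_id"]).any()
        manifest_ids = {r.probe_id for r in c.manifest}
        assert set(e["probe_id"]) <= manifest_ids

    def test_sparse_platform_is_strict_promoter_biased_subset(self):
        c = generate_cohort(small_config())
        dense_ids = {r.probe_id for r in c.manifest}
        sparse_ids = set(c.sparse_probe_ids)
        assert sparse_ids < dense_ids
        feature_of = {r.probe_id: r.feature_class for r in c.manifest}
        assert all(feature_of[p] == "promoter" for p in sparse_ids)


class TestPlantedMethylation:
    def test_noise_free_twins_are_identical_without_planting(self):
        cfg = small_config(
            tech_noise_sd=1e-5, epiallele_rate=0.0, genetic_rate=0.0,
            variable_probe_rate=0.0,
        )
        c = generate_cohort(cfg)
        m = c.matrix(2, "dense")
        for pid, (a, b) in c.truth.pairs.items():
            col_a = m.beta(f"{a}_t2_dense_r1").to_numpy()
            col_b = m.beta(f"{b}_t2_dense_r1").to_numpy()
            assert np.nanmax(np.abs(col_a - col_b)) < 1e-3

    def test_planted_epialleles_realize_their_delta(self):
        cfg = small_config(epiallele_rate=0.1, epiallele_delta=0.15,
                           temporal_stability=1.0, genetic_rate=0.0,
                           variable_probe_rate=0.0)
        c = generate_cohort(cfg)
        m = c.matrix(2, "dense")
        diffs = []
        for r in c.truth.epialleles.itertuples():
            a, b = c.truth.pairs[r.pair_id]
            other = b if r.individual_id == a else a
            d = (
                m.beta(f"{r.individual_id}_t2_dense_r1").loc[r.probe_id]
                - m.beta(f"{other}_t2_dense_r1").loc[r.probe_id]
            )
            diffs.append(abs(d))
        assert np.mean(diffs) >= 0.10

    def test_intra_pair_correlation_exceeds_inter_pair(self):
        c = generate_cohort(small_config(genetic_rate=0.08, genetic_delta=0.15))
        m = c.matrix(2, "dense")
        (p1a, p1b), (p2a, p2b) = c.truth.pairs.values()

        def corr(x, y):
            a = m.beta(f"{x}_t2_dense_r1")
            b = m.beta(f"{y}_t2_dense_r1")
            return a.corr(b)

        assert corr(p1a, p1b) > corr(p1a, p2a)
        assert corr(p2a, p2b) > corr(p1b, p2b)

    def test_temporal_stability_zero_removes_epialleles_at_t2(self):
        cfg = small_config(epiallele_rate=0.1, temporal_stability=0.0)
        c = generate_cohort(cfg)
        assert not c.truth.epialleles["persists_t2"].any()


class TestChipCounts:
    def test_zero_coupling_gives_no_correlation(self):
        cfg = small_config(n_probes=8000, meth_chip_coupling=0.0)
        c = generate_cohort(cfg)
        m = c.matrix(2, "dense")
        ct = generate_chip_counts(c.truth, m, "H2A.Z", cfg)
        rho = spearmanr(m.beta(m.sample_ids[0]).to_numpy(), ct.scores).statistic
        assert abs(rho) < 0.1

    def test_configured_coupling_is_realized(self):
        cfg = small_config(n_probes=8000, meth_chip_coupling=-0.6)
        c = generate_cohort(cfg)
        m = c.matrix(2, "dense")
        ct = generate_chip_counts(c.truth, m, "H2A.Z", cfg)
        rho = spearmanr(m.beta(m.sample_ids[0]).to_numpy(), ct.scores).statistic
        assert -0.7 <= rho <= -0.5

    def test_k27_counts_recover_truth_state(self):
        # strong separation: hi/lo count modes far apart, low dispersion
        cfg = small_config(n_probes=8000, nb_dispersion=0.02,
                           chip_mu_hi=400, chip_mu_lo=4)
        c = generate_cohort(cfg)
        m = c.matrix(2, "dense")
        k4 = generate_chip_counts(c.truth, m, "H3K4me3", cfg)
        k27 = generate_chip_counts(c.truth, m, "H3K27me3", cfg)
        truth_states = c.truth.promoters.set_index("tss_id")["chromatin_state"]
        q4 = 1 - truth_states.str.startswith("K4hi").mean()
        q27 = 1 - truth_states.str.contains("K27hi").mean()
        called = classify_chromatin_states(k4, k27, hi_quantile=(q4, q27))
        called = called.set_index("tss_id")["state"].loc[truth_states.index]
        k27hi_truth = truth_states.str.contains("K27hi")
        k27hi_called = called.str.contains("K27hi")
        assert (k27hi_called[k27hi_truth]).mean() >= 0.90
        assert (called == truth_states).mean() >= 0.90

    def test_unknown_mark_rejected(self):
        c = generate_cohort(small_config())
        with pytest.raises(ValueError):
            generate_chip_counts(c.truth, c.matrix(2, "dense"), "H3K9me3",
                                 c.config)


class TestExpression:
    def test_tier_bounds_are_forced(self):
        c_high = generate_cohort(small_config(high_expr_fraction=1.0,
                                              epiallele_rate=0.0))
        e = generate_expression(c_high.truth, c_high.config)
        assert float(e.values.min().min()) >= 1.0
        c_low = generate_cohort(small_config(high_expr_fraction=0.0,
                                             epiallele_rate=0.0))
        e = generate_expression(c_low.truth, c_low.config)
        assert float(e.values.max().max()) < 1.0

    def test_mixed_tiers_recover_configured_means(self):
        # moderate within-tier spread keeps the sample-mean check tight
        cfg = small_config(n_probes=16000, epiallele_rate=0.0,
                           expr_ind_sd=0.0, expr_log_sd=0.5)
        c = generate_cohort(cfg)
        e = generate_expression(c.truth, cfg)
        tier = c.truth.promoters.set_index("tss_id")["expression_tier"]
        mean_fpkm = e.mean_fpkm()
        high = mean_fpkm[tier == "high"].mean()
        low = mean_fpkm[tier == "low"].mean()
        assert abs(high - cfg.expr_high_mean) / cfg.expr_high_mean < 0.10
        assert abs(low - cfg.expr_low_mean) / cfg.expr_low_mean < 0.10


class TestAgeScores:
    def test_top_scores_are_exactly_the_designated_set(self):
        cfg = small_config(variable_probe_rate=0.05, n_age_top=100,
                           age_overlap=1.0)
        c = generate_cohort(cfg)
        scores, designated = generate_age_correlations(c.truth, c.manifest, cfg)
        top = set(scores.sort_values(ascending=False).index[:100])
        assert top == set(designated)
        assert set(designated) <= c.truth.planted_variability_probes()

    def test_overlap_zero_avoids_planted_probes(self):
        cfg = small_config(variable_probe_rate=0.05, n_age_top=100,
                           age_overlap=0.0)
        c = generate_cohort(cfg)
        _, designated = generate_age_correlations(c.truth, c.manifest, cfg)
        assert not set(designated) & c.truth.planted_variability_probes()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(tech_noise_sd=0.0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(epiallele_rate=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(epiallele_delta=-0.1).validate()
    with pytest.raises(ValueError):
        # too few probes to host the requested epialleles
        generate_cohort(
            SimulationConfig(seed=0, n_probes=64, cgi_cluster_size=8,
                             n_pairs=1, epiallele_rate=1.0,
                             lowexpr_targeting=1.0)
        )
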