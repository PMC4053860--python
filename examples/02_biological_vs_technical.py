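"""Does co-twin variation exceed technical noise?

Two twin pairs measured in triplicate. The statistic is the ratio of mean
iiDMR call counts (co-twin comparisons / replicate comparisons); the null
permutes the biological/technical labels over the pooled comparisons.
"""

from epitwin import (
    SimulationConfig,
    filter_probes,
    generate_cohort,
    technical_vs_biological_test,
)

cfg = SimulationConfig(
    seed=11, n_probes=10_000, n_pairs=2, n_tech_replicates=3,
    epiallele_rate=0.05, epiallele_delta=0.15,
    genetic_rate=0.0, variable_probe_rate=0.0,
)
cohort = generate_cohort(cfg)
kept, _ = filter_probes(cohort.manifest)
res = technical_vs_biological_test(
    cohort.matrix(2, "dense"), cohort.sheet, kept, n_perm=999, seed=0
)
print(f"mean co-twin calls:     {res.extras['mean_biological_calls']:.1f}")
print(f"mean replicate calls:   {res.extras['mean_technical_calls']:.1f}")
print(f"biological/technical ratio = {res.statistic:.2f}")
print(f"permutation p = {res.p_value:.4g} (resolution {res.extras['p_resolution']:.4g})")

# With twin-specific epialleles planted at 5% of promoters (delta 0.15),
# co-twin comparisons carry real differences that replicates lack, so the
# ratio is well above 1 and the permutation p sits at its resolution bound.
# With no planting the ratio hovers around 1 and p is uniform.
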