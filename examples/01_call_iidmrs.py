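"""Call iiDMRs between co-twins on a synthetic cohort.

Builds a 20k-probe, 5-pair twin cohort, applies probe QC, and calls
inter-individual DMRs (runs of >=2 adjacent probes with a same-direction
|delta beta| >= 0.05 within 500 bp) for every co-twin comparison, then
checks the calls against the planted truth.
"""

from epitwin import (
    SimulationConfig,
    call_iidmrs,
    comparison_plan,
    compute_deltas,
    dmr_probe_ids,
    filter_probes,
    generate_cohort,
)

cohort = generate_cohort(SimulationConfig(seed=1, n_probes=20_000, n_pairs=5))
kept, report = filter_probes(cohort.manifest)
print(f"probe QC: kept {report.n_kept}/{report.n_input} ({report.removed})")

matrix = cohort.matrix(2, "dense")
plan = comparison_plan(cohort.sheet, time_point=2, platform="dense")
truth = cohort.truth.epialleles
kept_ids = {r.probe_id for r in kept}

for comp in [c for c in plan if c.label == "intra_pair"]:
    track = compute_deltas(matrix, comp.sample_a, comp.sample_b, kept)
    calls = call_iidmrs(track)
    called = dmr_probe_ids(calls)
    rows = truth[
        truth["individual_id"].isin([comp.individual_a, comp.individual_b])
        & truth["persists_t2"]
    ]
    planted = set(rows["probe_id"]) & kept_ids
    recall = len(called & planted) / len(planted)
    print(
        f"{comp.individual_a} vs {comp.individual_b}: {len(calls)} iiDMRs, "
        f"{len(called)} member probes, planted-probe recall {recall:.2f}"
    )

# Each co-twin comparison finds the epialleles planted in either twin
# (recall near 1 at delta 0.15 over noise 0.015) plus a few calls from the
# planted continuous variability; unrelated-individual comparisons would
# additionally pick up the pair-shared (genetic-like) differences.
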