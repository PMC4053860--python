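"""Cohort-scale methylation variability statistics.

Implements the probe-level RMS (root-mean-square) intra-pair / inter-pair
difference profile, the pair-permutation construction behind the inter-pair
measure, and the permutation test asking whether biological (co-twin)
variation exceeds technical (replicate) variation in iiDMR call counts.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dmr import call_iidmrs, compute_deltas
from .types import MethylationMatrix, ProbeRecord, SampleSheet, StatResult


def _one_sample_per_individual(
    matrix: MethylationMatrix, sheet: SampleSheet
) -> dict[str, str]:
    """individual -> the first (replicate-sorted) sample present in the matrix."""
    cols = set(matrix.sample_ids)
    out = {}
    for ind in sheet.individuals():
        samples = [s for s in sheet.samples_for(ind) if s in cols]
        if samples:
            out[ind] = samples[0]
    return out


def rms_profile(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    n_permutations: int = 20,
    seed: int = 0,
    include_inter: bool = True,
) -> pd.DataFrame:
    """Per-probe RMS intra-pair (and permuted inter-pair) beta differences.

    rms_intra(probe) = sqrt(mean over complete pairs of (beta_t1 - beta_t2)^2),
    with pairs missing data at a probe dropped from that probe's mean; probes
    usable in fewer than two pairs are omitted. The inter-pair measure
    repeats the computation on ``n_permutations`` seeded derangement-style
    re-pairings (no individual keeps its true co-twin) and averages the mean
    squared differences before the square root.
    """
    sample_of = _one_sample_per_individual(matrix, sheet)
    complete = [
        (a, b)
        for mem in sheet.pairs().values()
        if len(mem) == 2
        for a, b in [(mem[0], mem[1])]
        if mem[0] in sample_of and mem[1] in sample_of
    ]
    if len(complete) < 2:
        raise ValueError("rms_profile requires >= 2 complete twin pairs")

    def _mean_sq(pairings: Sequence[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        sq_sum = np.zeros(matrix.shape[0])
        counts = np.zeros(matrix.shape[0])
        for a, b in pairings:
            d = (
                matrix.values[sample_of[a]].to_numpy(dtype=float)
                - matrix.values[sample_of[b]].to_numpy(dtype=float)
            )
            ok = ~np.isnan(d)
            sq_sum[ok] += d[ok] ** 2
            counts[ok] += 1
        return sq_sum, counts

    sq, n_pairs = _mean_sq(complete)
    usable = n_pairs >= 2
    rms_intra = np.full(matrix.shape[0], np.nan)
    rms_intra[usable] = np.sqrt(sq[usable] / n_pairs[usable])

    out = pd.DataFrame(
        {"probe_id": matrix.probe_ids, "rms_intra": rms_intra}
    )
    if include_inter:
        inds = sorted(sample_of)
        sq_tot = np.zeros(matrix.shape[0])
        n_tot = np.zeros(matrix.shape[0])
        for k in range(n_permutations):
            pairings = permute_pairs(sheet, seed=seed + k, individuals=inds)
            sq_k, n_k = _mean_sq(pairings)
            sq_tot += sq_k
            n_tot += n_k
        inter_ok = n_tot >= 2
        rms_inter = np.full(matrix.shape[0], np.nan)
        rms_inter[inter_ok] = np.sqrt(sq_tot[inter_ok] / n_tot[inter_ok])
        out["rms_inter"] = rms_inter
    return out[usable].reset_index(drop=True)


def permute_pairs(
    sheet: SampleSheet,
    seed: int,
    individuals: Optional[Sequence[str]] = None,
) -> list[tuple[str, str]]:
    """One derangement-style re-pairing: no individual keeps its co-twin.

    Deterministic given the seed; raises if fewer than two pairs are
    available (no valid re-pairing exists).
    """
    pairs = sheet.pairs()
    if individuals is not None:
        allowed = set(individuals)
        pairs = {
            pid: [i for i in mem if i in allowed] for pid, mem in pairs.items()
        }
        pairs = {pid: mem for pid, mem in pairs.items() if mem}
    if len(pairs) < 2:
        raise ValueError("pair permutation requires >= 2 pairs")
    inds = sorted(i for mem in pairs.values() for i in mem)
    if len(inds) < 4 or len(inds) % 2:
        # odd cohort: drop the lexicographically last individual
        if len(inds) % 2:
            inds = inds[:-1]
        if len(inds) < 4:
            raise ValueError("not enough individuals to re-pair across pairs")
    pair_of = {i: pid for pid, mem in pairs.items() for i in mem}
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        order = list(rng.permutation(inds))
        candidate = [
            (order[i], order[i + 1]) for i in range(0, len(order) - 1, 2)
        ]
        if all(pair_of[a] != pair_of[b] for a, b in candidate):
            return [tuple(sorted(p)) for p in candidate]
    raise RuntimeError("failed to find a cross-pair re-pairing")  # pragma: no cover


def comparison_call_counts(
    matrix: MethylationMatrix,
    kept: Sequence[ProbeRecord],
    sample_pairs: Sequence[tuple[str, str]],
    min_delta: float = 0.05,
    min_probes: int = 2,
    max_gap: int = 500,
) -> list[int]:
    """iiDMR call count for each (sample_a, sample_b) comparison."""
    counts = []
    for a, b in sample_pairs:
        track = compute_deltas(matrix, a, b, kept)
        counts.append(
            len(call_iidmrs(track, min_delta=min_delta, min_probes=min_probes,
                            max_gap=max_gap))
        )
    return counts


def technical_vs_biological_test(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    kept: Sequence[ProbeRecord],
    caller_params: Optional[dict] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> StatResult:
    """Does co-twin variation exceed technical-replicate variation?

    The statistic is the ratio of the mean iiDMR call count over all
    co-twin comparisons (every cross-replicate pairing of the two co-twins)
    to the mean count over all technical comparisons (replicate pairs
    within each individual). The null shuffles the biological/technical
    labels over the pooled comparisons and recomputes the ratio; the
    p-value uses the add-one estimator, so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    caller_params = caller_params or {}
    cols = set(matrix.sample_ids)

    bio_pairs: list[tuple[str, str]] = []
    tech_pairs: list[tuple[str, str]] = []
    inds_with_reps: set[str] = set()
    for pid, members in sheet.pairs().items():
        reps = {
            ind: [s for s in sheet.samples_for(ind) if s in cols] for ind in members
        }
        for ind, ss in reps.items():
            if len(ss) >= 2:
                inds_with_reps.add(ind)
            for i in range(len(ss)):
                for j in range(i + 1, len(ss)):
                    tech_pairs.append((ss[i], ss[j]))
        if len(members) == 2:
            for sa in reps[members[0]]:
                for sb in reps[members[1]]:
                    bio_pairs.append((sa, sb))
    rep_pairs = {sheet.pair_of(i) for i in inds_with_reps}
    if len(inds_with_reps) < 2 or len(rep_pairs) < 2:
        raise ValueError(
            "test requires technical replicates for >= 2 individuals from "
            ">= 2 pairs"
        )
    if not bio_pairs:
        raise ValueError("no co-twin comparisons available")

    bio_counts = np.array(
        comparison_call_counts(matrix, kept, bio_pairs, **caller_params), dtype=float
    )
    tech_counts = np.array(
        comparison_call_counts(matrix, kept, tech_pairs, **caller_params), dtype=float
    )

    def ratio(bio: np.ndarray, tech: np.ndarray) -> float:
        bio_mean, tech_mean = bio.mean(), tech.mean()
        if tech_mean == 0:
            # no false-positive calls at all: undefined ratio; +inf when
            # biological calls exist, neutral 1 when neither side has any
            return np.inf if bio_mean > 0 else 1.0
        return float(bio_mean / tech_mean)

    observed = ratio(bio_counts, tech_counts)
    pooled = np.concatenate([bio_counts, tech_counts])
    n_bio = len(bio_counts)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if ratio(perm[:n_bio], perm[n_bio:]) >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return StatResult(
        statistic_name="biological_vs_technical_call_ratio",
        statistic=observed,
        p_value=p,
        n_resamples=n_perm,
        seed=seed,
        extras={
            "mean_biological_calls": float(bio_counts.mean()),
            "mean_technical_calls": float(tech_counts.mean()),
            "n_biological_comparisons": len(bio_counts),
            "n_technical_comparisons": len(tech_counts),
            "p_resolution": 1.0 / (n_perm + 1),
        },
    )
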