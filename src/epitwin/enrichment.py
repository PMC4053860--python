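"""Enrichment of iiDMR probes across genomic and chromatin categories.

The enrichment unit is the probe: for each category we ask what fraction
of the universe probes in that category were called as iiDMR members, with
an exact (Clopper-Pearson) binomial 95% interval, against the overall DMR
fraction as background. Promoter chromatin states are a four-way
H3K4me3 x H3K27me3 quadrant classification (hi = above a per-mark quantile
of promoter-wide scores), housekeeping depletion is a 2x2 chi-squared test,
and the ageing-DMR comparison contrasts absolute methylation differences at
the top age-correlated probes with a random control set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import compute_deltas
from .types import (
    CountTrack,
    EnrichmentResult,
    MethylationMatrix,
    ProbeRecord,
    SampleSheet,
    StatResult,
)


def binomial_ci(
    k: int, n: int, alpha: float = 0.05, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Two-sided binomial CI for a proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return lo, hi
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        phat = k / n
        denom = 1 + z**2 / n
        centre = (phat + z**2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    raise ValueError(f"unknown CI method {method!r}")


def category_enrichment(
    dmr_probe_ids: set[str],
    categories: Mapping[str, str],
    universe: Sequence[str],
    alpha: float = 0.05,
    ci_method: str = "clopper-pearson",
) -> list[EnrichmentResult]:
    """Per-category DMR fraction with binomial CIs and the background line.

    ``categories`` maps probe_id -> category label over (a subset of) the
    universe; universe probes without a label are ignored for category rows
    but still count toward the background fraction.
    """
    universe_list = list(universe)
    if not universe_list:
        raise ValueError("empty probe universe")
    universe_set = set(universe_list)
    if not set(dmr_probe_ids) <= universe_set:
        raise ValueError("dmr_probe_ids must be a subset of the universe")
    background = len(dmr_probe_ids) / len(universe_set)
    by_cat: dict[str, list[str]] = {}
    for pid in universe_list:
        cat = categories.get(pid)
        if cat is not None:
            by_cat.setdefault(cat, []).append(pid)
    results = []
    for cat in sorted(set(categories.values())):
        members = by_cat.get(cat, [])
        n = len(members)
        k = sum(1 for p in members if p in dmr_probe_ids)
        if n == 0:
            results.append(
                EnrichmentResult(cat, 0, 0, float("nan"), float("nan"),
                                 float("nan"), background)
            )
            continue
        lo, hi = binomial_ci(k, n, alpha=alpha, method=ci_method)
        results.append(
            EnrichmentResult(
                category=cat,
                n_category_probes=n,
                n_dmr_probes_in_category=k,
                fraction=k / n,
                ci_low=lo,
                ci_high=hi,
                background_fraction=background,
            )
        )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "n_category_probes": r.n_category_probes,
                "n_dmr_probes": r.n_dmr_probes_in_category,
                "fraction": r.fraction,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "background_fraction": r.background_fraction,
            }
            for r in results
        ]
    )


def classify_chromatin_states(
    k4: CountTrack,
    k27: CountTrack,
    hi_quantile: float | tuple[float, float] = 0.75,
) -> pd.DataFrame:
    """Four-way promoter state from H3K4me3/H3K27me3 scores.

    A mark is "hi" at a promoter iff its score strictly exceeds the
    ``hi_quantile`` quantile of that mark's promoter-wide scores (a pair of
    quantiles applies them per mark, K4 then K27). Returns a frame with
    tss_id, k4_score, k27_score, state.
    """
    k4_s = k4.as_series()
    k27_s = k27.as_series()
    if set(k4_s.index) != set(k27_s.index):
        raise ValueError("K4 and K27 tracks must cover the same promoter set")
    k27_s = k27_s.loc[k4_s.index]
    for name, s in (("H3K4me3", k4_s), ("H3K27me3", k27_s)):
        if float(s.max()) == 0.0:
            raise ValueError(f"{name} track is all zero; quantile cutoff degenerate")
    q4, q27 = (
        hi_quantile if isinstance(hi_quantile, tuple) else (hi_quantile, hi_quantile)
    )
    k4_cut = float(np.quantile(k4_s.to_numpy(), q4))
    k27_cut = float(np.quantile(k27_s.to_numpy(), q27))
    k4_hi = k4_s.to_numpy() > k4_cut
    k27_hi = k27_s.to_numpy() > k27_cut
    states = np.array(
        [
            f"K4{'hi' if a else 'lo'}/K27{'hi' if b else 'lo'}"
            for a, b in zip(k4_hi, k27_hi)
        ],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "tss_id": k4_s.index,
            "k4_score": k4_s.to_numpy(),
            "k27_score": k27_s.to_numpy(),
            "state": states,
        }
    )


def housekeeping_depletion_test(
    dmr_tss: set[str],
    housekeeping_tss: set[str],
    universe_tss: set[str],
) -> StatResult:
    """2x2 chi-squared (no continuity correction) for DMR x housekeeping.

    Reports the direction (depletion iff observed overlap < expected under
    independence) alongside the two-sided p-value.
    """
    if not dmr_tss <= universe_tss or not housekeeping_tss <= universe_tss:
        raise ValueError("both sets must be subsets of the universe")
    n = len(universe_tss)
    a = len(dmr_tss & housekeeping_tss)
    b = len(dmr_tss) - a
    c = len(housekeeping_tss) - a
    d = n - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in the 2x2 table")
    expected_overlap = len(dmr_tss) * len(housekeeping_tss) / n
    chi2_stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return StatResult(
        statistic_name="housekeeping_chi2",
        statistic=float(chi2_stat),
        p_value=float(p),
        extras={
            "observed_overlap": a,
            "expected_overlap": expected_overlap,
            "direction": "depletion" if a < expected_overlap else "enrichment",
        },
    )


def admr_variability_comparison(
    age_scores: pd.Series,
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    kept: Sequence[ProbeRecord],
    comparisons: Sequence[tuple[str, str]],
    n_top: int = 500,
    n_control: int = 500,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, StatResult]:
    """Ageing-DMR vs control probe variability across pairwise comparisons.

    Takes the ``n_top`` most age-correlated probes and ``n_control`` seeded
    random probes from the remainder, pools |beta difference| over every
    supplied (sample_a, sample_b) comparison per set, and reports the mean
    with a percentile-bootstrap 95% interval. Ties across the rank-n_top
    boundary are broken by probe id.
    """
    if n_top < 1 or n_control < 1:
        raise ValueError("n_top and n_control must be positive")
    kept_ids = [r.probe_id for r in kept if r.probe_id in set(matrix.probe_ids)]
    scores = age_scores.loc[[p for p in kept_ids if p in age_scores.index]]
    if n_top + n_control > len(scores):
        raise ValueError("n_top + n_control exceeds the probe universe")
    order = sorted(scores.index, key=lambda p: (-scores.loc[p], p))
    top = set(order[:n_top])
    remainder = order[n_top:]
    rng = np.random.default_rng(seed)
    control = set(rng.choice(np.array(remainder, dtype=object), size=n_control,
                             replace=False))

    pools: dict[str, list[np.ndarray]] = {"admr": [], "control": []}
    kept_records = [r for r in kept if r.probe_id in set(matrix.probe_ids)]
    for a, b in comparisons:
        track = compute_deltas(matrix, a, b, kept_records)
        absd = pd.Series(np.abs(track.deltas), index=track.probe_ids).dropna()
        pools["admr"].append(absd.loc[[p for p in absd.index if p in top]].to_numpy())
        pools["control"].append(
            absd.loc[[p for p in absd.index if p in control]].to_numpy()
        )

    out = {}
    for label, chunks in pools.items():
        vals = np.concatenate(chunks)
        draws = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot_means = vals[draws].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        out[label] = StatResult(
            statistic_name=f"mean_abs_delta_{label}",
            statistic=float(vals.mean()),
            p_value=float("nan"),
            ci_low=float(lo),
            ci_high=float(hi),
            n_resamples=n_boot,
            seed=seed,
            extras={"n_observations": int(len(vals))},
        )
    return out
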