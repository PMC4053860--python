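"""Integrating methylation with chromatin (ChIP counts) and expression.

Promoters are TSS +/- 1000 bp windows (strand-aware anchor). Array probes
are assigned to their nearest TSS, discarding assignments more than 1 kb
away. ChIP scores are fragment counts over probe regions, library-size
normalised. The binned analyses follow the figure construction of the
underlying study: bin probes by inter-individual methylation difference,
then report the mean response (H2A.Z difference or log-FPKM ratio) with
percentile-bootstrap 95% intervals per bin.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import (
    BinnedSeries,
    CountTrack,
    DeltaTrack,
    GenomicInterval,
    ProbeRecord,
    StatResult,
)

PROMOTER_FLANK = 1000  # bp either side of the TSS anchor


def promoter_window(tss: GenomicInterval, flank: int = PROMOTER_FLANK) -> GenomicInterval:
    """[anchor - flank, anchor + flank) around the strand-aware TSS anchor,
    clipped at zero."""
    anchor = tss.anchor
    return GenomicInterval(
        chromosome=tss.chromosome,
        start=max(0, anchor - flank),
        end=anchor + flank,
        strand=tss.strand,
        name=tss.name,
    )


def assign_probes_to_tss(
    probes: Sequence[ProbeRecord],
    tss_list: Sequence[GenomicInterval],
    max_distance: int = 1000,
) -> dict[str, str]:
    """Map each probe to its nearest TSS anchor within ``max_distance`` bp.

    Ties are broken deterministically: the smaller anchor coordinate wins,
    then the lexicographically smaller TSS name.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for i, tss in enumerate(tss_list):
        name = tss.name if tss.name is not None else f"tss_{i}"
        by_chrom[tss.chromosome].append((tss.anchor, name))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    assignment: dict[str, str] = {}
    for probe in probes:
        anchors = by_chrom.get(probe.chromosome)
        if not anchors:
            continue
        coords = [a for a, _ in anchors]
        j = np.searchsorted(coords, probe.position)
        best: Optional[tuple[int, int, str]] = None  # (distance, anchor, name)
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(anchors):
                anchor, name = anchors[k]
                cand = (abs(probe.position - anchor), anchor, name)
                if best is None or cand < best:
                    best = cand
        if best is not None and best[0] <= max_distance:
            assignment[probe.probe_id] = best[2]
    return assignment


def count_fragments(
    fragments: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    mark: str = "H2A.Z",
    sample_id: str = "",
) -> CountTrack:
    """Count whole template fragments overlapping each region by >= 1 bp.

    Overlap is half-open intersection; a fragment fully containing a region
    still counts once for that region.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for frag in fragments:
        trees[frag.chromosome].addi(frag.start, frag.end)
    region_ids = []
    counts = []
    for i, region in enumerate(regions):
        region_ids.append(region.name if region.name is not None else f"region_{i}")
        counts.append(len(trees[region.chromosome].overlap(region.start, region.end)))
    return CountTrack(
        region_ids=np.array(region_ids, dtype=object),
        raw_counts=np.array(counts, dtype=np.int64),
        mark=mark,
        sample_id=sample_id,
    )


def normalize_counts(
    track: CountTrack, library_total: int, scale: int = 10_000_000
) -> CountTrack:
    """Counts-per-scale normalisation: raw * scale / library_total."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return CountTrack(
        region_ids=track.region_ids,
        raw_counts=track.raw_counts,
        mark=track.mark,
        sample_id=track.sample_id,
        norm_scores=np.asarray(track.raw_counts, dtype=float) * scale / library_total,
        library_total=library_total,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with mid-rank ties, two-sided p.

    Pairs with a missing member are dropped; at least 3 complete pairs are
    required and constant vectors are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("spearman requires >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return StatResult(
        statistic_name="spearman_rho",
        statistic=float(rho),
        p_value=float(p),
        extras={"n": int(len(x))},
    )


def _bin_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n_bins + 1)


def binned_mean_ci(
    delta: Union[DeltaTrack, np.ndarray],
    response: Sequence[float],
    bin_width: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    min_bin_n: int = 3,
) -> BinnedSeries:
    """Mean response per methylation-difference bin with bootstrap 95% CIs.

    Bin edges sit at multiples of ``bin_width`` covering the observed delta
    range. Each bin's interval is a percentile bootstrap over ``n_boot``
    resamples; bins with fewer than ``min_bin_n`` points are flagged and get
    no interval. Deterministic given the seed.
    """
    d = delta.deltas if isinstance(delta, DeltaTrack) else np.asarray(delta, dtype=float)
    r = np.asarray(response, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(r))
    d, r = d[ok], r[ok]
    if len(d) == 0:
        raise ValueError("no complete (delta, response) pairs")
    edges = _bin_edges(d, bin_width)
    # right-closed top bin so the maximum is not orphaned
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    n = np.zeros(n_bins, dtype=int)
    mean = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    has = np.zeros(n_bins, dtype=bool)
    rng = np.random.default_rng(seed)
    for b in range(n_bins):
        vals = r[idx == b]
        n[b] = len(vals)
        if n[b] == 0:
            continue
        mean[b] = vals.mean()
        if n[b] < min_bin_n:
            continue
        draws = rng.integers(0, n[b], size=(n_boot, n[b]))
        boot_means = vals[draws].mean(axis=1)
        lo[b], hi[b] = np.percentile(boot_means, [2.5, 97.5])
        has[b] = True
    return BinnedSeries(
        bin_edges=edges,
        n=n,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        has_ci=has,
        n_boot=n_boot,
        seed=seed,
    )


def expression_ratio_series(
    delta: DeltaTrack,
    expr_a: pd.Series,
    expr_b: pd.Series,
    assignment: Mapping[str, str],
    bin_width: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> BinnedSeries:
    """Log-FPKM ratio (individual A over B) binned by methylation difference.

    The response per TSS-assigned probe is log(FPKM_A + eps) - log(FPKM_B +
    eps) with eps = ``pseudocount`` guarding zero expression.
    """
    if not assignment:
        raise ValueError("empty probe-to-TSS assignment")
    deltas, responses = [], []
    for pid, d in zip(delta.probe_ids, delta.deltas):
        tss = assignment.get(str(pid))
        if tss is None or tss not in expr_a.index or tss not in expr_b.index:
            continue
        deltas.append(d)
        responses.append(
            np.log(expr_a.loc[tss] + pseudocount)
            - np.log(expr_b.loc[tss] + pseudocount)
        )
    return binned_mean_ci(
        np.asarray(deltas), responses, bin_width=bin_width, n_boot=n_boot, seed=seed
    )


def expression_shift_test(
    dmr_tss: set[str],
    all_tss: set[str],
    expr: pd.Series,
    low_threshold: float = 1.0,
) -> StatResult:
    """Are DMR-assigned genes expressed lower than the rest?

    One-sided Wilcoxon rank-sum on log FPKM (alternative: DMR genes lower),
    plus the fraction of each set below the low-expression threshold
    (FPKM < 1 by convention). All-constant expression yields p = 1 (no
    shift is detectable).
    """
    if not dmr_tss or not all_tss:
        raise ValueError("both TSS sets must be non-empty")
    if not dmr_tss <= all_tss:
        raise ValueError("dmr_tss must be a subset of all_tss")
    non_dmr = all_tss - dmr_tss
    if not non_dmr:
        raise ValueError("no non-DMR genes to compare against")
    a = expr.loc[sorted(dmr_tss & set(expr.index))].to_numpy(dtype=float)
    b = expr.loc[sorted(non_dmr & set(expr.index))].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("expression data missing for one of the sets")
    frac_low_dmr = float((a < low_threshold).mean())
    frac_low_other = float((b < low_threshold).mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        res = stats.mannwhitneyu(np.log1p(a), np.log1p(b), alternative="less")
        stat, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        statistic_name="expression_shift_ranksum",
        statistic=stat,
        p_value=p,
        extras={
            "n_dmr_genes": int(len(a)),
            "n_other_genes": int(len(b)),
            "frac_low_expression_dmr": frac_low_dmr,
            "frac_low_expression_other": frac_low_other,
        },
    )
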