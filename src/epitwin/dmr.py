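"""The iiDMR caller.

An inter-individual DMR between two samples is a maximal run of at least
``min_probes`` consecutive probes (consecutive in the kept, coordinate-
sorted probe list) whose beta differences all have the same sign, each with
absolute value >= ``min_delta`` (default 0.05, i.e. a 5% methylation
difference), with successive member probes at most ``max_gap`` bp apart
(default 500) on one chromosome. A missing or non-qualifying probe, a sign
change, a chromosome change, or an over-limit gap terminates a run.

"Adjacent" means consecutive among the analysed probes, not genomic
nucleotide adjacency: an array interrogates a sparse probe grid, and the
pairwise <=500 bp constraint is what makes the rule decidable without the
genome sequence.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DeltaTrack, DMRCall, MethylationMatrix, ProbeRecord


def compute_deltas(
    matrix: MethylationMatrix,
    sample_a: str,
    sample_b: str,
    kept: Sequence[ProbeRecord],
) -> DeltaTrack:
    """Per-probe delta = beta(A) - beta(B) over the kept probes.

    The track is sorted by (chromosome, position); the delta is missing
    (NaN) wherever either sample's beta is missing.
    """
    for s in (sample_a, sample_b):
        if s not in matrix.values.columns:
            raise KeyError(f"unknown sample id: {s}")
    recs = sorted(kept, key=lambda r: (r.chromosome, r.position, r.probe_id))
    recs = [r for r in recs if r.probe_id in matrix.values.index]
    ids = [r.probe_id for r in recs]
    a = matrix.values.loc[ids, sample_a].to_numpy(dtype=float)
    b = matrix.values.loc[ids, sample_b].to_numpy(dtype=float)
    return DeltaTrack(
        probe_ids=np.array(ids, dtype=object),
        chromosomes=np.array([r.chromosome for r in recs], dtype=object),
        positions=np.array([r.position for r in recs], dtype=np.int64),
        deltas=a - b,
        sample_a=sample_a,
        sample_b=sample_b,
    )


def _check_sorted(track: DeltaTrack) -> None:
    chroms = track.chromosomes
    pos = track.positions
    for i in range(1, len(pos)):
        if chroms[i] == chroms[i - 1] and pos[i] < pos[i - 1]:
            raise ValueError(
                f"delta track not coordinate-sorted at {chroms[i]}:{pos[i]}"
            )


def call_iidmrs(
    deltas: DeltaTrack,
    min_delta: float = 0.05,
    min_probes: int = 2,
    max_gap: int = 500,
    comparison_id: str = "",
) -> list[DMRCall]:
    """Call iiDMRs from a sorted delta track.

    Thresholding is inclusive (|delta| >= min_delta) on the raw floating
    values. Output calls are coordinate-sorted and non-overlapping; the end
    coordinate covers the CpG dinucleotide of the last member probe (+2).
    """
    if min_probes < 2:
        raise ValueError("min_probes must be >= 2")
    _check_sorted(deltas)
    d = deltas.deltas
    qualifies = ~np.isnan(d) & (np.abs(d) >= min_delta)
    signs = np.sign(d)
    calls: list[DMRCall] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_probes:
            idx = list(run)
            member_deltas = tuple(float(d[i]) for i in idx)
            calls.append(
                DMRCall(
                    chromosome=str(deltas.chromosomes[idx[0]]),
                    start=int(deltas.positions[idx[0]]),
                    end=int(deltas.positions[idx[-1]]) + 2,
                    probe_ids=tuple(str(deltas.probe_ids[i]) for i in idx),
                    deltas=member_deltas,
                    direction="gain" if member_deltas[0] > 0 else "loss",
                    comparison_id=comparison_id,
                )
            )
        run.clear()

    for i in range(len(d)):
        if not qualifies[i]:
            flush()
            continue
        if run:
            j = run[-1]
            same_chrom = deltas.chromosomes[i] == deltas.chromosomes[j]
            in_gap = same_chrom and (
                deltas.positions[i] - deltas.positions[j] <= max_gap
            )
            same_sign = signs[i] == signs[j]
            if not (in_gap and same_sign):
                flush()
        run.append(i)
    flush()
    return calls


def count_dmr_probes(
    calls: Sequence[DMRCall],
    manifest: Optional[Sequence[ProbeRecord]] = None,
) -> dict:
    """Summarise one comparison's calls: region count, member-probe count,
    and (if a manifest is supplied) member probes per feature class."""
    n_calls = len(calls)
    member_ids = [p for c in calls for p in c.probe_ids]
    out = {"n_calls": n_calls, "n_probes": len(member_ids)}
    if manifest is not None:
        feature_of = {r.probe_id: r.feature_class for r in manifest}
        per_feature: Counter = Counter(
            feature_of[p] for p in member_ids if p in feature_of
        )
        out["per_feature"] = dict(per_feature)
    return out


def dmr_probe_ids(calls: Sequence[DMRCall]) -> set[str]:
    """Union of member probes over calls ("probe belongs to >=1 call")."""
    return {p for c in calls for p in c.probe_ids}


def calls_to_frame(calls: Sequence[DMRCall]) -> pd.DataFrame:
    rows = [
        {
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "n_probes": c.n_probes,
            "direction": c.direction,
            "mean_abs_delta": c.mean_abs_delta,
            "comparison_id": c.comparison_id,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start",
            "end",
            "n_probes",
            "direction",
            "mean_abs_delta",
            "comparison_id",
        ],
    )
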