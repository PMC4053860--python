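"""Temporal stability of inter-individual methylation differences.

Compares per-probe beta differences measured at a later, denser platform
with differences for the same individuals measured years earlier on a
sparser, promoter-focused platform, and asks whether same-direction
agreement exceeds the 50% expected by chance (1-df goodness-of-fit chi^2).
Single-probe differences are used here (strict >threshold), not
multi-probe DMRs, for maximum power on the sparse common probe set.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .types import DeltaTrack, ProbeRecord, StatResult

logger = logging.getLogger(__name__)


def match_platforms(
    dense_manifest: Sequence[ProbeRecord],
    sparse_manifest: Sequence[ProbeRecord],
) -> list[str]:
    """Probe ids present on both platforms, in dense-manifest order."""
    sparse_ids = {r.probe_id for r in sparse_manifest}
    common = [r.probe_id for r in dense_manifest if r.probe_id in sparse_ids]
    if not common:
        raise ValueError("platforms share no probes")
    frac = len(common) / len(sparse_ids)
    logger.info(
        "matched %d/%d sparse probes (%.1f%%) to the dense platform",
        len(common),
        len(sparse_ids),
        100 * frac,
    )
    return common


def direction_consistency_test(
    delta_t2: DeltaTrack,
    delta_t1: DeltaTrack,
    threshold: float = 0.05,
    null_same_direction: float = 0.5,
    continuity_correction: bool = False,
) -> StatResult:
    """Do later-time differences keep their direction at the earlier time?

    Probes with a strict |delta_t2| > threshold are selected; among those,
    the tally of sign(delta_t1) == sign(delta_t2) is tested against the
    null that same/opposite direction are equiprobable (expected n/2 each)
    with a 1-df goodness-of-fit chi^2. Probes with missing or exactly-zero
    delta_t1 are excluded and reported.
    """
    t2 = pd.Series(delta_t2.deltas, index=delta_t2.probe_ids)
    t1 = pd.Series(delta_t1.deltas, index=delta_t1.probe_ids)
    common = t2.index.intersection(t1.index)
    t2, t1 = t2.loc[common], t1.loc[common]

    selected = t2[np.abs(t2) > threshold].dropna()
    excluded = selected.index[
        t1.loc[selected.index].isna() | (t1.loc[selected.index] == 0.0)
    ]
    usable = selected.drop(excluded)
    n = len(usable)
    if n == 0:
        raise ValueError("no probes selected above the threshold")
    same = int(
        (np.sign(t1.loc[usable.index]) == np.sign(usable)).sum()
    )
    opposite = n - same
    p_null = null_same_direction
    expected = np.array([n * p_null, n * (1 - p_null)])
    observed = np.array([same, opposite], dtype=float)
    dev = np.abs(observed - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(chi2.sf(stat, df=1))
    return StatResult(
        statistic_name="direction_consistency_chi2",
        statistic=stat,
        p_value=p,
        extras={
            "n_selected": n,
            "n_same_direction": same,
            "n_opposite_direction": opposite,
            "n_excluded": int(len(excluded)),
            "proportion_same": same / n,
            "threshold": threshold,
        },
    )
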