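"""Probe-level exclusion rules defining the analysis probe universe.

Probes are removed if their 50-mer maps more than once in the genome, if
they overlap a known SNP (per the array annotation), or if they lie on a
sex chromosome — the masks that guard against differential-hybridisation
artefacts. The kept set is independent of reporting order; the per-reason
report counts each removed probe once under a fixed precedence
(multi_mapped > snp_overlap > sex_chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import ProbeRecord

EXCLUSION_REASONS = ("multi_mapped", "snp_overlap", "sex_chromosome")


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    removed: dict  # reason -> count, precedence-resolved

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def filter_probes(
    manifest: Sequence[ProbeRecord],
) -> tuple[list[ProbeRecord], QCReport]:
    """Apply the probe-exclusion rules; returns (kept, report).

    Input order is preserved in the kept list. Raises if nothing survives.
    """
    kept: list[ProbeRecord] = []
    removed = {reason: 0 for reason in EXCLUSION_REASONS}
    for rec in manifest:
        if rec.multi_mapped:
            removed["multi_mapped"] += 1
        elif rec.snp_overlap:
            removed["snp_overlap"] += 1
        elif rec.sex_chromosome:
            removed["sex_chromosome"] += 1
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("probe QC removed every probe; nothing to analyze")
    return kept, QCReport(n_input=len(manifest), n_kept=len(kept), removed=removed)


def report_frame(report: QCReport):
    """QC report as a small table (reason, n_removed)."""
    import pandas as pd

    rows = [{"reason": r, "n_removed": report.removed[r]} for r in EXCLUSION_REASONS]
    rows.append({"reason": "kept", "n_removed": report.n_kept})
    return pd.DataFrame(rows)
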