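"""Domain containers shared across the pipeline.

Everything downstream of the file readers operates on these in-memory types:
probe manifests, beta-value matrices, sample sheets, expression tables,
genomic intervals, DMR calls, ChIP count tracks and statistic containers.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("promoter", "regulatory", "exon", "intron", "other")
CGI_RELATIONS = ("island", "shore", "open_sea")
CHIP_MARKS = ("H2A.Z", "H3K4me3", "H3K27me3")
CHROMATIN_STATES = ("K4hi/K27hi", "K4hi/K27lo", "K4lo/K27hi", "K4lo/K27lo")

_SEX_LABELS = frozenset({"chrX", "chrY", "X", "Y"})


def is_sex_chromosome(chromosome: str) -> bool:
    """True iff the label names chrX or chrY (with or without the prefix)."""
    return chromosome in _SEX_LABELS


@dataclass(frozen=True)
class ProbeRecord:
    """One methylation-array probe: genomic anchor, mask flags, annotation.

    ``position`` is the 0-based coordinate of the interrogated CpG cytosine.
    ``multi_mapped`` marks probes whose 50-mer maps more than once (the
    uniqueness filter applied before analysis); ``snp_overlap`` marks probes
    overlapping a known SNP per the array annotation.
    """

    probe_id: str
    chromosome: str
    position: int
    multi_mapped: bool = False
    snp_overlap: bool = False
    feature_class: str = "other"
    cgi_relation: str = "open_sea"
    nearest_tss_id: Optional[str] = None
    tss_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("probe_id must be non-empty")
        if self.position < 0:
            raise ValueError(
                f"probe {self.probe_id}: position must be >= 0, got {self.position}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"probe {self.probe_id}: unknown feature_class {self.feature_class!r}"
            )
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValueError(
                f"probe {self.probe_id}: unknown cgi_relation {self.cgi_relation!r}"
            )
        if (self.nearest_tss_id is None) != (self.tss_distance is None):
            raise ValueError(
                f"probe {self.probe_id}: nearest_tss_id and tss_distance must be "
                "present together"
            )

    @property
    def sex_chromosome(self) -> bool:
        return is_sex_chromosome(self.chromosome)


def validate_manifest(records: Sequence[ProbeRecord]) -> None:
    """Raise on duplicate probe ids."""
    seen: set[str] = set()
    for rec in records:
        if rec.probe_id in seen:
            raise ValueError(f"duplicate probe_id in manifest: {rec.probe_id}")
        seen.add(rec.probe_id)


def sort_manifest(records: Iterable[ProbeRecord]) -> list[ProbeRecord]:
    return sorted(records, key=lambda r: (r.chromosome, r.position, r.probe_id))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end); generic carrier for BED features."""

    chromosome: str
    start: int
    end: int
    strand: Optional[str] = None  # '+', '-', or None for unknown
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def anchor(self) -> int:
        """Single-bp anchor: start for +/unknown strand, end-1 for minus strand."""
        return self.end - 1 if self.strand == "-" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


class MethylationMatrix:
    """Beta values (probes x samples), missing values as NaN.

    Thin wrapper over a float DataFrame with probe ids as the index and
    sample ids as the columns; validates the [0, 1] range on construction.
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[1] == 0:
            raise ValueError("beta matrix has no samples")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id in beta matrix: {dup}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = finite[(finite < 0.0) | (finite > 1.0)][0]
            raise ValueError(f"beta value out of [0, 1]: {bad}")
        self.values = values.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def beta(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise KeyError(f"unknown sample id: {sample_id}")
        return self.values[sample_id]

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        keep = [p for p in probe_ids if p in self.values.index]
        return MethylationMatrix(self.values.loc[keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"MethylationMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "individual_id",
    "pair_id",
    "replicate_id",
    "time_point",
    "platform",
)

PLATFORMS = ("dense", "sparse")


class SampleSheet:
    """Per-sample design: individual, twin pair, replicate, time point, platform.

    A pair_id normally maps to two individuals; a singleton pair is allowed
    (e.g. when one co-twin's methylation data is unavailable) and is treated
    as its own pair by the comparison planner.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        frame = frame[list(SAMPLE_SHEET_COLUMNS)].copy()
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in sample sheet: {dup}")
        bad = set(frame["platform"]) - set(PLATFORMS)
        if bad:
            raise ValueError(f"unknown platform labels: {sorted(bad)}")
        frame["time_point"] = frame["time_point"].astype(int)
        for pair_id, grp in frame.groupby("pair_id"):
            n_ind = grp["individual_id"].nunique()
            if n_ind > 2:
                raise ValueError(
                    f"pair {pair_id} maps to {n_ind} individuals (max 2)"
                )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def individuals(self) -> list[str]:
        return sorted(self.frame["individual_id"].unique())

    def pair_of(self, individual_id: str) -> str:
        rows = self.frame[self.frame["individual_id"] == individual_id]
        if rows.empty:
            raise KeyError(f"unknown individual: {individual_id}")
        return rows["pair_id"].iloc[0]

    def pairs(self) -> dict[str, list[str]]:
        """pair_id -> sorted individual ids (1 or 2 entries)."""
        out: dict[str, list[str]] = {}
        for pair_id, grp in self.frame.groupby("pair_id"):
            out[pair_id] = sorted(grp["individual_id"].unique())
        return out

    def samples_for(
        self,
        individual_id: str,
        time_point: Optional[int] = None,
        platform: Optional[str] = None,
    ) -> list[str]:
        sel = self.frame["individual_id"] == individual_id
        if time_point is not None:
            sel &= self.frame["time_point"] == time_point
        if platform is not None:
            sel &= self.frame["platform"] == platform
        rows = self.frame[sel].sort_values(["replicate_id", "sample_id"])
        return list(rows["sample_id"])

    def __len__(self) -> int:
        return len(self.frame)


class ExpressionTable:
    """FPKM per TSS per sample (non-negative)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate tss_id in expression table")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression table contains missing values")
        if (arr < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.values = values.astype(float)

    @property
    def tss_ids(self) -> list[str]:
        return list(self.values.index)

    def fpkm(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def mean_fpkm(self) -> pd.Series:
        return self.values.mean(axis=1)


@dataclass(frozen=True)
class DMRCall:
    """One called inter-individual DMR (a maximal run of qualifying probes)."""

    chromosome: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    deltas: tuple[float, ...]
    direction: str  # 'gain' or 'loss', sample A relative to sample B
    comparison_id: str = ""

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 2:
            raise ValueError("a DMR call requires >= 2 member probes")
        if len(self.probe_ids) != len(self.deltas):
            raise ValueError("probe_ids and deltas length mismatch")
        signs = {np.sign(d) for d in self.deltas}
        if len(signs) != 1 or 0.0 in signs:
            raise ValueError("DMR deltas must share one non-zero sign")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"invalid direction {self.direction!r}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def mean_abs_delta(self) -> float:
        return float(np.mean(np.abs(self.deltas)))


@dataclass
class DeltaTrack:
    """Per-probe beta differences beta(A) - beta(B), coordinate sorted.

    NaN marks probes where either sample's beta is missing.
    """

    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    deltas: np.ndarray
    sample_a: str = ""
    sample_b: str = ""

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (len(self.chromosomes) == len(self.positions) == len(self.deltas) == n):
            raise ValueError("DeltaTrack arrays must share one length")
        finite = self.deltas[~np.isnan(self.deltas)]
        if finite.size and np.max(np.abs(finite)) > 1.0 + 1e-12:
            raise ValueError("|delta| cannot exceed 1")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
                "delta": self.deltas,
            }
        )


@dataclass
class CountTrack:
    """Fragment counts per region for one ChIP mark in one library.

    ``norm_scores`` are library-size normalised: raw * scale / library_total.
    """

    region_ids: np.ndarray
    raw_counts: np.ndarray
    mark: str
    sample_id: str
    norm_scores: Optional[np.ndarray] = None
    library_total: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mark not in CHIP_MARKS:
            raise ValueError(f"unknown ChIP mark {self.mark!r}")
        if (np.asarray(self.raw_counts) < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def scores(self) -> np.ndarray:
        """Normalised scores if available, else raw counts as float."""
        if self.norm_scores is not None:
            return np.asarray(self.norm_scores, dtype=float)
        return np.asarray(self.raw_counts, dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.region_ids)


@dataclass
class StatResult:
    """Statistic + p-value + optional CI, with resampling provenance."""

    statistic_name: str
    statistic: float
    p_value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_resamples: int = 0
    seed: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            raise ValueError("ci_low must be <= ci_high")


@dataclass
class BinnedSeries:
    """Per-bin mean response with percentile-bootstrap 95% intervals.

    Bins with fewer than the minimum number of observations are flagged
    (``has_ci`` False) and carry NaN interval endpoints.
    """

    bin_edges: np.ndarray  # length n_bins + 1, contiguous
    n: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    has_ci: np.ndarray
    n_boot: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "n": self.n,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "has_ci": self.has_ci,
            }
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """DMR fraction in one probe category with a binomial CI."""

    category: str
    n_category_probes: int
    n_dmr_probes_in_category: int
    fraction: float
    ci_low: float
    ci_high: float
    background_fraction: float

    @property
    def defined(self) -> bool:
        return self.n_category_probes > 0
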