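"""Readers and writers for every on-disk format the pipeline touches.

All tables are tab-separated UTF-8 with a header row; intervals are BED3+
(0-based half-open). The missing-value token is "NA" (an empty cell is also
accepted); missingness is preserved, never imputed. Readers validate hard
and sort deterministically so downstream output does not depend on input
row order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    DMRCall,
    ExpressionTable,
    GenomicInterval,
    MethylationMatrix,
    ProbeRecord,
    SampleSheet,
    is_sex_chromosome,
    sort_manifest,
    validate_manifest,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("NA", "")

_BOOL_TOKENS = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "t": True,
    "f": False,
}


def _parse_bool(token: str, context: str) -> bool:
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"{context}: cannot parse boolean from {token!r}") from None


def _parse_optional(token: str) -> Optional[str]:
    token = token.strip()
    return None if token in MISSING_TOKENS else token


PathLike = Union[str, Path]


def read_probe_manifest(path: PathLike) -> list[ProbeRecord]:
    """Read a probe manifest TSV into validated, coordinate-sorted records.

    Required columns: probe_id, chromosome, position, multi_mapped,
    snp_overlap, feature_class, cgi_relation, nearest_tss_id, tss_distance.
    A sex_chromosome column, if present, is checked for consistency with the
    chromosome label (it is otherwise derived).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        required = [
            "probe_id",
            "chromosome",
            "position",
            "multi_mapped",
            "snp_overlap",
            "feature_class",
            "cgi_relation",
            "nearest_tss_id",
            "tss_distance",
        ]
        missing = [c for c in required if c not in cols]
        if missing:
            raise ValueError(f"{path}: manifest missing columns {missing}")
        records: list[ProbeRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            probe_id = fields[cols["probe_id"]].strip()
            try:
                position = int(fields[cols["position"]])
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: malformed position "
                    f"{fields[cols['position']]!r}"
                ) from None
            tss_id = _parse_optional(fields[cols["nearest_tss_id"]])
            tss_dist_tok = _parse_optional(fields[cols["tss_distance"]])
            tss_distance = int(tss_dist_tok) if tss_dist_tok is not None else None
            rec = ProbeRecord(
                probe_id=probe_id,
                chromosome=fields[cols["chromosome"]].strip(),
                position=position,
                multi_mapped=_parse_bool(
                    fields[cols["multi_mapped"]], f"{path} line {lineno}"
                ),
                snp_overlap=_parse_bool(
                    fields[cols["snp_overlap"]], f"{path} line {lineno}"
                ),
                feature_class=fields[cols["feature_class"]].strip(),
                cgi_relation=fields[cols["cgi_relation"]].strip(),
                nearest_tss_id=tss_id,
                tss_distance=tss_distance,
            )
            if "sex_chromosome" in cols:
                flagged = _parse_bool(
                    fields[cols["sex_chromosome"]], f"{path} line {lineno}"
                )
                if flagged != rec.sex_chromosome:
                    raise ValueError(
                        f"{path} line {lineno}: sex_chromosome flag inconsistent "
                        f"with chromosome {rec.chromosome!r}"
                    )
            records.append(rec)
    validate_manifest(records)
    return sort_manifest(records)


MANIFEST_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "multi_mapped",
    "snp_overlap",
    "sex_chromosome",
    "feature_class",
    "cgi_relation",
    "nearest_tss_id",
    "tss_distance",
)


def write_probe_manifest(records: Sequence[ProbeRecord], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.probe_id,
                        r.chromosome,
                        str(r.position),
                        str(r.multi_mapped).lower(),
                        str(r.snp_overlap).lower(),
                        str(r.sex_chromosome).lower(),
                        r.feature_class,
                        r.cgi_relation,
                        r.nearest_tss_id if r.nearest_tss_id is not None else "NA",
                        str(r.tss_distance) if r.tss_distance is not None else "NA",
                    ]
                )
                + "\n"
            )


def read_beta_matrix(
    path: PathLike, manifest: Sequence[ProbeRecord]
) -> MethylationMatrix:
    """Read a probes x samples beta TSV, restricted to manifest probes.

    Probes absent from the manifest are dropped (the count is logged);
    values outside [0, 1] are a hard error; "NA"/empty cells are missing.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: beta matrix has no sample columns")
    values = frame.apply(pd.to_numeric, errors="raise")
    arr = values.to_numpy(dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        bad = finite[(finite < 0.0) | (finite > 1.0)][0]
        raise ValueError(f"{path}: beta value out of [0, 1]: {bad}")
    manifest_ids = [r.probe_id for r in manifest]
    known = set(manifest_ids)
    n_dropped = int((~values.index.isin(known)).sum())
    if n_dropped:
        logger.info("%s: dropped %d probes not in manifest", path, n_dropped)
    keep = [p for p in manifest_ids if p in set(values.index)]
    return MethylationMatrix(values.loc[keep])


def write_beta_matrix(matrix: MethylationMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(Path(path), sep="\t", na_rep="NA", float_format="%.6g")


def read_sample_sheet(path: PathLike) -> SampleSheet:
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    sheet.frame.to_csv(Path(path), sep="\t", index=False)


def read_expression_table(path: PathLike) -> ExpressionTable:
    frame = pd.read_csv(Path(path), sep="\t", index_col=0)
    return ExpressionTable(frame)


def write_expression_table(table: ExpressionTable, path: PathLike) -> None:
    out = table.values.copy()
    out.index.name = "tss_id"
    out.to_csv(Path(path), sep="\t", float_format="%.6g")


def read_intervals(path: PathLike) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open), sorted per chromosome.

    Column 4 becomes ``name`` and column 6 ``strand`` when present; track
    and browser lines and '#' comments are skipped.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: malformed coordinates"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = None
            if len(fields) > 5 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name)
            )
    intervals.sort(key=lambda iv: (iv.chromosome, iv.start, iv.end, iv.name or ""))
    return intervals


def write_intervals(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [
                        iv.chromosome,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        "0",
                        iv.strand or ".",
                    ]
                )
                + "\n"
            )


def write_dmr_bed(calls: Sequence[DMRCall], path: PathLike) -> None:
    """Write DMR calls as BED6+3: name, capped 1000x|mean delta| score,
    strand '.', then n_probes, direction, mean_delta columns."""
    with Path(path).open("w") as fh:
        for i, call in enumerate(calls):
            score = min(1000, int(round(1000 * call.mean_abs_delta)))
            signed_mean = float(np.mean(call.deltas))
            name = f"{call.comparison_id or 'dmr'}_{i}"
            fh.write(
                "\t".join(
                    [
                        call.chromosome,
                        str(call.start),
                        str(call.end),
                        name,
                        str(score),
                        ".",
                        str(call.n_probes),
                        call.direction,
                        f"{signed_mean:.6g}",
                        ",".join(call.probe_ids),
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path: PathLike) -> list[DMRCall]:
    """Round-trip reader for :func:`write_dmr_bed` output."""
    calls: list[DMRCall] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path} line {lineno}: not a DMR BED row")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            direction = f[7]
            signed_mean = float(f[8])
            probe_ids = tuple(f[9].split(","))
            n_probes = int(f[6])
            # per-probe deltas are not individually stored in BED; reconstruct
            # a same-sign vector with the recorded mean for metadata fidelity
            deltas = tuple([signed_mean] * n_probes)
            comparison_id = f[3].rsplit("_", 1)[0]
            calls.append(
                DMRCall(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    probe_ids=probe_ids,
                    deltas=deltas,
                    direction=direction,
                    comparison_id=comparison_id,
                )
            )
    return calls
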