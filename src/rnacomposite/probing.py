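"""Readers/writers for per-nucleotide probing tracks and duplex-group tables.

Track files are tab-separated with header ``position base s1 v1 dms`` and
"NA" for missing values; duplex files are tab-separated
``dataset_id left_start left_end right_start right_end reads``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import Interval

__all__ = [
    "ProbingTrack",
    "DuplexGroup",
    "TrackFormatError",
    "read_track",
    "write_track",
    "read_duplexes",
    "write_duplexes",
    "write_bedgraph",
    "track_by_position",
]

TRACK_COLUMNS = ["position", "base", "s1", "v1", "dms"]
DUPLEX_COLUMNS = ["dataset_id", "left_start", "left_end", "right_start", "right_end", "reads"]


class TrackFormatError(ValueError):
    """Invalid probing track or duplex table content."""


@dataclass(frozen=True)
class ProbingTrack:
    """One covered nucleotide: mean S1/V1 nuclease and DMS stop counts.

    ``dms`` is defined only for A/C residues; missing values are None.
    """

    position: int
    base: str
    s1: float | None
    v1: float | None
    dms: float | None

    def __post_init__(self) -> None:
        if self.base not in "ACGUN":
            raise TrackFormatError(f"position {self.position}: bad base {self.base!r}")
        for name in ("s1", "v1", "dms"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise TrackFormatError(
                    f"position {self.position}: negative or non-finite {name}={v}"
                )
        if self.dms is not None and self.base in "GUN":
            raise TrackFormatError(
                f"position {self.position}: DMS count on non-A/C base {self.base}"
            )


@dataclass(frozen=True)
class DuplexGroup:
    """A crosslink-ligation duplex record: two spans plus a read count."""

    dataset_id: str
    left: Interval
    right: Interval
    reads: int

    def __post_init__(self) -> None:
        if self.left.end >= self.right.start:
            raise TrackFormatError(
                f"duplex {self.dataset_id}: left span {self.left} not strictly 5' of "
                f"right span {self.right}"
            )
        if self.reads < 1:
            raise TrackFormatError(f"duplex {self.dataset_id}: reads must be >= 1")


def _parse_cell(raw: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "NA":
        return None
    return float(raw)


def read_track(path) -> list[ProbingTrack]:
    """Read a probing track TSV; validates monotone positions and counts."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TRACK_COLUMNS:
        raise TrackFormatError(f"expected columns {TRACK_COLUMNS}, got {list(df.columns)}")
    rows: list[ProbingTrack] = []
    last_pos = 0
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(rec.position)
            row = ProbingTrack(
                position=pos,
                base=rec.base,
                s1=_parse_cell(rec.s1),
                v1=_parse_cell(rec.v1),
                dms=_parse_cell(rec.dms),
            )
        except (ValueError, TrackFormatError) as exc:
            raise TrackFormatError(f"line {lineno}: {exc}") from exc
        if pos <= last_pos:
            raise TrackFormatError(
                f"line {lineno}: positions not strictly increasing ({pos} after {last_pos})"
            )
        last_pos = pos
        rows.append(row)
    return rows


def write_track(rows: list[ProbingTrack], path) -> None:
    def fmt(v: float | None) -> str:
        if v is None:
            return "NA"
        return f"{v:g}"

    with open(path, "w") as fh:
        fh.write("\t".join(TRACK_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.position}\t{r.base}\t{fmt(r.s1)}\t{fmt(r.v1)}\t{fmt(r.dms)}\n")


def track_by_position(rows: list[ProbingTrack]) -> dict[int, ProbingTrack]:
    return {r.position: r for r in rows}


def read_duplexes(path) -> dict[str, list[DuplexGroup]]:
    """Read a duplex-group TSV, returning records grouped by dataset id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != DUPLEX_COLUMNS:
        raise TrackFormatError(f"expected columns {DUPLEX_COLUMNS}, got {list(df.columns)}")
    grouped: dict[str, list[DuplexGroup]] = {}
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            dup = DuplexGroup(
                dataset_id=rec.dataset_id,
                left=Interval(int(rec.left_start), int(rec.left_end)),
                right=Interval(int(rec.right_start), int(rec.right_end)),
                reads=int(rec.reads),
            )
        except (ValueError, TrackFormatError) as exc:
            raise TrackFormatError(f"line {lineno}: {exc}") from exc
        grouped.setdefault(dup.dataset_id, []).append(dup)
    return grouped


def write_duplexes(duplexes: list[DuplexGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DUPLEX_COLUMNS) + "\n")
        for d in duplexes:
            fh.write(
                f"{d.dataset_id}\t{d.left.start}\t{d.left.end}\t"
                f"{d.right.start}\t{d.right.end}\t{d.reads}\n"
            )


def write_bedgraph(rows: list[ProbingTrack], channel: str, chrom: str, path) -> None:
    """bedGraph export of one count channel (0-based half-open on write)."""
    if channel not in ("s1", "v1", "dms"):
        raise ValueError(f"unknown channel {channel!r}")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}_{channel}"\n')
        for r in rows:
            v = getattr(r, channel)
            if v is not None:
                fh.write(f"{chrom}\t{r.position - 1}\t{r.position}\t{v:g}\n")
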