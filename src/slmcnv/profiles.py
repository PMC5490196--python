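"""Genomic profile containers and tab-delimited I/O.

A *profile* is an ordered set of non-overlapping windows on one chromosome,
each carrying a numeric signal: either a raw read count (RC) or a log2-ratio
relative to the diploid expectation.  Segmentation partitions a profile into
runs of constant mean; CNV calls classify those runs as losses or gains.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ProfileFormatError(ValueError):
    """The on-disk table is missing required columns or is unparseable."""


class ProfileValidationError(ValueError):
    """Window coordinates violate the profile invariants."""


class Scale(enum.Enum):
    """What the per-window value means."""

    RC = "rc"
    LOG2RATIO = "log2ratio"


class CopyState(enum.Enum):
    LOSS = "LOSS"
    NEUTRAL = "NEUTRAL"
    GAIN = "GAIN"


@dataclass(frozen=True)
class GenomicWindow:
    """One window: ``[start, end)`` on ``chrom`` with a numeric signal."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ProfileValidationError(
                f"window end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class GenomicProfile:
    """Ordered, non-overlapping windows of one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name shared by all windows.
    starts, ends : array of int
        0-based half-open window coordinates, sorted by start.
    values : array of float
        Per-window signal, on ``scale``.
    scale : Scale
        Whether ``values`` are raw read counts or log2-ratios.
    gc, mappability : array of float, optional
        Per-window covariates in [0, 1], used by normalization.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    scale: Scale = Scale.LOG2RATIO
    gc: np.ndarray | None = None
    mappability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.starts)
        if n < 1:
            raise ProfileValidationError("profile must contain at least one window")
        if len(self.ends) != n or len(self.values) != n:
            raise ProfileValidationError("starts, ends and values must have equal length")
        if np.any(self.ends <= self.starts):
            i = int(np.argmax(self.ends <= self.starts))
            raise ProfileValidationError(
                f"window end must exceed start at window {i} "
                f"({self.chrom}:{self.starts[i]}-{self.ends[i]})"
            )
        if np.any(np.diff(self.starts) < 0):
            raise ProfileValidationError("windows must be sorted by start")
        if n > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            i = int(np.argmax(self.starts[1:] < self.ends[:-1]))
            raise ProfileValidationError(
                f"windows {i} and {i + 1} overlap on {self.chrom}"
            )
        for name in ("gc", "mappability"):
            cov = getattr(self, name)
            if cov is not None:
                cov = np.asarray(cov, dtype=np.float64)
                if len(cov) != n:
                    raise ProfileValidationError(f"{name} length does not match profile")
                setattr(self, name, cov)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def windows(self) -> list[GenomicWindow]:
        return [
            GenomicWindow(self.chrom, int(s), int(e), float(v))
            for s, e, v in zip(self.starts, self.ends, self.values)
        ]

    def gaps(self) -> np.ndarray:
        """Inter-window genomic distances ``start_i - end_{i-1}`` (bp, length N-1).

        Overlap-free but adjacent windows have gap 0; the floor at 0 makes
        dense tilings reduce exactly to the homogeneous model.
        """
        if len(self) == 1:
            return np.zeros(0, dtype=np.float64)
        return np.maximum(self.starts[1:] - self.ends[:-1], 0).astype(np.float64)

    def replace_values(self, values: np.ndarray, scale: Scale) -> "GenomicProfile":
        """Copy of this profile with new values (coordinates unchanged)."""
        return GenomicProfile(
            self.chrom, self.starts.copy(), self.ends.copy(),
            np.asarray(values, dtype=np.float64), scale,
            None if self.gc is None else self.gc.copy(),
            None if self.mappability is None else self.mappability.copy(),
        )

    def subset(self, mask: np.ndarray) -> "GenomicProfile":
        """Profile restricted to windows where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenomicProfile(
            self.chrom, self.starts[mask], self.ends[mask], self.values[mask],
            self.scale,
            None if self.gc is None else self.gc[mask],
            None if self.mappability is None else self.mappability[mask],
        )


@dataclass(frozen=True)
class Segment:
    """Run of windows ``[start_index, end_index]`` (inclusive) at one mean level."""

    start_index: int
    end_index: int
    mean_level: float

    @property
    def n_windows(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class Segmentation:
    """Decoded piecewise-constant mean of a profile.

    ``levels[i]`` is the decoded mean for window *i*; ``segments`` is the
    run-length-collapsed view; ``breakpoints`` lists every window index *i*
    with ``levels[i] != levels[i-1]``.
    """

    levels: np.ndarray
    segments: list[Segment]
    breakpoints: list[int]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        n = len(self.levels)
        if not self.segments:
            raise ProfileValidationError("segmentation must contain at least one segment")
        if self.segments[0].start_index != 0 or self.segments[-1].end_index != n - 1:
            raise ProfileValidationError("segments must span the whole profile")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_index != a.end_index + 1:
                raise ProfileValidationError("segments must tile the profile without gaps")
        if len(self.segments) != len(self.breakpoints) + 1:
            raise ProfileValidationError("segment count must equal breakpoint count + 1")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @classmethod
    def from_levels(cls, levels: np.ndarray) -> "Segmentation":
        """Collapse a per-window level vector into runs."""
        levels = np.asarray(levels, dtype=np.float64)
        change = np.flatnonzero(levels[1:] != levels[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(levels)]))
        segments = [
            Segment(int(a), int(b - 1), float(levels[a]))
            for a, b in zip(bounds[:-1], bounds[1:])
        ]
        return cls(levels, segments, [int(c) for c in change])


@dataclass(frozen=True)
class CNVCall:
    """A called altered (or neutral) interval on genomic coordinates."""

    chrom: str
    start: int
    end: int
    copy_state: CopyState
    mean_level: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ProfileValidationError("CNV call end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


_DEFAULT_COLUMNS: dict[str, int] = {"chrom": 0, "start": 1, "end": 2, "value": 3}
_OPTIONAL_COLUMNS = ("gc", "mappability")


def _fmt(x: float) -> str:
    # shortest repr that round-trips the double exactly
    return repr(float(x))


def read_profile(
    path,
    column_spec: Mapping[str, int | str] | None = None,
    scale: Scale = Scale.LOG2RATIO,
    has_header: bool | None = None,
) -> list[GenomicProfile]:
    """Read a tab-delimited profile table, one :class:`GenomicProfile` per chromosome.

    The table needs chrom/start/end/value columns; ``column_spec`` maps those
    roles (plus optional ``gc`` and ``mappability``) to integer positions or,
    with a header line, to column names.  Rows are sorted by start within each
    chromosome, so shuffled input parses to the same profile as sorted input.
    gzip input is handled transparently by file extension.

    Returns profiles in order of first appearance of each chromosome.
    """
    spec = dict(_DEFAULT_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    for role in ("chrom", "start", "end", "value"):
        if role not in spec:
            raise ProfileFormatError(f"column_spec is missing required role {role!r}")

    by_name = any(isinstance(v, str) for v in spec.values())
    if has_header is None:
        has_header = by_name
    try:
        df = pd.read_csv(
            path, sep="\t", header=0 if has_header else None,
            comment="#", compression="infer", dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ProfileFormatError(f"cannot parse {path}: {exc}") from exc

    def col(role: str) -> pd.Series:
        key = spec[role]
        if isinstance(key, str):
            if key not in df.columns:
                raise ProfileFormatError(f"missing required column {key!r} for role {role!r}")
            return df[key]
        if key >= df.shape[1]:
            raise ProfileFormatError(
                f"column index {key} for role {role!r} out of range "
                f"(table has {df.shape[1]} columns)"
            )
        return df.iloc[:, key]

    # astype(float64) is a correctly-rounded parse (pd.to_numeric is not),
    # which the bit-exact round-trip guarantee relies on
    data = pd.DataFrame({
        "chrom": col("chrom").astype(str),
        "start": pd.to_numeric(col("start")),
        "end": pd.to_numeric(col("end")),
        "value": col("value").astype(np.float64),
    })
    for role in _OPTIONAL_COLUMNS:
        if role in spec:
            data[role] = col(role).astype(np.float64)

    bad = data["end"] <= data["start"]
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 1  # 1-based data row
        raise ProfileValidationError(f"end <= start at data row {row}")

    profiles: list[GenomicProfile] = []
    for chrom in data["chrom"].unique():
        sub = data[data["chrom"] == chrom].sort_values("start", kind="mergesort")
        profiles.append(
            GenomicProfile(
                str(chrom),
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(np.float64),
                scale,
                sub["gc"].to_numpy(np.float64) if "gc" in sub else None,
                sub["mappability"].to_numpy(np.float64) if "mappability" in sub else None,
            )
        )
    if not profiles:
        raise ProfileFormatError(f"no data rows in {path}")
    return profiles


def write_profile(profiles: GenomicProfile | Iterable[GenomicProfile], path) -> None:
    """Write profiles as a headerless tab-delimited table (chrom, start, end, value[, gc, map]).

    Float values are written with full round-trip precision, so
    ``read_profile(write_profile(...))`` is bit-exact.
    """
    if isinstance(profiles, GenomicProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        for p in profiles:
            extra = [c for c in (p.gc, p.mappability) if c is not None]
            for i in range(len(p)):
                row = [p.chrom, str(int(p.starts[i])), str(int(p.ends[i])), _fmt(p.values[i])]
                row += [_fmt(c[i]) for c in extra]
                fh.write("\t".join(row) + "\n")


def segment_rows(seg: Segmentation, profile: GenomicProfile) -> list[str]:
    """Tab-delimited segment rows: chrom, start_bp, end_bp, n_windows, mean_level.

    Segment bp coordinates come from the first window's start and the last
    window's end of each segment; means keep full float precision.
    """
    if len(seg.levels) != len(profile):
        raise ProfileValidationError(
            f"segmentation length {len(seg.levels)} does not match profile length {len(profile)}"
        )
    return [
        "\t".join([
            profile.chrom,
            str(int(profile.starts[s.start_index])),
            str(int(profile.ends[s.end_index])),
            str(s.n_windows),
            _fmt(s.mean_level),
        ])
        for s in seg.segments
    ]


def write_segments(seg: Segmentation, profile: GenomicProfile, path) -> None:
    """Write the :func:`segment_rows` table to ``path``."""
    with open(path, "w") as fh:
        for row in segment_rows(seg, profile):
            fh.write(row + "\n")


def read_segments(path) -> pd.DataFrame:
    """Read a table written by :func:`write_segments`."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "n_windows", "mean_level"],
    )
    return df


def write_cnv_bed(calls: Sequence[CNVCall], path) -> None:
    """Write CNV calls as BED: chrom, start, end, state, mean_level."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_state.value}\t{_fmt(c.mean_level)}\n"
            )


def read_cnv_bed(path) -> list[CNVCall]:
    """Read a BED of calls written by :func:`write_cnv_bed` (or truth intervals).

    A missing 5th column defaults the mean level to -1 for LOSS, +log2(3/2)
    for GAIN and 0 for NEUTRAL so that truth BEDs need only four columns.
    """
    defaults = {
        CopyState.LOSS: -1.0,
        CopyState.GAIN: float(np.log2(1.5)),
        CopyState.NEUTRAL: 0.0,
    }
    calls: list[CNVCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ProfileFormatError("CNV BED needs at least 4 columns")
            state = CopyState(parts[3])
            mean = float(parts[4]) if len(parts) > 4 else defaults[state]
            calls.append(CNVCall(parts[0], int(parts[1]), int(parts[2]), state, mean))
    return calls
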