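"""Stepwise per-base coverage tracks with Bedgraph semantics.

A track stores, per chromosome, sorted non-overlapping (start, end, value)
steps; every position not covered by a step has implicit value 0 (as emitted
by ``genomeCoverageBed -bga``, whose explicit zero rows are equivalent to
gaps).  Queries are exact per-base semantics; interval means are computed
from cumulative step mass without materialising per-base arrays.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, TextIO, Union

import numpy as np

from .intervals import GenomicInterval


class BedgraphFormatError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class _ChromSteps:
    """Sorted non-overlapping steps on one chromosome, with cumulative mass."""

    __slots__ = ("starts", "ends", "values", "_cummass")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, values: np.ndarray):
        self.starts = starts
        self.ends = ends
        self.values = values
        lengths = (ends - starts).astype(np.float64)
        self._cummass = np.concatenate(([0.0], np.cumsum(values * lengths)))

    @property
    def total(self) -> float:
        return float(self._cummass[-1])

    def mass_upto(self, pos) -> np.ndarray:
        """Total signal mass in [0, pos); vectorised over pos."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        n = len(self.starts)
        k = np.searchsorted(self.ends, pos, side="right")
        full = self._cummass[k]
        if n == 0:
            return full
        kk = np.minimum(k, n - 1)
        overlap = (k < n) & (self.starts[kk] < pos)
        partial = np.where(overlap, self.values[kk] * (pos - self.starts[kk]), 0.0)
        return full + partial

    def dense(self, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions < 0 are zero."""
        out = np.zeros(end - start, dtype=np.float64)
        lo = np.searchsorted(self.ends, start, side="right")
        hi = np.searchsorted(self.starts, end, side="left")
        for i in range(lo, hi):
            a = max(self.starts[i], start)
            b = min(self.ends[i], end)
            if b > a:
                out[a - start : b - start] = self.values[i]
        return out


class CoverageTrack:
    """Per-chromosome stepwise coverage with implicit zeros in gaps."""

    def __init__(
        self,
        steps: Optional[Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
        *,
        label: str = "",
        total_mapped_reads: Optional[int] = None,
    ):
        self.label = label
        self.total_mapped_reads = total_mapped_reads
        self._chroms: dict[str, _ChromSteps] = {}
        if steps:
            for chrom, (s, e, v) in steps.items():
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    # -- construction ------------------------------------------------------

    def _set_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: empty or inverted step")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping steps")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError(f"{chrom}: negative or non-finite value")
        keep = values != 0.0  # zeros are implicit
        self._chroms[chrom] = _ChromSteps(starts[keep], ends[keep], values[keep])

    @classmethod
    def from_dense(
        cls,
        dense: Mapping[str, np.ndarray],
        *,
        label: str = "",
        total_mapped_reads: Optional[int] = None,
    ) -> "CoverageTrack":
        """Build a track from per-chromosome dense arrays (run-length encoded)."""
        track = cls(label=label, total_mapped_reads=total_mapped_reads)
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                track._chroms[chrom] = _ChromSteps(
                    np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)
                )
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            track._set_chrom(chrom, starts, ends, values)
        return track

    # -- inspection --------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cs = self._chroms[chrom]
        return cs.starts.copy(), cs.ends.copy(), cs.values.copy()

    # -- queries -----------------------------------------------------------

    def query(self, interval: GenomicInterval) -> tuple[np.ndarray, float]:
        """Per-base values and their mean over an interval.

        An interval on a chromosome absent from the track yields an all-zero
        vector and sets :attr:`last_query_missing_chrom` (annotation and
        track chromosome sets rarely match exactly, so this is a warning
        condition rather than an error).
        """
        self.last_query_missing_chrom = interval.chrom not in self._chroms
        if self.last_query_missing_chrom:
            values = np.zeros(len(interval), dtype=np.float64)
        else:
            values = self._chroms[interval.chrom].dense(interval.start, interval.end)
        return values, float(values.mean())

    def interval_means(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorised per-base means over many [start, end) intervals."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(ends <= starts):
            raise ValueError("empty interval in interval_means")
        if chrom not in self._chroms:
            return np.zeros(len(starts), dtype=np.float64)
        cs = self._chroms[chrom]
        mass = cs.mass_upto(ends) - cs.mass_upto(np.maximum(starts, 0))
        return mass / (ends - starts)

    def scaled(self, factor: float) -> "CoverageTrack":
        """A copy with every step value multiplied by ``factor``."""
        out = CoverageTrack(label=self.label, total_mapped_reads=self.total_mapped_reads)
        for chrom, cs in self._chroms.items():
            out._set_chrom(chrom, cs.starts, cs.ends, cs.values * factor)
        return out

    # -- summaries ---------------------------------------------------------

    def total_signal(self) -> float:
        return sum(cs.total for cs in self._chroms.values())


@dataclass(frozen=True)
class TrackSummary:
    """Library-size summary used for per-million normalisation."""

    total_signal: float
    normaliser: float
    scale_per_million: float
    basis: str  # 'declared_reads' or 'signal_over_read_length'


def track_total(
    track: CoverageTrack,
    *,
    read_length_bp: int = 50,
    basis: str = "reads",
) -> TrackSummary:
    """Summarise a track's library size for per-million scaling.

    With ``basis='reads'`` the normaliser is the declared mapped-read count
    when present, else ``total_signal / read_length_bp`` (each mapped read
    contributes read_length_bp of signal mass, so this recovers the read
    count of an alignment-derived track).  ``basis='bases'`` normalises by
    total signal mass instead.
    """
    total = track.total_signal()
    if basis == "bases":
        normaliser = total
        label = "mapped_bases"
    elif basis == "reads":
        if track.total_mapped_reads is not None:
            normaliser = float(track.total_mapped_reads)
            label = "declared_reads"
        else:
            normaliser = total / read_length_bp
            label = "signal_over_read_length"
    else:
        raise ValueError(f"unknown basis {basis!r}")
    scale = 1e6 / normaliser if normaliser > 0 else 0.0
    return TrackSummary(total_signal=total, normaliser=normaliser, scale_per_million=scale, basis=label)


# --------------------------------------------------------------------------
# Bedgraph I/O
# --------------------------------------------------------------------------

def _open_text(source: Union[str, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if str(source).endswith(".gz"):
        return gzip.open(source, "rt")
    return open(source, "rt")


def read_bedgraph(
    source: Union[str, TextIO, Iterable[str]],
    *,
    label: str = "",
    total_mapped_reads: Optional[int] = None,
) -> CoverageTrack:
    """Read a 4-column Bedgraph into a :class:`CoverageTrack`.

    ``track``/``browser`` header lines and comments are skipped; zero-valued
    rows (as ``-bga`` emits) are accepted and folded into the implicit-zero
    gaps.  Overlapping steps or negative values raise
    :class:`BedgraphFormatError` with the offending line number.
    A ``#total_mapped_reads=N`` comment, when present, sets the declared
    library size.
    """
    if hasattr(source, "read") or isinstance(source, str):
        stream: Iterator[str] = iter(_open_text(source))  # type: ignore[arg-type]
    else:
        stream = iter(source)

    per_chrom: dict[str, list[tuple[int, int, float, int]]] = {}
    declared = total_mapped_reads
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#total_mapped_reads="):
                declared = int(line.split("=", 1)[1])
            continue
        if line.startswith(("track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise BedgraphFormatError(lineno, f"expected 4 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise BedgraphFormatError(lineno, str(exc)) from exc
        if start < 0 or end <= start:
            raise BedgraphFormatError(lineno, f"invalid interval [{start}, {end})")
        if value < 0 or not np.isfinite(value):
            raise BedgraphFormatError(lineno, f"negative or non-finite value {fields[3]}")
        per_chrom.setdefault(chrom, []).append((start, end, value, lineno))

    track = CoverageTrack(label=label, total_mapped_reads=declared)
    for chrom, rows in per_chrom.items():
        rows.sort(key=lambda r: r[0])
        prev_end = -1
        for start, end, _value, lineno in rows:
            if start < prev_end:
                raise BedgraphFormatError(lineno, f"{chrom}: step [{start}, {end}) overlaps previous step")
            prev_end = end
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=np.float64)
        track._set_chrom(chrom, starts, ends, values)
    return track


def write_bedgraph(track: CoverageTrack, stream: TextIO) -> None:
    """Write sorted 4-column Bedgraph; contiguous equal-value steps merged.

    Values print in their shortest round-trip representation (``repr`` of a
    Python float, with integral values printed as integers), so a
    write → read cycle reproduces every per-base value exactly.
    """
    if track.total_mapped_reads is not None:
        stream.write(f"#total_mapped_reads={track.total_mapped_reads}\n")
    for chrom in track.chromosomes:
        starts, ends, values = track.steps(chrom)
        i = 0
        n = len(starts)
        while i < n:
            j = i
            while j + 1 < n and ends[j] == starts[j + 1] and values[j + 1] == values[i]:
                j += 1
            v = values[i]
            text = str(int(v)) if v == int(v) else repr(float(v))
            stream.write(f"{chrom}\t{starts[i]}\t{ends[j]}\t{text}\n")
            i = j + 1
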