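"""Piecewise-constant coverage tracks with bedGraph semantics.

A track stores, per chromosome, sorted non-overlapping segments
``(starts, ends, values)``; positions not covered by any segment carry
signal 0 (genome-browser gap semantics, not missing data). Tracks can be
library-size normalized to "signal per million": after normalization the
genome-wide integral ``sum(value * span)`` equals 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CoverageTrack", "read_bedgraph", "write_bedgraph"]


@dataclass
class _ChromSignal:
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray


@dataclass
class CoverageTrack:
    """Per-chromosome piecewise-constant, non-negative signal."""

    factor: str = ""
    condition: str = ""
    replicate: int = 0
    normalized: bool = False
    _chroms: dict[str, _ChromSignal] = field(default_factory=dict)

    def add_chrom(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise ValueError(f"{chrom}: negative signal values")
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: start >= end segment")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping bedGraph segments")
        self._chroms[chrom] = _ChromSignal(starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sig = self._chroms[chrom]
        return sig.starts, sig.ends, sig.values

    @property
    def total_signal(self) -> float:
        """Genome-wide integral sum(value * span)."""
        return float(
            sum(
                np.sum(sig.values * (sig.ends - sig.starts))
                for sig in self._chroms.values()
            )
        )

    def scale(self, c: float) -> "CoverageTrack":
        out = CoverageTrack(self.factor, self.condition, self.replicate, self.normalized)
        for chrom, sig in self._chroms.items():
            out._chroms[chrom] = _ChromSignal(sig.starts, sig.ends, sig.values * c)
        return out

    def normalize(self, target: float = 1e6) -> "CoverageTrack":
        """Return a copy scaled so the genome-wide integral equals ``target``."""
        total = self.total_signal
        if total <= 0:
            raise ValueError("cannot normalize a track with zero total signal")
        out = self.scale(target / total)
        out.normalized = True
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over ``[start, end)``; 0 over gaps."""
        if start >= end:
            raise ValueError("window start must be < end")
        sig = self._chroms.get(chrom)
        if sig is None:
            return 0.0
        i = int(np.searchsorted(sig.ends, start, side="right"))
        j = int(np.searchsorted(sig.starts, end, side="left"))
        if i >= j:
            return 0.0
        ov = np.minimum(sig.ends[i:j], end) - np.maximum(sig.starts[i:j], start)
        return float(np.sum(sig.values[i:j] * ov))

    def window_density(self, chrom: str, start: int, end: int, chrom_size: int | None = None) -> float:
        """Mean signal per bp over ``[start, end)``.

        Raises if the window falls outside the chromosome when a size is given.
        """
        if chrom_size is not None and (start < 0 or end > chrom_size):
            raise ValueError(f"window [{start}, {end}) outside {chrom} of size {chrom_size}")
        return self.window_sum(chrom, start, end) / (end - start)

    def bin_sums(self, chrom: str, chrom_size: int, bin_bp: int) -> np.ndarray:
        """Integral of the signal in consecutive ``bin_bp`` tiles of the chromosome."""
        n_bins = int(np.ceil(chrom_size / bin_bp))
        out = np.zeros(n_bins)
        sig = self._chroms.get(chrom)
        if sig is None:
            return out
        # distribute each segment's mass over the bins it spans,
        # clipping anything past the stated chromosome size
        for s, e, v in zip(sig.starts, sig.ends, sig.values):
            s, e = max(int(s), 0), min(int(e), chrom_size)
            if e <= s:
                continue
            b0, b1 = s // bin_bp, (e - 1) // bin_bp
            if b0 == b1:
                out[b0] += v * (e - s)
            else:
                out[b0] += v * ((b0 + 1) * bin_bp - s)
                out[b0 + 1 : b1] += v * bin_bp
                out[b1] += v * (e - b1 * bin_bp)
        return out


def read_bedgraph(
    path: str | Path,
    factor: str = "",
    condition: str = "",
    replicate: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> CoverageTrack:
    """Read a bedGraph file; gaps are signal 0; overlapping segments are an error.

    Rows on chromosomes absent from ``chrom_sizes`` (when given) are dropped
    with a logged count.
    """
    track = CoverageTrack(factor=factor, condition=condition, replicate=replicate)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            if s >= e:
                logger.warning("%s:%d: start >= end, record rejected", path, lineno)
                continue
            if chrom_sizes is not None and chrom not in chrom_sizes:
                n_dropped += 1
                continue
            by_chrom.setdefault(chrom, []).append((s, e, v))
    if n_dropped:
        logger.info("%s: dropped %d rows on chromosomes absent from chrom_sizes", path, n_dropped)
    for chrom, rows in by_chrom.items():
        arr = np.array(rows, dtype=float)
        track.add_chrom(chrom, arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path, omit_zero: bool = True) -> None:
    """Write a track as bedGraph; zero-valued segments are omitted by default."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.segments(chrom)
            for s, e, v in zip(starts, ends, values):
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
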