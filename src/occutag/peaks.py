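"""Peak sets: scored intervals for one factor/condition (BED6 / narrowPeak I/O)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Peak", "PeakSet", "read_peaks", "write_narrowpeak"]


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    summit: int | None = None  # absolute coordinate

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: width must be > 0")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    factor: str = ""
    condition: str = ""
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def widths(self) -> list[int]:
        return [p.width for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "score": [p.score for p in self.peaks],
            }
        )


def read_peaks(
    path: str | Path,
    format: str = "narrowPeak",
    factor: str = "",
    condition: str = "",
    chrom_sizes: dict[str, int] | None = None,
) -> PeakSet:
    """Read a BED6 or narrowPeak (BED6+4) file into a sorted, validated PeakSet.

    narrowPeak column 10 is the summit offset from ``start``; -1 means no
    summit. Records with start >= end are rejected with a warning; records on
    chromosomes absent from ``chrom_sizes`` (when given) are dropped.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                logger.warning("%s:%d: start >= end, record rejected", path, lineno)
                continue
            if chrom_sizes is not None and chrom not in chrom_sizes:
                n_dropped += 1
                continue
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            summit = None
            if format == "narrowPeak" and len(f) >= 10:
                off = int(f[9])
                summit = start + off if off >= 0 else None
            peaks.append(Peak(chrom, start, end, name, score, summit))
    if n_dropped:
        logger.info("%s: dropped %d peaks on chromosomes absent from chrom_sizes", path, n_dropped)
    return PeakSet(factor=factor, condition=condition, peaks=peaks)


def write_narrowpeak(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            off = p.summit - p.start if p.summit is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t0\t-1\t-1\t{off}\n"
            )
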