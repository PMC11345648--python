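"""Gene models, CpG-island annotation, and the readers that build them.

Internally every interval is 0-based half-open. GTF input (1-based, closed)
is converted at the boundary; BED-family inputs are taken as-is. A gene's
TSS/TES are strand-aware single-base anchors: for a plus-strand gene on
``[start, end)`` the TSS is ``start`` and the TES is ``end - 1``; on the
minus strand the two are swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_models",
    "write_gene_models_gtf",
    "read_cgis",
    "write_bed",
]


@dataclass
class GeneModel:
    """One gene: location, strand, exon structure, and derived TSS/TES anchors."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty if < 2 exons)."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus strand-aware gene models and CGI intervals."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    cgis: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > size:
                raise ValueError(f"gene {g.gene_id} outside [0, {size})")
        for chrom, s, e in self.cgis:
            size = self.chrom_sizes.get(chrom)
            if size is None or s < 0 or e > size or s >= e:
                raise ValueError(f"invalid CGI ({chrom}, {s}, {e})")

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV chrom → length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from minimal GTF (gene + optional exon records) or BED12.

    GTF coordinates are 1-based closed and converted to 0-based half-open
    (``start - 1``, ``end`` unchanged). Records with an unknown strand are
    rejected with a warning; malformed lines raise with their line number.
    """
    path = Path(path)
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r, record rejected", path, lineno, strand)
                continue
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                genes[gene_id] = GeneModel(gene_id, chrom, strand, start0, end0)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append((start0, end0))
    if n_lines == 0:
        logger.warning("%s: empty gene-model file", path)
    out = []
    for gid, g in genes.items():
        g.exons = sorted(exons.get(gid, []))
        g.__post_init__()
        out.append(g)
    return out


def _read_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                logger.warning("%s:%d: unknown strand %r, record rejected", path, lineno, strand)
                continue
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append(GeneModel(name, chrom, strand, start, end, exons))
    if not out:
        logger.warning("%s: no gene records read", path)
    return out


def write_gene_models_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write minimal GTF (gene + exon records, 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\toccutag\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attr}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\toccutag\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attr}\n")


def read_cgis(path: str | Path) -> list[tuple[str, int, int]]:
    """CGI intervals from a BED3+ file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            s, e = int(f[1]), int(f[2])
            if s >= e:
                logger.warning("%s:%d: start >= end, record rejected", path, lineno)
                continue
            out.append((f[0], s, e))
    return sorted(out)


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
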