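"""Per-base brute-force oracles, independent of the package's interval engine.

Everything here materialises explicit per-base arrays and answers queries by
scanning them, so it is only usable on toy genomes (<= ~100 kb) but is
trivially correct under half-open semantics.
"""

from __future__ import annotations

import numpy as np

FEATURES = ("promoter", "exon", "intron", "distal_intergenic")


def bf_overlaps(a, b) -> bool:
    return len(set(range(a[0], a[1])) & set(range(b[0], b[1]))) >= 1


def bf_intersection_length(a, b) -> int:
    return len(set(range(a[0], a[1])) & set(range(b[0], b[1])))


def bf_merge(intervals, genome_len):
    occ = np.zeros(genome_len + 2, dtype=np.int8)
    for s, e in intervals:
        occ[s:e] = 1
    diff = np.diff(occ)
    starts = np.where(diff == 1)[0] + 1
    if occ[0]:
        starts = np.r_[0, starts]
    ends = np.where(diff == -1)[0] + 1
    return list(zip(starts.tolist(), ends.tolist()))


def bf_value_array(segments, genome_len):
    """Explicit per-base value array from (s, e, v) segments (gaps are 0)."""
    arr = np.zeros(genome_len)
    for s, e, v in segments:
        arr[s:e] = v
    return arr


def bf_window_density(segments, start, end):
    """segments: list of (s, e, v); returns mean per-base value over [start, end)."""
    total = 0.0
    for pos in range(start, end):
        for s, e, v in segments:
            if s <= pos < e:
                total += v
                break
    return total / (end - start)


def bf_strand_window(anchor, strand, up, down):
    if strand == "+":
        return anchor - up, anchor + down
    return anchor + 1 - down, anchor + 1 + up


def bf_paint(genes, chrom_len, promoter_window):
    """Per-base class codes: 0 distal, 1 intron, 2 exon, 3 promoter."""
    up, down = promoter_window
    paint = np.zeros(chrom_len, dtype=np.int8)
    for g in genes:
        exonic = np.zeros(chrom_len, dtype=bool)
        for s, e in g.exons:
            exonic[s:e] = True
        for pos in range(g.start, g.end):
            code = 2 if exonic[pos] else 1
            paint[pos] = max(paint[pos], code)
    for g in genes:
        ws, we = bf_strand_window(g.tss, g.strand, up, down)
        ws, we = max(ws, 0), min(we, chrom_len)
        paint[ws:we] = 3
    return paint


def bf_annotate(peak, paint):
    """Label by the highest-priority painted base the peak overlaps."""
    top = int(paint[peak[0] : peak[1]].max()) if peak[1] > peak[0] else 0
    return {3: "promoter", 2: "exon", 1: "intron", 0: "distal_intergenic"}[top]


def bf_bound(gene, peaks, chrom_len, up=2000, down_tes=300):
    if gene.strand == "+":
        ws, we = gene.start - up, gene.end + down_tes
    else:
        ws, we = gene.start - down_tes, gene.end + up
    ws, we = max(ws, 0), min(we, chrom_len)
    window = np.zeros(chrom_len, dtype=bool)
    window[ws:we] = True
    for s, e in peaks:
        if window[max(s, 0) : min(e, chrom_len)].any():
            return True
    return False
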