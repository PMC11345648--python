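"""Peak classification by genomic feature and CpG-island context.

Each peak receives exactly one feature label under the priority
promoter > exon > intron > distal_intergenic (a peak overlapping both a
promoter window and an exon counts as promoter), the convention implied by
standard ChIP annotation tools. Overlap means >= 1 bp under half-open
semantics; a majority-overlap rule is available via ``min_overlap_frac``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation
from .intervals import IntervalIndex, strand_window, clamp, intersection_length
from .peaks import PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_PRIORITY",
    "annotate_features",
    "feature_summary",
    "classify_cgi",
    "cgi_summary",
    "co_occupancy",
    "width_stats",
]

FEATURE_PRIORITY = ("promoter", "exon", "intron", "distal_intergenic")


def _feature_intervals(
    ann: GenomeAnnotation, promoter_window: tuple[int, int]
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    up, down = promoter_window
    out: dict[str, dict[str, list[tuple[int, int]]]] = {
        "promoter": {}, "exon": {}, "intron": {}
    }
    for g in ann.genes:
        size = ann.chrom_sizes[g.chrom]
        ps, pe = clamp(*strand_window(g.tss, g.strand, up, down), size)
        if pe > ps:
            out["promoter"].setdefault(g.chrom, []).append((ps, pe))
        exons = g.exons if g.exons else []
        for s, e in exons:
            out["exon"].setdefault(g.chrom, []).append((s, e))
        # intron = gene body minus exons (whole body if no exon structure given)
        pos = g.start
        for s, e in exons:
            if s > pos:
                out["intron"].setdefault(g.chrom, []).append((pos, s))
            pos = max(pos, e)
        if g.end > pos:
            out["intron"].setdefault(g.chrom, []).append((pos, g.end))
    return out


def annotate_features(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    promoter_window: tuple[int, int] = (2000, 500),
    min_overlap_frac: float = 0.0,
) -> pd.DataFrame:
    """Label every peak with exactly one genomic feature.

    ``promoter_window`` is (upstream_bp, downstream_bp) around the TSS,
    strand-aware. With ``min_overlap_frac`` > 0 a class is only eligible if
    at least that fraction of the peak overlaps it (majority rule at 0.5);
    the default is the >= 1 bp rule.
    """
    if len(peaks) == 0:
        logger.warning("empty peak set: empty annotation returned")
    feats = _feature_intervals(ann, promoter_window)
    if min_overlap_frac <= 0.0:
        idx = {
            cls: {c: IntervalIndex(ivs) for c, ivs in feats[cls].items()}
            for cls in ("promoter", "exon", "intron")
        }
        labels = []
        for p in peaks:
            label = "distal_intergenic"
            for cls in ("promoter", "exon", "intron"):
                ix = idx[cls].get(p.chrom)
                if ix is not None and ix.any_overlap(p.start, p.end):
                    label = cls
                    break
            labels.append(label)
    else:
        labels = []
        for p in peaks:
            label = "distal_intergenic"
            for cls in ("promoter", "exon", "intron"):
                ivs = feats[cls].get(p.chrom, [])
                ov = sum(intersection_length((p.start, p.end), iv) for iv in ivs)
                if ov >= min_overlap_frac * p.width:
                    label = cls
                    break
            labels.append(label)
    df = peaks.to_frame()
    df["feature"] = labels
    return df


def feature_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per feature class (percentages sum to 100)."""
    counts = annotated["feature"].value_counts()
    total = max(len(annotated), 1)
    rows = [
        {"feature": cls, "count": int(counts.get(cls, 0)),
         "percent": 100.0 * counts.get(cls, 0) / total}
        for cls in FEATURE_PRIORITY
    ]
    return pd.DataFrame(rows)


def classify_cgi(
    peaks_or_annotated: PeakSet | pd.DataFrame,
    ann: GenomeAnnotation,
    tss_flank: int = 500,
) -> pd.DataFrame:
    """Flag peaks overlapping CGIs and TSS-proximal CGIs.

    A TSS-proximal CGI is a CGI that itself overlaps the strand-aware window
    ``tss_flank`` bp up- and downstream of some TSS (the TSS base included,
    so at ``tss_flank=0`` only CGIs containing the TSS base qualify).
    TSS-proximal CGIs are a subset of CGIs, so the peak-level implication
    tss_proximal_cgi_overlap => cgi_overlap always holds.
    """
    if isinstance(peaks_or_annotated, PeakSet):
        df = peaks_or_annotated.to_frame()
    else:
        df = peaks_or_annotated.copy()

    windows: dict[str, list[tuple[int, int]]] = {}
    for g in ann.genes:
        ws, we = clamp(
            *strand_window(g.tss, g.strand, tss_flank, tss_flank + 1),
            ann.chrom_sizes[g.chrom],
        )
        windows.setdefault(g.chrom, []).append((ws, we))
    win_idx = {c: IntervalIndex(ivs) for c, ivs in windows.items()}

    proximal = []
    for c, s, e in ann.cgis:
        ix = win_idx.get(c)
        if ix is not None and ix.any_overlap(s, e):
            proximal.append((c, s, e))

    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in ann.cgis:
        cgi_by_chrom.setdefault(c, []).append((s, e))
    prox_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in proximal:
        prox_by_chrom.setdefault(c, []).append((s, e))
    cgi_idx = {c: IntervalIndex(v) for c, v in cgi_by_chrom.items()}
    prox_idx = {c: IntervalIndex(v) for c, v in prox_by_chrom.items()}

    def flag(idx_map, row):
        ix = idx_map.get(row.chrom)
        return bool(ix is not None and ix.any_overlap(row.start, row.end))

    df["cgi_overlap"] = [flag(cgi_idx, r) for r in df.itertuples()]
    df["tss_proximal_cgi_overlap"] = [flag(prox_idx, r) for r in df.itertuples()]
    return df


def cgi_summary(flagged: pd.DataFrame) -> pd.DataFrame:
    """Three-way counts/percentages: CGI, TSS-proximal CGI, non-CGI peaks."""
    n = max(len(flagged), 1)
    n_cgi = int(flagged["cgi_overlap"].sum())
    n_prox = int(flagged["tss_proximal_cgi_overlap"].sum())
    rows = [
        {"group": "cgi", "count": n_cgi, "percent": 100.0 * n_cgi / n},
        {"group": "tss_proximal_cgi", "count": n_prox, "percent": 100.0 * n_prox / n},
        {"group": "non_cgi", "count": len(flagged) - n_cgi,
         "percent": 100.0 * (len(flagged) - n_cgi) / n},
    ]
    return pd.DataFrame(rows)


def co_occupancy(peaks_a: PeakSet, peaks_b: PeakSet) -> dict:
    """Directional co-occupancy: peaks of one set overlapping >= 1 peak of the other."""

    def count(a: PeakSet, b: PeakSet) -> int:
        idx = {
            c: IntervalIndex([(p.start, p.end) for p in plist])
            for c, plist in b.by_chrom().items()
        }
        total = 0
        for p in a:
            ix = idx.get(p.chrom)
            if ix is not None and ix.any_overlap(p.start, p.end):
                total += 1
        return total

    ca = count(peaks_a, peaks_b)
    cb = count(peaks_b, peaks_a)
    return {
        "countA_overlapping_B": ca,
        "countB_overlapping_A": cb,
        "fracA": ca / len(peaks_a) if len(peaks_a) else float("nan"),
        "fracB": cb / len(peaks_b) if len(peaks_b) else float("nan"),
    }


def width_stats(peaks_a: PeakSet, peaks_b: PeakSet) -> dict:
    """Peak-width medians/quartiles per set plus a two-sided Mann-Whitney U p."""
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValueError("width_stats requires two non-empty peak sets")
    wa = np.asarray(peaks_a.widths(), dtype=float)
    wb = np.asarray(peaks_b.widths(), dtype=float)
    out = {
        "A": {"n": len(wa), "median": float(np.median(wa)),
              "q1": float(np.percentile(wa, 25)), "q3": float(np.percentile(wa, 75))},
        "B": {"n": len(wb), "median": float(np.median(wb)),
              "q1": float(np.percentile(wb, 25)), "q3": float(np.percentile(wb, 75))},
    }
    if len(wa) < 2 or len(wb) < 2:
        out["p"] = float("nan")
        return out
    pooled = np.concatenate([wa, wb])
    if np.all(pooled == pooled[0]):
        out["p"] = 1.0  # all ranks tied under the mid-rank convention
        return out
    out["p"] = float(stats.mannwhitneyu(wa, wb, alternative="two-sided").pvalue)
    return out
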