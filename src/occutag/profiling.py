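"""Metagene profiles, expression stratification, and correlation measures."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .genome import GeneModel, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "stratify_expression",
    "metagene",
    "occupancy_expression_trend",
    "replicate_correlation",
]

STRATA_ORDER = ("high", "medium", "low", "silent")


def stratify_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into high/medium/low/silent/off expression strata.

    Off: mean TPM exactly 0. Silent: 0 < mean TPM < 1. The remaining
    (nonsilent, mean TPM >= 1) genes are split by quartile of mean TPM:
    high = top 25%, low = bottom 25%, medium = the middle half. Ties at the
    quartile boundary are broken by gene_id order, so the cut is
    deterministic.
    """
    df = expr.copy()
    if "mean_tpm" not in df.columns:
        rep_cols = [c for c in df.columns if c.startswith("tpm_")]
        df["mean_tpm"] = df[rep_cols].mean(axis=1)
    ns = df[df["mean_tpm"] >= 1.0]
    if len(ns) < 4:
        raise ValueError(f"need >= 4 nonsilent genes to form quartiles, got {len(ns)}")
    q = len(ns) // 4
    ranked = ns.sort_values(["mean_tpm", "gene_id"], ascending=[False, True])
    high = set(ranked["gene_id"].iloc[:q])
    low = set(ranked["gene_id"].iloc[len(ranked) - q :])

    def assign(row):
        if row.mean_tpm == 0:
            return "off"
        if row.mean_tpm < 1:
            return "silent"
        if row.gene_id in high:
            return "high"
        if row.gene_id in low:
            return "low"
        return "medium"

    df["stratum"] = [assign(r) for r in df.itertuples()]
    return df


def _gene_bin_edges(
    g: GeneModel, flank_bp: int, flank_bins: int, body_bins: int
) -> np.ndarray:
    """Genomic bin edges, 5' to 3' for a plus-strand gene (caller flips minus)."""
    up = np.linspace(g.start - flank_bp, g.start, flank_bins + 1)
    body = np.linspace(g.start, g.end, body_bins + 1)
    down = np.linspace(g.end, g.end + flank_bp, flank_bins + 1)
    return np.concatenate([up[:-1], body[:-1], down])


def metagene(
    track: CoverageTrack,
    ann: GenomeAnnotation,
    genes: list[GeneModel] | None = None,
    flank_bp: int = 2000,
    flank_bins: int = 40,
    body_bins: int = 100,
) -> pd.DataFrame:
    """Per-gene binned density matrix: fixed-bp flanks around a scaled body.

    Rows are genes, columns ``bin_0 .. bin_{2*flank_bins+body_bins-1}``,
    always oriented 5' to 3' (minus-strand genes are reversed). Values are
    mean signal per bp in each bin. Genes with a body shorter than
    ``body_bins`` bp are skipped with a logged count; flank bins falling
    outside the chromosome contribute their overlapping part only (density 0
    if fully outside).
    """
    if genes is None:
        genes = ann.genes
    rows, index = [], []
    n_skipped = 0
    for g in genes:
        if g.length < body_bins:
            n_skipped += 1
            continue
        size = ann.chrom_sizes[g.chrom]
        edges = _gene_bin_edges(g, flank_bp, flank_bins, body_bins)
        dens = np.zeros(len(edges) - 1)
        for i in range(len(dens)):
            lo, hi = edges[i], edges[i + 1]
            clo, chi = max(lo, 0.0), min(hi, float(size))
            if chi > clo:
                dens[i] = track.window_sum(g.chrom, clo, chi) / (hi - lo)
        if g.strand == "-":
            dens = dens[::-1]
        rows.append(dens)
        index.append(g.gene_id)
    if n_skipped:
        logger.info("metagene: skipped %d genes shorter than %d bp", n_skipped, body_bins)
    cols = [f"bin_{i}" for i in range(2 * flank_bins + body_bins)]
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=cols)


def occupancy_expression_trend(
    matrix: pd.DataFrame,
    strata: pd.DataFrame,
    flank_bins: int = 40,
    tss_bins: int = 5,
) -> dict:
    """Mean TSS-adjacent density per expression stratum and its rank ordering.

    TSS density for a gene is the mean of ``tss_bins`` bins centered on the
    flank/body boundary (robust to single-bin noise). Reports Spearman rho
    between the stratum rank (high > medium > low > silent) and the stratum
    mean; rho is NaN when fewer than two strata are populated.
    """
    half = tss_bins // 2
    cols = [f"bin_{i}" for i in range(flank_bins - half, flank_bins - half + tss_bins)]
    tss_density = matrix[cols].mean(axis=1)
    stratum_of = dict(zip(strata["gene_id"], strata["stratum"]))
    per_stratum: dict[str, float] = {}
    for s in STRATA_ORDER:
        members = [g for g in matrix.index if stratum_of.get(g) == s]
        per_stratum[s] = float(tss_density.loc[members].mean()) if members else float("nan")
    ranks, means = [], []
    for rank, s in enumerate(reversed(STRATA_ORDER), start=1):  # silent=1 .. high=4
        if not np.isnan(per_stratum[s]):
            ranks.append(rank)
            means.append(per_stratum[s])
    if len(ranks) < 2:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(ranks, means).statistic)
    return {"per_stratum_tss_density": per_stratum, "spearman_rho": rho}


def replicate_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    chrom_sizes: dict[str, int],
    bin_bp: int = 10_000,
) -> dict:
    """Pearson r of log2(1 + density) over genome-wide bins.

    The genome is tiled into ``bin_bp`` bins; bins with zero signal in both
    tracks are dropped. Raises if fewer than 3 informative bins remain.
    """
    va, vb = [], []
    for chrom, size in chrom_sizes.items():
        sa = track_a.bin_sums(chrom, size, bin_bp) / bin_bp
        sb = track_b.bin_sums(chrom, size, bin_bp) / bin_bp
        va.append(sa)
        vb.append(sb)
    da = np.concatenate(va)
    db = np.concatenate(vb)
    keep = (da > 0) | (db > 0)
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} informative bins; need >= 3")
    la = np.log2(1 + da[keep])
    lb = np.log2(1 + db[keep])
    if np.allclose(la, lb):
        r = 1.0  # a track against itself (or an identical copy)
    else:
        r = float(stats.pearsonr(la, lb).statistic)
    return {"r": r, "n_bins": int(keep.sum())}
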