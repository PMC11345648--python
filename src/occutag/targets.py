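"""Bound-gene detection and integration with differential expression.

A gene is *bound* by a factor if any peak overlaps the strand-aware window
from 2 kb upstream of its TSS to 0.3 kb downstream of its TES. A *direct
target* is a bound gene with a significant expression change upon the
factor's depletion (fold change >= 1.5 and FDR < 0.05 by default, both
directions symmetric on the log2 scale). Common targets of two factors are
the intersection of their direct-target sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAnnotation
from .intervals import IntervalIndex, clamp
from .peaks import PeakSet

logger = logging.getLogger(__name__)

__all__ = ["bound_genes", "de_classify", "call_direct_targets", "common_targets"]


def gene_target_window(g: GeneModel, chrom_size: int, up: int = 2000, down_tes: int = 300) -> tuple[int, int]:
    """Strand-aware [TSS - up, TES + down_tes), clamped at chromosome bounds."""
    if g.strand == "+":
        return clamp(g.start - up, g.end + down_tes, chrom_size)
    return clamp(g.start - down_tes, g.end + up, chrom_size)


def bound_genes(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    up: int = 2000,
    down_tes: int = 300,
) -> pd.Series:
    """Boolean per gene: any peak overlaps the gene's target window."""
    idx = {
        c: IntervalIndex([(p.start, p.end) for p in plist])
        for c, plist in peaks.by_chrom().items()
    }
    flags = {}
    for g in ann.genes:
        ws, we = gene_target_window(g, ann.chrom_sizes[g.chrom], up, down_tes)
        ix = idx.get(g.chrom)
        flags[g.gene_id] = bool(ix is not None and we > ws and ix.any_overlap(ws, we))
    return pd.Series(flags, name="bound")


def de_classify(de: pd.DataFrame, fc_min: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Assign DE status from log2FC and FDR.

    down iff log2fc <= -log2(fc_min) and fdr < alpha; up symmetric; else ns.
    A fold change of exactly ``fc_min`` is significant (threshold inclusive).
    """
    for col in ("log2fc", "fdr"):
        if col not in de.columns:
            raise ValueError(f"DE table missing required column {col!r}")
    out = de.copy()
    thr = np.log2(fc_min)
    sig = out["fdr"] < alpha
    out["status"] = np.where(
        sig & (out["log2fc"] <= -thr), "down",
        np.where(sig & (out["log2fc"] >= thr), "up", "ns"),
    )
    return out


def call_direct_targets(bound: pd.Series, de: pd.DataFrame) -> pd.DataFrame:
    """Direct target = bound AND significantly differentially expressed.

    If the gene universes disagree, the intersection is used with a logged
    count. Returns a per-gene table with bound, status and direct_target.
    """
    if "status" not in de.columns:
        raise ValueError("DE table must be classified first (missing 'status')")
    de_idx = de.set_index("gene_id")
    common = bound.index.intersection(de_idx.index)
    dropped = (len(bound) - len(common)) + (len(de_idx) - len(common))
    if dropped:
        logger.info("call_direct_targets: gene universes disagree; %d records dropped", dropped)
    out = pd.DataFrame(
        {
            "gene_id": common,
            "bound": bound.loc[common].to_numpy(),
            "status": de_idx.loc[common, "status"].to_numpy(),
        }
    )
    out["direct_target"] = out["bound"] & (out["status"] != "ns")
    return out


def target_counts(targets: pd.DataFrame) -> dict:
    direct = targets[targets["direct_target"]]
    return {
        "n_direct": int(len(direct)),
        "n_down": int((direct["status"] == "down").sum()),
        "n_up": int((direct["status"] == "up").sum()),
    }


def common_targets(targets_a: pd.DataFrame, targets_b: pd.DataFrame) -> dict:
    """Intersection of two direct-target sets with Venn counts.

    Venn conservation holds by construction: a_only + both = |A|,
    b_only + both = |B|.
    """
    set_a = set(targets_a.loc[targets_a["direct_target"], "gene_id"])
    set_b = set(targets_b.loc[targets_b["direct_target"], "gene_id"])
    both = set_a & set_b
    return {
        "common": sorted(both),
        "venn": {
            "a_only": len(set_a - set_b),
            "b_only": len(set_b - set_a),
            "both": len(both),
        },
        "n_a": len(set_a),
        "n_b": len(set_b),
    }
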