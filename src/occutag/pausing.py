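"""Promoter-proximal pausing index (PI) and three-class grouping.

PI (also called traveling ratio) is the ratio of promoter read density to
gene-body read density. Genes are grouped with the conventional thresholds:
highly paused (PI >= 3), moderately paused (1.5 <= PI < 3) and nonpaused
(PI < 1.5). Genes with zero body density get PI = NA rather than infinity
and are excluded from class counts, which avoids depth-dependent artifacts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .genome import GeneModel, GenomeAnnotation
from .intervals import strand_window

logger = logging.getLogger(__name__)

__all__ = [
    "PAUSE_CLASSES",
    "pause_class",
    "pausing_table",
    "classify_pausing",
    "groupwise_pi_compare",
]

PAUSE_CLASSES = ("highly", "moderately", "nonpaused")


def pause_class(pi: float) -> str:
    """Exact printed thresholds: >= 3 highly; [1.5, 3) moderately; < 1.5 nonpaused."""
    if not np.isfinite(pi):
        return "NA"
    if pi >= 3.0:
        return "highly"
    if pi >= 1.5:
        return "moderately"
    return "nonpaused"


def pausing_table(
    track: CoverageTrack,
    ann: GenomeAnnotation,
    genes: list[GeneModel] | None = None,
    promoter_window: tuple[int, int] = (50, 300),
    body_offset: int = 300,
) -> pd.DataFrame:
    """Per-gene promoter density, body density, PI and pause class.

    Promoter = strand-aware ``[TSS - up, TSS + down)``; body = from
    ``body_offset`` bp downstream of the TSS to the TES. Genes whose
    promoter window leaves the chromosome, or whose body is empty after the
    offset, are skipped with a logged count. PI is scale-invariant: both
    densities share the track's normalization.
    """
    if genes is None:
        genes = ann.genes
    up, down = promoter_window
    rows = []
    n_skipped = 0
    for g in genes:
        size = ann.chrom_sizes[g.chrom]
        ps, pe = strand_window(g.tss, g.strand, up, down)
        if ps < 0 or pe > size:
            n_skipped += 1
            continue
        if g.strand == "+":
            bs, be = g.tss + body_offset, g.end
        else:
            bs, be = g.start, g.tss + 1 - body_offset
        if be <= bs:
            n_skipped += 1
            continue
        pd_dens = track.window_density(g.chrom, ps, pe)
        bd_dens = track.window_density(g.chrom, bs, be)
        pi = pd_dens / bd_dens if bd_dens > 0 else float("nan")
        rows.append(
            {
                "gene_id": g.gene_id,
                "promoter_density": pd_dens,
                "body_density": bd_dens,
                "pi": pi,
                "pause_class": pause_class(pi),
            }
        )
    if n_skipped:
        logger.info("pausing_table: skipped %d genes (window outside chromosome or empty body)", n_skipped)
    return pd.DataFrame(rows)


def classify_pausing(records: pd.DataFrame) -> dict:
    """Class counts and gene lists; NA-PI genes are reported but not counted."""
    out: dict = {"counts": {}, "genes": {}}
    for cls in PAUSE_CLASSES:
        members = records.loc[records["pause_class"] == cls, "gene_id"].tolist()
        out["counts"][cls] = len(members)
        out["genes"][cls] = members
    out["counts"]["NA"] = int((records["pause_class"] == "NA").sum())
    return out


def groupwise_pi_compare(
    records_control: pd.DataFrame,
    records_kd: pd.DataFrame,
    decrease_margin: float = 0.0,
) -> pd.DataFrame:
    """Compare PI between conditions within control-defined pause classes.

    For each class: median delta PI (kd - control), the fraction of genes
    whose relative PI decrease ``(control - kd) / control`` exceeds
    ``decrease_margin``, and a two-sided Wilcoxon signed-rank p (NA for
    classes with < 3 informative genes or all-zero differences).
    """
    merged = records_control.merge(
        records_kd[["gene_id", "pi"]], on="gene_id", suffixes=("_control", "_kd")
    )
    merged = merged[np.isfinite(merged["pi_control"]) & np.isfinite(merged["pi_kd"])]
    rows = []
    for cls in PAUSE_CLASSES:
        sub = merged[merged["pause_class"] == cls]
        if len(sub) == 0:
            rows.append({"pause_class": cls, "n": 0, "median_delta_pi": float("nan"),
                         "frac_decreased": float("nan"), "p": float("nan")})
            continue
        delta = (sub["pi_kd"] - sub["pi_control"]).to_numpy()
        rel_dec = (sub["pi_control"] - sub["pi_kd"]).to_numpy() / sub["pi_control"].to_numpy()
        if len(sub) < 3 or np.all(delta == 0):
            p = float("nan")
        else:
            p = float(stats.wilcoxon(delta, alternative="two-sided").pvalue)
        rows.append(
            {
                "pause_class": cls,
                "n": len(sub),
                "median_delta_pi": float(np.median(delta)),
                "frac_decreased": float(np.mean(rel_dec > decrease_margin)),
                "p": p,
            }
        )
    return pd.DataFrame(rows)
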