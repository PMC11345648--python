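"""Windowed TSS/TES differential occupancy between conditions.

Densities are measured in strand-aware windows anchored at the TSS or TES,
per replicate, then compared between conditions. The default significance
test is a pooled two-sided rate-ratio (binomial) test on window signal
scaled to equal library size — robust at two replicates per condition; a
Welch t on log2(1 + density) across replicates is available. BH FDR is
applied within each table (one (factor, window) family per call).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack
from .genome import GeneModel, GenomeAnnotation
from .intervals import strand_window

logger = logging.getLogger(__name__)

__all__ = [
    "gene_window_density",
    "differential_occupancy",
    "fc_threshold_count",
    "occupancy_loss_set",
]


def gene_window_density(
    tracks: dict[str, list[CoverageTrack]],
    ann: GenomeAnnotation,
    genes: list[GeneModel] | None = None,
    anchor: str = "TSS",
    window: tuple[int, int] = (1000, 1000),
) -> pd.DataFrame:
    """Per-gene, per-replicate window signal for each condition.

    Returns a long table with the raw window sum, window width, the track's
    library size (total signal) and the library-normalized density in signal
    per bp per million. Genes whose window leaves the chromosome are skipped
    with a logged count.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if genes is None:
        genes = ann.genes
    up, down = window
    rows = []
    n_skipped = 0
    lib = {
        (cond, tr.replicate): tr.total_signal
        for cond, trs in tracks.items()
        for tr in trs
    }
    for g in genes:
        size = ann.chrom_sizes[g.chrom]
        pos = g.tss if anchor == "TSS" else g.tes
        ws, we = strand_window(pos, g.strand, up, down)
        if ws < 0 or we > size:
            n_skipped += 1
            continue
        for cond, trs in tracks.items():
            for tr in trs:
                raw = tr.window_sum(g.chrom, ws, we)
                total = lib[(cond, tr.replicate)]
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "anchor": anchor,
                        "condition": cond,
                        "replicate": tr.replicate,
                        "raw_sum": raw,
                        "width": we - ws,
                        "library_size": total,
                        "density_cpm": raw / (we - ws) / total * 1e6 if total > 0 else 0.0,
                    }
                )
    if n_skipped:
        logger.info("gene_window_density: skipped %d genes with windows outside chromosome", n_skipped)
    return pd.DataFrame(rows)


def _binomial_rate_test(ka: float, kb: float, la: float, lb: float) -> float:
    """Two-sided exact binomial test of equal rates given library sizes."""
    n = int(round(ka + kb))
    if n == 0:
        return 1.0
    p0 = la / (la + lb)
    return float(stats.binomtest(int(round(ka)), n, p0, alternative="two-sided").pvalue)


def _size_factor(raw_c: np.ndarray, raw_k: np.ndarray) -> float:
    """Composition-robust kd/control scaling: exp(median log per-gene ratio).

    Total-signal scaling is biased when a sizable gene set changes occupancy
    (every unchanged gene then appears shifted the other way); the median
    per-gene ratio over genes observed in both conditions estimates the
    depth ratio from the unchanged majority. The log-space median makes the
    factor exactly reciprocal under condition swap.
    """
    ok = (raw_c > 0) & (raw_k > 0)
    if not ok.any():
        return 1.0
    return float(np.exp(np.median(np.log(raw_k[ok] / raw_c[ok]))))


def differential_occupancy(
    densities: pd.DataFrame,
    condition_control: str = "control",
    condition_kd: str = "kd",
    alpha: float = 0.05,
    fc_min: float = 1.5,
    test: str = "binomial",
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Per-gene occupancy change table with direction calls.

    Cross-condition scaling uses median-of-ratios size factors by default
    (``normalization="library"`` trusts the tracks' total signal instead,
    which is biased when many genes change in one direction).
    ``test="binomial"``: pooled rate-ratio test on summed raw window signal
    against the effective library sizes (any replicate number).
    ``test="welch"``: Welch t on log2(1 + density) across replicates; needs
    >= 2 per condition, otherwise p is NA and only fold changes are reported
    (with a warning). Direction: decreased iff log2fc < 0, FDR < alpha and
    max(fc, 1/fc) >= fc_min; increased symmetrically; else unchanged.
    """
    if test not in ("binomial", "welch"):
        raise ValueError(f"unknown test {test!r}")
    if normalization not in ("median_ratio", "library"):
        raise ValueError(f"unknown normalization {normalization!r}")
    piv = densities.pivot_table(
        index="gene_id", columns=["condition", "replicate"],
        values=["raw_sum", "density_cpm"], aggfunc="first",
    )
    genes = piv.index
    widths = densities.groupby("gene_id")["width"].first().loc[genes]

    libs = (
        densities.groupby(["condition", "replicate"])["library_size"].first()
    )
    la_raw = float(libs[condition_control].sum())
    lb_raw = float(libs[condition_kd].sum())
    raw_c = piv["raw_sum"][condition_control].sum(axis=1)
    raw_k = piv["raw_sum"][condition_kd].sum(axis=1)

    if normalization == "median_ratio":
        s = _size_factor(raw_c.to_numpy(), raw_k.to_numpy())
        la, lb = la_raw, la_raw * s  # effective kd library on the control scale
    else:
        la, lb = la_raw, lb_raw
    dens_c = (raw_c / widths / la * 1e6).to_numpy()
    dens_k = (raw_k / widths / lb * 1e6).to_numpy()

    # fold change from pooled scaled signal with a half-count pseudocount,
    # so log2fc is finite and antisymmetric under condition swap
    rate_c = (raw_c + 0.5) / la
    rate_k = (raw_k + 0.5) / lb
    log2fc = np.log2(rate_k / rate_c)

    if test == "binomial":
        pvals = np.array(
            [_binomial_rate_test(raw_c[g], raw_k[g], la, lb) for g in genes]
        )
    else:
        n_c = piv["density_cpm"][condition_control].shape[1]
        n_k = piv["density_cpm"][condition_kd].shape[1]
        if n_c < 2 or n_k < 2:
            logger.warning("welch test needs >= 2 replicates per condition; "
                           "reporting fold changes only")
            pvals = np.full(len(genes), np.nan)
        else:
            # rescale kd replicate densities onto the effective size factors
            adj = (lb_raw / la_raw) * (la / lb)
            lc = np.log2(1 + piv["density_cpm"][condition_control].to_numpy())
            lk = np.log2(1 + piv["density_cpm"][condition_kd].to_numpy() * adj)
            res = stats.ttest_ind(lc, lk, axis=1, equal_var=False)
            pvals = np.asarray(res.pvalue)
            pvals[~np.isfinite(pvals)] = 1.0

    if np.all(np.isnan(pvals)):
        fdr = np.full(len(genes), np.nan)
    else:
        fdr = multipletests(pvals, method="fdr_bh")[1]

    fold_max = np.maximum(2.0 ** log2fc, 2.0 ** -log2fc)
    direction = np.where(
        (fdr < alpha) & (fold_max >= fc_min),
        np.where(log2fc < 0, "decreased", "increased"),
        "unchanged",
    )
    direction = np.where(np.isnan(fdr), "unchanged", direction)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "density_control": dens_c,
            "density_kd": dens_k,
            "log2fc": log2fc.to_numpy() if hasattr(log2fc, "to_numpy") else log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    ).reset_index(drop=True)


def fc_threshold_count(changes: pd.DataFrame, fc_min: float, direction: str = "decreased") -> int:
    """Count genes past a pure fold-change threshold, significance not required.

    ``direction="decreased"`` counts genes with control/kd density >= fc_min
    (a fold change of exactly fc_min is counted); ``"increased"`` is the
    mirror. Genes with zero density in both conditions are not counted.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    c = changes["density_control"].to_numpy(dtype=float)
    k = changes["density_kd"].to_numpy(dtype=float)
    both_zero = (c == 0) & (k == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = c / k if direction == "decreased" else k / c
    return int(np.sum(~both_zero & (ratio >= fc_min)))


def occupancy_loss_set(changes: pd.DataFrame, loss: float = 0.5) -> list[str]:
    """Genes whose occupancy reduction (control - kd) / control strictly exceeds ``loss``.

    The inequality is strict ("over 50%" excludes exactly 50%); genes with
    zero control density are excluded with a logged count.
    """
    c = changes["density_control"].to_numpy(dtype=float)
    k = changes["density_kd"].to_numpy(dtype=float)
    zero_control = c == 0
    if zero_control.any():
        logger.info("occupancy_loss_set: excluded %d genes with zero control density",
                    int(zero_control.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = (c - k) / c
    keep = ~zero_control & (reduction > loss)
    return changes.loc[keep, "gene_id"].tolist()
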