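"""Seeded synthetic-data generator with known ground truth.

Emulates the statistical structure of a factor-occupancy study: a toy
multi-gene genome with strand-aware TSS/TES, CpG islands enriched at
promoters, factor peaks with a designed genomic-feature mixture, replicate
coverage tracks for a control and a knockdown condition with designed
promoter/body densities (hence designed pausing indices and designed
per-gene occupancy reductions), and an expression/DE table whose TPM is
positively coupled to promoter occupancy.

Signal model
------------
Signal is drawn per 10 bp bin from a Poisson whose mean encodes the designed
densities. Each gene carries a flat promoter plateau over the strand-aware
window ``[TSS - plateau_up, TSS + plateau_down)`` at rate
``body_rate x designed_PI`` (so the designed pausing index is exactly the
expected promoter/body density ratio) and a uniform gene-body rate
elsewhere in the gene. The knockdown condition multiplies the promoter
plateau (or the whole gene, if ``kd_scope="gene"``) by the gene's designed
occupancy factor. All genomic placements are snapped to the 10 bp bin grid
so that designed densities are exactly the expectation of any bin-aligned
window density.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack, write_bedgraph
from .genome import GeneModel, GenomeAnnotation, write_chrom_sizes, write_gene_models_gtf, write_bed
from .intervals import strand_window, clamp
from .peaks import Peak, PeakSet, write_narrowpeak

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_tracks",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

FEATURES = ("promoter", "exon", "intron", "distal_intergenic")


@dataclass
class SimulationConfig:
    """All knobs of the generator; fixed seed implies byte-identical outputs."""

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (3000, 8000)
    gene_margin: int = 3000
    frac_tss_cgi: float = 0.7
    n_background_cgis: int = 100
    # peaks
    n_peaks: int = 2000
    peak_width_range: tuple[int, int] = (200, 500)
    peak_feature_mix: tuple[float, float, float, float] = (0.724, 0.050, 0.119, 0.107)
    # signal
    factor: str = "factorX"
    true_pi_per_group: dict[str, float] = field(
        default_factory=lambda: {"highly": 5.0, "moderately": 2.0, "nonpaused": 0.8}
    )
    pause_class_probs: dict[str, float] = field(
        default_factory=lambda: {"highly": 0.35, "moderately": 0.40, "nonpaused": 0.25}
    )
    promoter_rate: float = 0.6
    body_rate: float = 0.3
    plateau_window: tuple[int, int] = (50, 300)  # (upstream, downstream) of TSS, bp
    bin_bp: int = 10
    depth: float = 1.0
    n_replicates: int = 2
    silent_factor: float = 0.1
    # knockdown
    kd_effect: dict[str, dict] = field(
        default_factory=lambda: {"lost": {"n_genes": 40, "factor": 0.4}}
    )
    kd_scope: str = "gene"  # or "promoter" (plateau only, changes designed PI)
    # expression
    frac_silent: float = 0.15
    frac_off: float = 0.05
    expr_coupling: float = 1.0
    expr_scale: float = 10.0
    noise_sd: float = 0.2  # sd of natural-log multiplicative TPM noise
    expr_n_replicates: int = 3
    n_de_bound_down: int = 25
    n_de_bound_up: int = 15
    n_de_unbound_down: int = 0
    n_de_unbound_up: int = 0
    de_log2fc: float = 3.0
    # annotation geometry used when painting feature classes for peak placement
    annotation_promoter_window: tuple[int, int] = (2000, 500)

    def __post_init__(self) -> None:
        mix = np.asarray(self.peak_feature_mix, dtype=float)
        if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
            raise ValueError("peak_feature_mix must be 4 non-negative probabilities summing to 1")
        probs = np.asarray(list(self.pause_class_probs.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("pause_class_probs must sum to 1")
        if set(self.pause_class_probs) != set(self.true_pi_per_group):
            raise ValueError("pause_class_probs and true_pi_per_group must share keys")
        if self.promoter_rate < 0 or self.body_rate < 0 or self.depth <= 0:
            raise ValueError("rates must be >= 0 and depth > 0")
        for name, spec in self.kd_effect.items():
            if spec["factor"] <= 0:
                raise ValueError(f"kd_effect[{name!r}]: factor must be > 0")
        if self.chrom_length % self.bin_bp:
            raise ValueError("chrom_length must be a multiple of bin_bp")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("gene_length_range", "peak_width_range", "peak_feature_mix",
                    "plateau_window", "annotation_promoter_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Designed per-gene and per-peak quantities, sufficient to score every stage."""

    genes: pd.DataFrame
    peaks: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {"genes": self.genes.to_dict(orient="list")}
        if self.peaks is not None:
            payload["peaks"] = self.peaks.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"])
        peaks = pd.DataFrame(payload["peaks"]) if "peaks" in payload else None
        return cls(genes=genes, peaks=peaks)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: GroundTruth
    peaks: PeakSet
    tracks: dict[str, list[CoverageTrack]]  # condition -> replicate tracks
    expression: pd.DataFrame
    de: pd.DataFrame


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the root seed; stable across runs and call order."""
    child = np.random.SeedSequence(
        seed, spawn_key=(abs(hash_stream(stream)) % (2**31),)
    )
    return np.random.default_rng(child)


def hash_stream(name: str) -> int:
    # deterministic string hash (python's hash() is salted per process)
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def _snap(x: int, grid: int) -> int:
    return (x // grid) * grid


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Place non-overlapping genes on a uniform grid-snapped toy genome.

    CGIs are placed over ``frac_tss_cgi`` of TSSs and, later (after feature
    painting in :func:`simulate_tracks`), a background set in intergenic
    space is appended.
    """
    cfg = config
    rng = _rng(cfg.seed, "genome")
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}
    grid = cfg.bin_bp
    m = _snap(cfg.gene_margin, grid)

    counts = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        counts[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, k in zip(chrom_sizes, counts):
        if k == 0:
            continue
        lo, hi = cfg.gene_length_range
        lengths = rng.integers(lo // grid, hi // grid + 1, size=k) * grid
        needed = int(lengths.sum()) + (k + 1) * m
        if needed > cfg.chrom_length:
            raise ValueError(
                f"cannot place {k} genes with margins on {chrom}: "
                f"need {needed} bp > {cfg.chrom_length}; use a larger genome"
            )
        slack_units = (cfg.chrom_length - needed) // grid
        weights = rng.dirichlet(np.ones(k + 1))
        extras = np.floor(weights * slack_units).astype(int) * grid
        pos = m + int(extras[0])
        for j in range(k):
            length = int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + length
            exons = _make_exons(rng, start, end, grid)
            genes.append(GeneModel(f"g{gid:05d}", chrom, strand, start, end, exons))
            gid += 1
            pos = end + m + int(extras[j + 1])

    n = len(genes)
    classes = list(cfg.true_pi_per_group)
    probs = [cfg.pause_class_probs[c] for c in classes]
    pause_class = rng.choice(classes, size=n, p=probs) if n else np.array([], dtype=object)
    true_pi = np.array([cfg.true_pi_per_group[c] for c in pause_class]) if n else np.array([])

    perm = rng.permutation(n)
    n_off = int(round(cfg.frac_off * n))
    n_silent = int(round(cfg.frac_silent * n))
    off = np.zeros(n, dtype=bool)
    silent = np.zeros(n, dtype=bool)
    off[perm[:n_off]] = True
    silent[perm[n_off : n_off + n_silent]] = True

    # TSS-proximal CGIs over a designed fraction of genes
    cgis: list[tuple[str, int, int]] = []
    tss_in_cgi = np.zeros(n, dtype=bool)
    n_cgi = int(round(cfg.frac_tss_cgi * n))
    cgi_genes = rng.permutation(n)[:n_cgi]
    tss_in_cgi[cgi_genes] = True
    for i in sorted(cgi_genes):
        g = genes[i]
        length = int(rng.integers(40, 81)) * grid
        jitter = int(rng.integers(-10, 11)) * grid
        s = g.tss - length // 2 + jitter
        s, e = clamp(s, s + length, chrom_sizes[g.chrom])
        cgis.append((g.chrom, s, e))

    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "pause_class": pause_class,
            "true_pi": true_pi,
            "silent": silent,
            "off": off,
            "tss_in_cgi": tss_in_cgi,
        }
    )
    ann = GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes, cgis=sorted(cgis))
    return ann, GroundTruth(genes=truth_genes)


def _make_exons(rng: np.random.Generator, start: int, end: int, grid: int) -> list[tuple[int, int]]:
    k = int(rng.integers(2, 5))
    parts = 2 * k - 1
    base = 200
    remaining_units = (end - start - base * parts) // grid
    extra = rng.multinomial(remaining_units, np.ones(parts) / parts) * grid
    sizes = base + extra
    sizes[-1] += (end - start) - int(sizes.sum())  # absorb grid rounding
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(k)]


def _paint_features(ann: GenomeAnnotation, promoter_window: tuple[int, int]) -> dict[str, np.ndarray]:
    """Per-base class map: 0 distal, 1 intron, 2 exon, 3 promoter (priority ascending)."""
    up, down = promoter_window
    painted = {c: np.zeros(s, dtype=np.uint8) for c, s in ann.chrom_sizes.items()}
    for g in ann.genes:
        arr = painted[g.chrom]
        exon_cover = np.zeros(g.length, dtype=bool)
        for s, e in g.exons:
            exon_cover[s - g.start : e - g.start] = True
        body = arr[g.start : g.end]
        body[~exon_cover] = np.maximum(body[~exon_cover], 1)
        body[exon_cover] = np.maximum(body[exon_cover], 2)
    for g in ann.genes:
        s, e = clamp(*strand_window(g.tss, g.strand, up, down), ann.chrom_sizes[g.chrom])
        painted[g.chrom][s:e] = 3
    return painted


def _class_runs(painted: np.ndarray, cls: int) -> list[tuple[int, int]]:
    mask = painted == cls
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _allocate_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to categories (exact mixture)."""
    ideal = n * probs
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    short = n - counts.sum()
    for idx in np.argsort(-rem)[:short]:
        counts[idx] += 1
    return counts


def simulate_tracks(
    ann: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, list[CoverageTrack]], PeakSet]:
    """Per-bin Poisson coverage for control and knockdown, plus designed peaks.

    Mutates ``truth``: fills per-gene kd assignments, designed densities, and
    bound flags; fills the per-peak truth table; appends background CGIs to
    ``ann.cgis`` (placed in distal space, so never TSS-proximal).
    """
    cfg = config
    rng_kd = _rng(cfg.seed, "kd")
    rng_peaks = _rng(cfg.seed, "peaks")
    rng_sig = _rng(cfg.seed, "signal")
    genes = ann.genes
    n = len(genes)
    tg = truth.genes

    # knockdown assignment
    # knockdown reductions are assigned to nonsilent genes only: silent/off
    # genes carry near-floor designed occupancy, so a designed reduction
    # there would be meaningless (and undetectable at any realistic depth)
    kd_factor = np.ones(n)
    kd_set = np.array([""] * n, dtype=object)
    eligible = np.where(~(tg["silent"] | tg["off"]).to_numpy())[0]
    free = list(rng_kd.permutation(eligible))
    for name, spec in cfg.kd_effect.items():
        take = [i for i in free if kd_set[i] == ""][: spec["n_genes"]]
        if len(take) < spec["n_genes"]:
            raise ValueError(f"kd_effect[{name!r}]: not enough genes to assign")
        for i in take:
            kd_set[i] = name
            kd_factor[i] = spec["factor"]
    tg["kd_set"] = kd_set
    tg["kd_factor"] = kd_factor

    # designed densities (raw signal per bp, before Poisson sampling)
    s_factor = np.where(tg["silent"] | tg["off"], cfg.silent_factor, 1.0)
    tg["designed_body_density"] = cfg.body_rate * s_factor * cfg.depth
    tg["designed_promoter_density"] = tg["designed_body_density"] * tg["true_pi"]

    # feature painting and designed peaks
    painted = _paint_features(ann, cfg.annotation_promoter_window)
    mix = np.asarray(cfg.peak_feature_mix)
    counts = _allocate_counts(cfg.n_peaks, mix)
    paint_code = {"promoter": 3, "exon": 2, "intron": 1, "distal_intergenic": 0}
    chrom_runs = {
        cls: [
            (c, r)
            for c in ann.chrom_sizes
            for r in _class_runs(painted[c], paint_code[cls])
        ]
        for cls in FEATURES
    }
    wlo, whi = cfg.peak_width_range
    peak_rows = []
    for cls, n_cls in zip(FEATURES, counts):
        runs = chrom_runs[cls]
        if n_cls and not runs:
            raise ValueError(f"no genomic space available for {cls} peaks")
        lens = np.array([e - s for _, (s, e) in runs])
        for _ in range(n_cls):
            w = int(rng_peaks.integers(wlo, whi + 1))
            slack = lens - w + 1
            feas = slack > 0
            if not feas.any():
                raise ValueError(f"no {cls} region can host a {w} bp peak")
            p = np.where(feas, slack, 0).astype(float)
            ri = int(rng_peaks.choice(len(runs), p=p / p.sum()))
            chrom, (rs, re) = runs[ri]
            start = rs + int(rng_peaks.integers(0, re - rs - w + 1))
            peak_rows.append((chrom, start, start + w, cls))
    peak_rows.sort(key=lambda r: (r[0], r[1], r[2]))
    peaks = PeakSet(
        factor=cfg.factor,
        condition="control",
        peaks=[
            Peak(c, s, e, f"{cfg.factor}_peak_{i:05d}", 100.0, (s + e) // 2)
            for i, (c, s, e, _cls) in enumerate(peak_rows)
        ],
    )

    # background CGIs in (eroded) distal space
    rng_cgi = _rng(cfg.seed, "background_cgi")
    distal_runs = [
        (c, (s + cfg.bin_bp, e - cfg.bin_bp))
        for c in ann.chrom_sizes
        for s, e in _class_runs(painted[c], 0)
        if e - s > 2 * cfg.bin_bp + 600
    ]
    bg = []
    for _ in range(cfg.n_background_cgis):
        length = int(rng_cgi.integers(300, 601))
        lens = np.array([e - s for _, (s, e) in distal_runs])
        slack = np.maximum(lens - length + 1, 0).astype(float)
        ri = int(rng_cgi.choice(len(distal_runs), p=slack / slack.sum()))
        chrom, (rs, re) = distal_runs[ri]
        start = rs + int(rng_cgi.integers(0, re - rs - length + 1))
        bg.append((chrom, start, start + length))
    ann.cgis = sorted(ann.cgis + bg)

    # per-peak truth: designed feature + CGI flags
    proximal = _tss_proximal_cgis(ann, flank=500)
    cgi_flags, prox_flags = [], []
    for p in peaks:
        cgi_flags.append(any(c == p.chrom and p.start < e and s < p.end for c, s, e in ann.cgis))
        prox_flags.append(any(c == p.chrom and p.start < e and s < p.end for c, s, e in proximal))
    truth.peaks = pd.DataFrame(
        {
            "name": [p.name for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "feature": [cls for _c, _s, _e, cls in peak_rows],
            "cgi_overlap": cgi_flags,
            "tss_proximal_cgi_overlap": prox_flags,
        }
    )

    # per-gene bound flag: any peak in [TSS-2000, TES+300), strand-aware
    bound = np.zeros(n, dtype=bool)
    by_chrom: dict[str, list[Peak]] = peaks.by_chrom()
    for i, g in enumerate(genes):
        ws, we = _gene_bound_window(g, ann.chrom_sizes[g.chrom])
        bound[i] = any(p.start < we and ws < p.end for p in by_chrom.get(g.chrom, []))
    tg["bound"] = bound

    # mean rate arrays per bin, per condition
    bb = cfg.bin_bp
    up_p, down_p = cfg.plateau_window
    means = {
        cond: {c: np.zeros(size // bb) for c, size in ann.chrom_sizes.items()}
        for cond in ("control", "kd")
    }
    for i, g in enumerate(genes):
        rp = float(tg["designed_promoter_density"].iloc[i])
        rb = float(tg["designed_body_density"].iloc[i])
        ps, pe = clamp(*strand_window(g.tss, g.strand, up_p, down_p), ann.chrom_sizes[g.chrom])
        if g.strand == "+":
            bs, be = pe, g.end
        else:
            bs, be = g.start, ps
        for cond in ("control", "kd"):
            f = kd_factor[i] if cond == "kd" else 1.0
            fp = f
            fb = f if cfg.kd_scope == "gene" else 1.0
            arr = means[cond][g.chrom]
            arr[ps // bb : pe // bb] = rp * fp
            if be > bs:
                arr[bs // bb : be // bb] = rb * fb
    # distal peaks carry their own occupancy footprint
    for (chrom, s, e, cls) in peak_rows:
        if cls != "distal_intergenic":
            continue
        b0, b1 = s // bb, -(-e // bb)
        for cond in ("control", "kd"):
            means[cond][chrom][b0:b1] = cfg.promoter_rate * cfg.depth

    tracks: dict[str, list[CoverageTrack]] = {"control": [], "kd": []}
    for cond in ("control", "kd"):
        for rep in range(1, cfg.n_replicates + 1):
            tr = CoverageTrack(factor=cfg.factor, condition=cond, replicate=rep)
            for chrom in ann.chrom_sizes:
                lam = means[cond][chrom] * bb
                counts_bin = rng_sig.poisson(lam)
                nz = np.nonzero(counts_bin)[0]
                tr.add_chrom(chrom, nz * bb, nz * bb + bb, counts_bin[nz] / bb)
            tracks[cond].append(tr)

    low = tg.loc[(tg["designed_promoter_density"] * (up_p + down_p)) < 1, "gene_id"]
    if len(low):
        logger.warning(
            "depth too low to represent designed PI for %d genes: %s",
            len(low), ", ".join(low.head(10)),
        )
    return tracks, peaks


def _tss_proximal_cgis(ann: GenomeAnnotation, flank: int = 500) -> list[tuple[str, int, int]]:
    out = []
    for c, s, e in ann.cgis:
        for g in ann.genes:
            if g.chrom != c:
                continue
            ws, we = strand_window(g.tss, g.strand, flank, flank + 1)
            if s < we and ws < e:
                out.append((c, s, e))
                break
    return out


def _gene_bound_window(g: GeneModel, chrom_size: int, up: int = 2000, down_tes: int = 300) -> tuple[int, int]:
    if g.strand == "+":
        return clamp(g.start - up, g.end + down_tes, chrom_size)
    return clamp(g.start - down_tes, g.end + up, chrom_size)


def simulate_expression(
    ann: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM coupled to designed promoter occupancy, plus a knockdown DE table.

    ``log TPM = expr_coupling x log(designed promoter density) + N(0, noise_sd)``
    for nonsilent genes (scaled so nonsilent means stay >= 1); designed silent
    genes get 0 < TPM < 1; off genes get TPM 0. Designed DE genes receive an
    exact log2 fold-change offset in the knockdown condition; the DE table
    carries that exact log2FC, a pooled-variance t p-value computed on the simulated
    replicate TPMs, and BH FDR.
    """
    cfg = config
    rng = _rng(cfg.seed, "expression")
    tg = truth.genes
    n = len(tg)
    nonsilent = ~(tg["silent"] | tg["off"]).to_numpy()
    dens = tg["designed_promoter_density"].to_numpy(dtype=float)

    # designed DE status (among nonsilent genes, split bound/unbound)
    de_log2fc = np.zeros(n)
    de_status = np.array(["ns"] * n, dtype=object)
    bound = tg["bound"].to_numpy()
    for is_bound, n_down, n_up in (
        (True, cfg.n_de_bound_down, cfg.n_de_bound_up),
        (False, cfg.n_de_unbound_down, cfg.n_de_unbound_up),
    ):
        pool = np.where(nonsilent & (bound == is_bound))[0]
        pool = rng.permutation(pool)
        if len(pool) < n_down + n_up:
            logger.warning(
                "only %d %s nonsilent genes for %d designed DE genes",
                len(pool), "bound" if is_bound else "unbound", n_down + n_up,
            )
        take_down = pool[:n_down]
        take_up = pool[n_down : n_down + n_up]
        de_log2fc[take_down] = -cfg.de_log2fc
        de_log2fc[take_up] = cfg.de_log2fc
        de_status[take_down] = "down"
        de_status[take_up] = "up"
    tg["de_status"] = de_status
    tg["designed_log2fc"] = de_log2fc

    reps = cfg.expr_n_replicates
    tpm_a = np.zeros((n, reps))
    tpm_b = np.zeros((n, reps))
    ns_idx = np.where(nonsilent)[0]
    if len(ns_idx):
        d_ref = dens[ns_idx].min()
        base = cfg.expr_scale * (dens[ns_idx] / d_ref) ** cfg.expr_coupling
        tpm_a[ns_idx] = base[:, None] * np.exp(rng.normal(0, cfg.noise_sd, (len(ns_idx), reps)))
        base_b = base * 2.0 ** de_log2fc[ns_idx]
        tpm_b[ns_idx] = base_b[:, None] * np.exp(rng.normal(0, cfg.noise_sd, (len(ns_idx), reps)))
    sil_idx = np.where(tg["silent"].to_numpy())[0]
    if len(sil_idx):
        base_s = rng.uniform(0.1, 0.8, len(sil_idx))
        for mat in (tpm_a, tpm_b):
            mat[sil_idx] = np.clip(
                base_s[:, None] + rng.normal(0, 0.05, (len(sil_idx), reps)), 0.01, 0.99
            )
    # off genes stay exactly 0

    expr = pd.DataFrame({"gene_id": tg["gene_id"]})
    for r in range(reps):
        expr[f"tpm_rep{r + 1}"] = tpm_a[:, r]
    expr["mean_tpm"] = tpm_a.mean(axis=1)

    # Welch t on log2 TPM between conditions; off genes (all zero) -> p = 1
    with np.errstate(divide="ignore"):
        la = np.log2(np.where(tpm_a > 0, tpm_a, np.nan))
        lb = np.log2(np.where(tpm_b > 0, tpm_b, np.nan))
    pvals = np.ones(n)
    ok = nonsilent | tg["silent"].to_numpy()
    if ok.any():
        # pooled-variance t: replicate noise is homoskedastic by design, and
        # Welch's df collapses toward 2 at three replicates, capping power
        res = stats.ttest_ind(la[ok], lb[ok], axis=1, equal_var=True)
        p = np.asarray(res.pvalue)
        p[~np.isfinite(p)] = 1.0
        pvals[ok] = p
    fdr = multipletests(pvals, method="fdr_bh")[1]
    de = pd.DataFrame(
        {"gene_id": tg["gene_id"], "log2fc": de_log2fc, "p": pvals, "fdr": fdr}
    )
    return expr, de


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome -> tracks/peaks -> expression/DE."""
    ann, truth = simulate_genome(config)
    tracks, peaks = simulate_tracks(ann, truth, config)
    expr, de = simulate_expression(ann, truth, config)
    return SimulatedDataset(config, ann, truth, peaks, tracks, expr, de)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    write_chrom_sizes(ds.annotation.chrom_sizes, paths["chrom_sizes"])
    paths["genes"] = outdir / "genes.gtf"
    write_gene_models_gtf(ds.annotation.genes, paths["genes"])
    paths["cgis"] = outdir / "cgis.bed"
    write_bed(ds.annotation.cgis, paths["cgis"])
    paths["peaks"] = outdir / f"{ds.config.factor}_control_peaks.narrowPeak"
    write_narrowpeak(ds.peaks, paths["peaks"])
    for cond, tracks in ds.tracks.items():
        for tr in tracks:
            key = f"track_{cond}_rep{tr.replicate}"
            paths[key] = outdir / f"{ds.config.factor}_{cond}_rep{tr.replicate}.bedgraph"
            write_bedgraph(tr, paths[key])
    paths["expression"] = outdir / "expression.tsv"
    ds.expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6g")
    paths["de"] = outdir / "de.tsv"
    ds.de.to_csv(paths["de"], sep="\t", index=False, float_format="%.6g")
    paths["truth"] = outdir / "truth.json"
    ds.truth.to_json(paths["truth"])
    return paths
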