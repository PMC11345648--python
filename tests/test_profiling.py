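"""Expression strata, metagene geometry, and correlation measures."""

import numpy as np
import pandas as pd
import pytest

from occutag.genome import GeneModel, GenomeAnnotation
from occutag.profiling import (
    metagene,
    occupancy_expression_trend,
    replicate_correlation,
    stratify_expression,
)

from conftest import make_track


def _expr(tpms):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(tpms))],
                         "mean_tpm": tpms})


def test_strata_boundaries_and_quartiles():
    # 100 nonsilent genes (tpm 1..100), one silent, one off
    df = _expr(list(range(1, 101)) + [0.5, 0.0])
    out = stratify_expression(df)
    counts = out["stratum"].value_counts()
    assert counts["high"] == 25 and counts["low"] == 25 and counts["medium"] == 50
    assert counts["silent"] == 1 and counts["off"] == 1
    assert out.loc[out["mean_tpm"] == 0.5, "stratum"].iloc[0] == "silent"
    assert out.loc[out["mean_tpm"] == 0.0, "stratum"].iloc[0] == "off"
    assert out.loc[out["mean_tpm"] == 100, "stratum"].iloc[0] == "high"
    # partition: every gene in exactly one stratum
    assert out["stratum"].notna().all() and len(out) == len(df)


def test_strata_tpm_exactly_one_is_nonsilent():
    df = _expr([1.0, 2.0, 3.0, 4.0])
    out = stratify_expression(df)
    assert set(out["stratum"]) <= {"high", "medium", "low"}


def test_strata_needs_four_nonsilent():
    with pytest.raises(ValueError):
        stratify_expression(_expr([1.0, 2.0, 3.0, 0.1]))


def test_strata_ties_broken_deterministically():
    df = _expr([5.0] * 8)
    out1 = stratify_expression(df)
    out2 = stratify_expression(df.sample(frac=1, random_state=0).reset_index(drop=True))
    merged = out1.merge(out2, on="gene_id", suffixes=("_a", "_b"))
    assert (merged["stratum_a"] == merged["stratum_b"]).all()


def _one_gene_ann(strand="+", start=10000, end=14000, chrom_len=50000):
    g = GeneModel("g", "chr1", strand, start, end, [(start, end)])
    return GenomeAnnotation(chrom_sizes={"chr1": chrom_len}, genes=[g]), g


def test_metagene_uniform_track_fills_every_cell():
    ann, _ = _one_gene_ann()
    tr = make_track({"chr1": [(0, 50000, 3.0)]})
    mg = metagene(tr, ann, flank_bp=1000, flank_bins=10, body_bins=20)
    assert mg.shape == (1, 40)
    assert np.allclose(mg.to_numpy(), 3.0)


def test_metagene_minus_strand_mirror_equals_plus():
    # plus gene with signal plateau at its 5' end, minus gene with the
    # mirror-image plateau: metagene rows must be identical
    ann_p, gp = _one_gene_ann("+", 10000, 14000)
    ann_m, gm = _one_gene_ann("-", 10000, 14000)
    tr_p = make_track({"chr1": [(10000, 11000, 5.0), (11000, 14000, 1.0)]})
    tr_m = make_track({"chr1": [(10000, 13000, 1.0), (13000, 14000, 5.0)]})
    row_p = metagene(tr_p, ann_p, flank_bp=1000, flank_bins=10, body_bins=20)
    row_m = metagene(tr_m, ann_m, flank_bp=1000, flank_bins=10, body_bins=20)
    assert np.allclose(row_p.to_numpy(), row_m.to_numpy())


def test_metagene_translation_invariance():
    ann_a, _ = _one_gene_ann("+", 10000, 14000)
    ann_b, _ = _one_gene_ann("+", 20000, 24000)
    segs_a = [(9000, 10500, 2.0), (10500, 14000, 0.5)]
    segs_b = [(s + 10000, e + 10000, v) for s, e, v in segs_a]
    mg_a = metagene(make_track({"chr1": segs_a}), ann_a, flank_bp=1000, flank_bins=10, body_bins=20)
    mg_b = metagene(make_track({"chr1": segs_b}), ann_b, flank_bp=1000, flank_bins=10, body_bins=20)
    assert np.allclose(mg_a.to_numpy(), mg_b.to_numpy())


def test_metagene_body_mean_preserves_window_density():
    ann, g = _one_gene_ann()
    rng = np.random.default_rng(3)
    segs = [(10000 + i * 100, 10000 + (i + 1) * 100, float(v))
            for i, v in enumerate(rng.integers(0, 6, 40)) if v > 0]
    tr = make_track({"chr1": segs})
    mg = metagene(tr, ann, flank_bp=1000, flank_bins=10, body_bins=40)
    body = mg.iloc[0, 10:50].to_numpy()
    assert body.mean() == pytest.approx(tr.window_density("chr1", 10000, 14000), rel=1e-9)


def test_metagene_skips_too_short_genes():
    genes = [GeneModel("tiny", "chr1", "+", 100, 150)]
    ann = GenomeAnnotation(chrom_sizes={"chr1": 50000}, genes=genes)
    tr = make_track({"chr1": [(0, 50000, 1.0)]})
    mg = metagene(tr, ann, flank_bp=100, flank_bins=2, body_bins=200)
    assert len(mg) == 0


def test_trend_rho_is_one_under_designed_coupling(default_dataset):
    ds = default_dataset
    tr = ds.tracks["control"][0].normalize()
    strata = stratify_expression(ds.expression)
    mg = metagene(tr, ds.annotation)
    trend = occupancy_expression_trend(mg, strata)
    assert trend["spearman_rho"] == 1.0
    per = trend["per_stratum_tss_density"]
    assert per["high"] > per["medium"] > per["low"] > per["silent"]


def test_trend_single_stratum_is_nan():
    mg = pd.DataFrame(np.ones((3, 100)),
                      index=pd.Index([f"g{i}" for i in range(3)], name="gene_id"),
                      columns=[f"bin_{i}" for i in range(100)])
    strata = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "stratum": ["high"] * 3})
    trend = occupancy_expression_trend(mg, strata, flank_bins=20)
    assert np.isnan(trend["spearman_rho"])


def test_replicate_correlation_self_is_one(default_dataset):
    tr = default_dataset.tracks["control"][0].normalize()
    res = replicate_correlation(tr, tr, default_dataset.annotation.chrom_sizes)
    assert res["r"] == 1.0


def test_replicate_correlation_same_rates_high(default_dataset):
    a, b = [t.normalize() for t in default_dataset.tracks["control"][:2]]
    res = replicate_correlation(a, b, default_dataset.annotation.chrom_sizes)
    assert res["r"] >= 0.9


def test_replicate_correlation_independent_tracks_near_zero():
    rng = np.random.default_rng(8)
    sizes = {"chr1": 10_000_000}
    bins = np.arange(0, 10_000_000, 10_000)

    def random_track(rng):
        vals = rng.uniform(0.1, 5.0, len(bins))
        return make_track({"chr1": [(int(s), int(s) + 10_000, float(v))
                                    for s, v in zip(bins, vals)]})

    res = replicate_correlation(random_track(rng), random_track(rng), sizes)
    assert res["n_bins"] >= 1000
    assert abs(res["r"]) < 0.1


def test_replicate_correlation_needs_informative_bins():
    sizes = {"chr1": 30_000}
    a = make_track({"chr1": [(0, 100, 1.0)]})
    with pytest.raises(ValueError):
        replicate_correlation(a, a, sizes, bin_bp=30_000)
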