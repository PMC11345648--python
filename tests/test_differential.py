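"""Differential occupancy: calibration, boundaries, antisymmetry."""

import numpy as np
import pandas as pd
import pytest

from occutag.differential import (
    differential_occupancy,
    fc_threshold_count,
    gene_window_density,
    occupancy_loss_set,
)
from occutag.simulate import SimulationConfig, simulate_dataset

from conftest import make_track


@pytest.fixture(scope="module")
def kd_dataset():
    cfg = SimulationConfig(
        seed=21, n_chrom=2, chrom_length=1_200_000, n_genes=150, n_peaks=200,
        n_background_cgis=20, n_de_bound_down=0, n_de_bound_up=0,
        kd_effect={"lost": {"n_genes": 30, "factor": 0.4}},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def kd_changes(kd_dataset):
    dens = gene_window_density(kd_dataset.tracks, kd_dataset.annotation, anchor="TSS")
    return dens, differential_occupancy(dens)


def test_uniform_track_density_everywhere():
    from occutag.genome import GeneModel, GenomeAnnotation
    genes = [GeneModel("a", "chr1", "+", 10000, 16000),
             GeneModel("b", "chr1", "-", 30000, 37000)]
    ann = GenomeAnnotation(chrom_sizes={"chr1": 50000}, genes=genes)
    tr = make_track({"chr1": [(0, 50000, 2.0)]}, condition="control", replicate=1)
    for anchor in ("TSS", "TES"):
        dens = gene_window_density({"control": [tr]}, ann, anchor=anchor)
        assert np.allclose(dens["raw_sum"] / dens["width"], 2.0)


def test_identical_conditions_yield_no_calls(kd_dataset):
    tracks = {"control": kd_dataset.tracks["control"],
              "kd": kd_dataset.tracks["control"]}
    dens = gene_window_density(tracks, kd_dataset.annotation)
    ch = differential_occupancy(dens)
    assert (ch["direction"] == "unchanged").all()
    assert (ch["p"] == 1.0).all()  # identical pooled counts, p0 = 1/2


def test_sensitivity_and_direction_on_designed_reduction(kd_dataset, kd_changes):
    tg = kd_dataset.truth.genes.set_index("gene_id")
    _, ch = kd_changes
    ch = ch.set_index("gene_id")
    kd_genes = tg.index[tg["kd_factor"] < 1]
    sens = (ch.loc[kd_genes, "direction"] == "decreased").mean()
    assert sens >= 0.9
    null_genes = tg.index[tg["kd_factor"] == 1]
    assert (ch.loc[null_genes, "direction"] == "decreased").sum() <= 2


def test_direction_labels_consistent_with_thresholds(kd_changes):
    _, ch = kd_changes
    dec = ch[ch["direction"] == "decreased"]
    assert (dec["log2fc"] < 0).all()
    assert (dec["fdr"] < 0.05).all()
    assert (np.maximum(2 ** dec["log2fc"], 2 ** -dec["log2fc"]) >= 1.5).all()


def test_antisymmetry_under_condition_swap(kd_changes):
    dens, ch = kd_changes
    swapped = dens.copy()
    swapped["condition"] = swapped["condition"].map({"control": "kd", "kd": "control"})
    ch_sw = differential_occupancy(swapped)
    m = ch.merge(ch_sw, on="gene_id", suffixes=("", "_sw"))
    assert np.allclose(m["log2fc"], -m["log2fc_sw"])
    assert np.allclose(m["p"], m["p_sw"], rtol=1e-9)
    flip = {"decreased": "increased", "increased": "decreased", "unchanged": "unchanged"}
    assert (m["direction"].map(flip) == m["direction_sw"]).all()


def test_fdr_monotone_in_alpha(kd_changes):
    dens, _ = kd_changes
    sets = []
    for alpha in (0.1, 0.05, 0.01):
        ch = differential_occupancy(dens, alpha=alpha)
        sets.append(set(ch.loc[ch["direction"] != "unchanged", "gene_id"]))
    assert sets[2] <= sets[1] <= sets[0]


def test_pooled_test_invariant_to_common_library_scaling(kd_changes):
    dens, ch = kd_changes
    scaled = dens.copy()
    scaled["library_size"] *= 17.0
    ch2 = differential_occupancy(scaled)
    assert np.allclose(ch["p"], ch2["p"])


def test_null_type_one_error_calibrated():
    cfg = SimulationConfig(
        seed=22, n_chrom=2, chrom_length=1_500_000, n_genes=200, n_peaks=100,
        n_background_cgis=10, n_de_bound_down=0, n_de_bound_up=0, kd_effect={},
    )
    ds = simulate_dataset(cfg)
    dens = gene_window_density(ds.tracks, ds.annotation)
    ch = differential_occupancy(dens)
    assert ch["p"].mean() > 0.3  # roughly uniform, allowing discreteness
    assert (ch["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.035)


def test_welch_mode_and_single_replicate_warning(kd_dataset, caplog):
    dens = gene_window_density(kd_dataset.tracks, kd_dataset.annotation)
    ch = differential_occupancy(dens, test="welch")
    tg = kd_dataset.truth.genes.set_index("gene_id")
    kd_genes = tg.index[tg["kd_factor"] < 1]
    # welch at n=2 is far weaker than the pooled test but fold changes agree
    assert (ch.set_index("gene_id").loc[kd_genes, "log2fc"] < 0).all()

    single = dens[dens["replicate"] == 1]
    with caplog.at_level("WARNING"):
        ch1 = differential_occupancy(single, test="welch")
    assert ch1["p"].isna().all()
    assert (ch1["direction"] == "unchanged").all()


def test_fc_threshold_boundary_inclusive():
    ch = pd.DataFrame({
        "gene_id": ["a", "b", "c", "d"],
        "density_control": [1.1, 1.0, 2.0, 0.0],
        "density_kd": [1.0, 1.0, 1.0, 0.0],
    })
    assert fc_threshold_count(ch, fc_min=1.1) == 2  # exactly 1.1 counts; 2.0 counts
    assert fc_threshold_count(ch.assign(density_control=[1.0] * 4,
                                        density_kd=[1.0] * 4), 1.1) == 0
    with pytest.raises(ValueError):
        fc_threshold_count(ch, fc_min=0.9)


def test_fc_threshold_count_recovers_designed_set(kd_dataset, kd_changes):
    _, ch = kd_changes
    tg = kd_dataset.truth.genes
    n_designed = int((tg["kd_factor"] < 1).sum())
    # 0.4x reduction is fold 2.5 >> 1.4; all designed genes must be counted
    assert fc_threshold_count(ch, fc_min=1.4) >= n_designed


def test_occupancy_loss_strict_boundary_and_edge_cases(caplog):
    ch = pd.DataFrame({
        "gene_id": ["exact_half", "full_loss", "zero_control", "small_loss"],
        "density_control": [2.0, 3.0, 0.0, 2.0],
        "density_kd": [1.0, 0.0, 1.0, 1.5],
    })
    with caplog.at_level("INFO"):
        out = occupancy_loss_set(ch, loss=0.5)
    assert out == ["full_loss"]  # exactly 50% is excluded; zero control excluded
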