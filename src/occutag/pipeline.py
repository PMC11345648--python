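"""End-to-end demo pipeline: simulate -> annotate -> profile -> pausing ->
differential -> targets, with a scorecard against the generator's ground truth.

Every stage writes plain-text artifacts into the output directory; given the
same seed the whole directory is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_mod
from . import differential as diff_mod
from . import pausing as pause_mod
from . import profiling as prof_mod
from . import targets as tgt_mod
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_FLOAT_FMT = "%.6g"


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every stage on a simulated dataset and score results against truth.

    Returns the scorecard dict (also written as ``scorecard.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    ds = simulate_dataset(config)
    write_dataset(ds, outdir)
    ann = ds.annotation
    tg = ds.truth.genes.set_index("gene_id")

    # --- annotation ---------------------------------------------------------
    annotated = ann_mod.annotate_features(ds.peaks, ann,
                                          promoter_window=config.annotation_promoter_window)
    annotated = ann_mod.classify_cgi(annotated, ann)
    annotated.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    fsum = ann_mod.feature_summary(annotated)
    fsum.to_csv(outdir / "feature_summary.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    csum = ann_mod.cgi_summary(annotated)
    csum.to_csv(outdir / "cgi_summary.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)

    # --- profiling ----------------------------------------------------------
    norm_control = [t.normalize() for t in ds.tracks["control"]]
    strata = prof_mod.stratify_expression(ds.expression)
    strata.to_csv(outdir / "expression_strata.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    mg = prof_mod.metagene(norm_control[0], ann)
    mg.to_csv(outdir / "metagene_control_rep1.tsv", sep="\t", float_format=_FLOAT_FMT)
    with open(outdir / "metagene_control_rep1.json", "w") as fh:
        json.dump({"flank_bp": 2000, "flank_bins": 40, "body_bins": 100}, fh, sort_keys=True)
    trend = prof_mod.occupancy_expression_trend(mg, strata)
    if len(norm_control) >= 2:
        repcor = prof_mod.replicate_correlation(norm_control[0], norm_control[1],
                                                ann.chrom_sizes)
    else:
        repcor = {"r": float("nan"), "n_bins": 0}

    # --- pausing ------------------------------------------------------------
    norm_kd = [t.normalize() for t in ds.tracks["kd"]]
    mean_tpm = dict(zip(strata["gene_id"], strata["mean_tpm"]))
    expressed = [g for g in ann.genes if mean_tpm[g.gene_id] >= 1.0]
    pi_control = pause_mod.pausing_table(norm_control[0], ann, expressed)
    pi_kd = pause_mod.pausing_table(norm_kd[0], ann, expressed)
    pi_control.to_csv(outdir / "pausing_control.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    pi_kd.to_csv(outdir / "pausing_kd.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    pi_compare = pause_mod.groupwise_pi_compare(pi_control, pi_kd)
    pi_compare.to_csv(outdir / "pausing_groupwise_compare.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    # --- differential occupancy --------------------------------------------
    changes = {}
    for anchor in ("TSS", "TES"):
        dens = diff_mod.gene_window_density(ds.tracks, ann, anchor=anchor)
        ch = diff_mod.differential_occupancy(dens)
        ch.to_csv(outdir / f"differential_{anchor.lower()}.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
        changes[anchor] = ch
    loss = diff_mod.occupancy_loss_set(changes["TSS"], loss=0.5)
    with open(outdir / "occupancy_loss_genes.txt", "w") as fh:
        fh.write("\n".join(loss) + ("\n" if loss else ""))
    n_fc11 = diff_mod.fc_threshold_count(changes["TSS"], fc_min=1.1)

    # --- targets ------------------------------------------------------------
    de = tgt_mod.de_classify(ds.de)
    bound = tgt_mod.bound_genes(ds.peaks, ann)
    targets = tgt_mod.call_direct_targets(bound, de)
    targets.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    tcounts = tgt_mod.target_counts(targets)

    # --- scorecard against ground truth -------------------------------------
    truth_peaks = ds.truth.peaks.set_index("name")
    merged_peaks = annotated.set_index("name").join(truth_peaks, rsuffix="_truth")
    feature_acc = float((merged_peaks["feature"] == merged_peaks["feature_truth"]).mean())
    cgi_acc = float((merged_peaks["cgi_overlap"] == merged_peaks["cgi_overlap_truth"]).mean())
    prox_acc = float(
        (merged_peaks["tss_proximal_cgi_overlap"]
         == merged_peaks["tss_proximal_cgi_overlap_truth"]).mean()
    )
    subset_ok = bool(
        (~annotated["tss_proximal_cgi_overlap"] | annotated["cgi_overlap"]).all()
    )
    mix = dict(zip(ann_mod.FEATURE_PRIORITY, config.peak_feature_mix))
    mix_err = float(max(
        abs(row.percent / 100.0 - mix[row.feature]) for row in fsum.itertuples()
    ))

    pic = pi_control.set_index("gene_id")
    pic = pic[pic["pause_class"] != "NA"]
    truth_cls = tg.loc[pic.index, "pause_class"]
    pi_class_recovery = float((pic["pause_class"] == truth_cls).mean())
    rel_err = np.abs(pic["pi"] - tg.loc[pic.index, "true_pi"]) / tg.loc[pic.index, "true_pi"]
    pi_median_rel_error = float(np.median(rel_err))

    kd_genes = set(tg.index[tg["kd_factor"] < 1.0])
    ch_tss = changes["TSS"].set_index("gene_id")
    called_dec = set(ch_tss.index[ch_tss["direction"] == "decreased"])
    sensitivity = (
        len(called_dec & kd_genes) / len(kd_genes) if kd_genes else float("nan")
    )
    false_dec = len(called_dec - kd_genes)

    loss_truth = {
        g for g in kd_genes
        if (1.0 - tg.loc[g, "kd_factor"]) > 0.5
    }
    loss_set = set(loss)
    direct_truth = set(tg.index[tg["bound"] & (tg["de_status"] != "ns")])
    direct_called = set(targets.loc[targets["direct_target"], "gene_id"])

    scorecard = {
        "seed": config.seed,
        "n_genes": len(ann.genes),
        "n_peaks": len(ds.peaks),
        "feature_percentages": {r.feature: r.percent for r in fsum.itertuples()},
        "feature_mix_max_abs_error": mix_err,
        "feature_label_accuracy": feature_acc,
        "cgi_flag_accuracy": cgi_acc,
        "tss_proximal_flag_accuracy": prox_acc,
        "tss_proximal_subset_of_cgi": subset_ok,
        "pct_peaks_cgi": float(csum.loc[csum["group"] == "cgi", "percent"].iloc[0]),
        "pct_peaks_tss_proximal_cgi": float(
            csum.loc[csum["group"] == "tss_proximal_cgi", "percent"].iloc[0]
        ),
        "occupancy_expression_spearman_rho": trend["spearman_rho"],
        "stratum_tss_density": trend["per_stratum_tss_density"],
        "replicate_correlation_r": repcor["r"],
        "replicate_correlation_n_bins": repcor["n_bins"],
        "pi_class_recovery": pi_class_recovery,
        "pi_median_rel_error": pi_median_rel_error,
        "differential_sensitivity": sensitivity,
        "differential_false_decreased": false_dec,
        "n_decreased_tss": int((changes["TSS"]["direction"] == "decreased").sum()),
        "n_increased_tss": int((changes["TSS"]["direction"] == "increased").sum()),
        "n_decreased_tes": int((changes["TES"]["direction"] == "decreased").sum()),
        "n_increased_tes": int((changes["TES"]["direction"] == "increased").sum()),
        "n_fc_ge_1.1_decreased": n_fc11,
        "loss_set_size": len(loss_set),
        "loss_set_jaccard_vs_design": (
            len(loss_set & loss_truth) / len(loss_set | loss_truth)
            if loss_set | loss_truth else float("nan")
        ),
        "n_direct_targets": tcounts["n_direct"],
        "n_direct_down": tcounts["n_down"],
        "n_direct_up": tcounts["n_up"],
        "direct_targets_match_design": bool(direct_called == direct_truth),
    }
    scorecard = _round_floats(scorecard)
    with open(outdir / "scorecard.json", "w") as fh:
        json.dump(scorecard, fh, sort_keys=True, indent=1)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir)
    return scorecard
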