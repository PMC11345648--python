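"""Feature/CGI peak classification, co-occupancy, width statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from occutag.annotation import (
    FEATURE_PRIORITY,
    annotate_features,
    cgi_summary,
    classify_cgi,
    co_occupancy,
    feature_summary,
    width_stats,
)
from occutag.genome import GenomeAnnotation
from occutag.peaks import Peak, PeakSet

from conftest import random_oracle_genome
import oracles


def _peakset(intervals, chrom="chr1"):
    return PeakSet(peaks=[Peak(chrom, s, e, f"p{i}") for i, (s, e) in enumerate(intervals)])


def test_priority_promoter_beats_exon(toy_annotation):
    # spans gminus's promoter window AND gplus's 3' exon? build a peak over
    # gplus exon2 and gminus promoter: gminus promoter (+2000/-500 strandaware)
    # covers [35500, 38000); gplus exon2 is [14000,16000). Use a peak over both
    # features' territory via two separate checks instead.
    peaks = _peakset([(35400, 35700)])  # gminus exon2 AND gminus promoter region
    df = annotate_features(peaks, toy_annotation)
    assert df["feature"].iloc[0] == "promoter"


def test_wholly_intergenic_is_distal(toy_annotation):
    df = annotate_features(_peakset([(44000, 44500)]), toy_annotation)
    assert df["feature"].iloc[0] == "distal_intergenic"


def test_intron_and_exon_labels(toy_annotation):
    df = annotate_features(_peakset([(12500, 13500), (15000, 15400)]), toy_annotation)
    assert list(df["feature"]) == ["intron", "exon"]


def test_empty_peak_set_warns(toy_annotation, caplog):
    with caplog.at_level("WARNING"):
        df = annotate_features(PeakSet(), toy_annotation)
    assert len(df) == 0


def test_feature_percentages_sum_to_100(default_dataset):
    df = annotate_features(default_dataset.peaks, default_dataset.annotation)
    summary = feature_summary(df)
    assert summary["percent"].sum() == pytest.approx(100.0, abs=0.1)


def test_annotation_matches_priority_painting_oracle():
    rng = np.random.default_rng(123)
    for _ in range(5):
        chrom_len, genes, peak_ivs = random_oracle_genome(rng)
        ann = GenomeAnnotation(chrom_sizes={"chr1": chrom_len}, genes=genes)
        paint = oracles.bf_paint(genes, chrom_len, (2000, 500))
        df = annotate_features(_peakset(peak_ivs), ann)
        expected = [oracles.bf_annotate(iv, paint) for iv in sorted(peak_ivs)]
        assert list(df["feature"]) == expected


def test_designed_mix_recovered_on_synthetic_peaks(default_dataset):
    df = annotate_features(default_dataset.peaks, default_dataset.annotation)
    summary = feature_summary(df).set_index("feature")
    for cls, p in zip(FEATURE_PRIORITY, default_dataset.config.peak_feature_mix):
        assert summary.loc[cls, "percent"] / 100.0 == pytest.approx(p, abs=0.02)


def test_cgi_flags_on_toy_genome(toy_annotation):
    peaks = _peakset([(9900, 10200), (44100, 44300), (20000, 20200)])
    df = classify_cgi(peaks, toy_annotation)
    flags = df.set_index("name")
    assert flags.loc["p0", "cgi_overlap"] and flags.loc["p0", "tss_proximal_cgi_overlap"]
    assert flags.loc["p1", "cgi_overlap"] and not flags.loc["p1", "tss_proximal_cgi_overlap"]
    assert not flags.loc["p2", "cgi_overlap"]


def test_tss_flank_zero_requires_cgi_on_tss_base(toy_annotation):
    # gplus TSS=10000 is inside its CGI [9800,10400) -> still proximal at flank 0
    peaks = _peakset([(9900, 10200)])
    df = classify_cgi(peaks, toy_annotation, tss_flank=0)
    assert df["tss_proximal_cgi_overlap"].iloc[0]
    # shift the CGI so it misses the TSS base but stays within 500 bp
    ann2 = GenomeAnnotation(
        chrom_sizes=toy_annotation.chrom_sizes,
        genes=toy_annotation.genes,
        cgis=[("chr1", 10100, 10400)],
    )
    df2 = classify_cgi(peaks, ann2, tss_flank=0)
    assert not df2["tss_proximal_cgi_overlap"].iloc[0]
    df3 = classify_cgi(peaks, ann2, tss_flank=500)
    assert df3["tss_proximal_cgi_overlap"].iloc[0]


def test_tss_proximal_implies_cgi_for_every_peak(default_dataset):
    df = classify_cgi(default_dataset.peaks, default_dataset.annotation)
    assert (~df["tss_proximal_cgi_overlap"] | df["cgi_overlap"]).all()
    summary = cgi_summary(df)
    assert summary.loc[summary["group"] == "tss_proximal_cgi", "count"].iloc[0] <= \
        summary.loc[summary["group"] == "cgi", "count"].iloc[0]


def test_cgi_flags_match_designed_truth(default_dataset):
    df = classify_cgi(default_dataset.peaks, default_dataset.annotation).set_index("name")
    truth = default_dataset.truth.peaks.set_index("name")
    assert (df["cgi_overlap"] == truth["cgi_overlap"]).all()
    assert (df["tss_proximal_cgi_overlap"] == truth["tss_proximal_cgi_overlap"]).all()


def test_co_occupancy_identity_disjoint_and_constructed():
    a = _peakset([(i * 1000, i * 1000 + 300) for i in range(10)])
    res = co_occupancy(a, a)
    assert res["fracA"] == res["fracB"] == 1.0
    b = _peakset([(i * 1000 + 500, i * 1000 + 700) for i in range(10)])
    res = co_occupancy(a, b)
    assert res["countA_overlapping_B"] == 0 and res["countB_overlapping_A"] == 0

    rng = np.random.default_rng(9)
    a_ivs = [(i * 2000, i * 2000 + 400) for i in range(1000)]
    overlap_idx = rng.choice(1000, size=600, replace=False)
    b_ivs = [(a_ivs[i][0] + 200, a_ivs[i][0] + 600) for i in overlap_idx]
    res = co_occupancy(_peakset(a_ivs), _peakset(b_ivs))
    assert res["countA_overlapping_B"] == 600
    assert res["countB_overlapping_A"] == 600


def test_width_stats_identical_and_scaled():
    a = _peakset([(0, 100), (200, 300), (400, 500)])
    res = width_stats(a, a)
    assert res["A"]["median"] == res["B"]["median"] == 100
    assert res["p"] == 1.0  # all widths tied

    b = _peakset([(0, 200), (300, 500), (600, 800)])
    res = width_stats(a, b)
    assert res["B"]["median"] / res["A"]["median"] == pytest.approx(2.0)


def test_width_stats_null_rejection_rate_is_calibrated():
    rng = np.random.default_rng(77)
    rejections = 0
    trials = 200
    for _ in range(trials):
        wa = rng.integers(100, 500, size=40)
        wb = rng.integers(100, 500, size=40)
        a = _peakset([(i * 1000, i * 1000 + int(w)) for i, w in enumerate(wa)])
        b = _peakset([(i * 1000, i * 1000 + int(w)) for i, w in enumerate(wb)])
        if width_stats(a, b)["p"] < 0.05:
            rejections += 1
    assert rejections / trials == pytest.approx(0.05, abs=0.03)


def test_width_stats_degenerate_sets():
    a = _peakset([(0, 100)])
    b = _peakset([(0, 150), (200, 260)])
    res = width_stats(a, b)
    assert np.isnan(res["p"])
    with pytest.raises(ValueError):
        width_stats(PeakSet(), b)
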