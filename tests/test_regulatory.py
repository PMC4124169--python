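"""PWM scanning, motif clusters, and peak enrichment at transcript ends."""

import numpy as np
import pandas as pd
import pytest

from isletkit.regulatory import (
    PWM,
    EndEnrichmentResult,
    end_enrichment,
    max_window_count,
    motif_cluster,
    read_jaspar,
    scan_pwm,
    write_jaspar,
)

_RC = str.maketrans("ACGT", "TGCA")


def _consensus_pwm(consensus="ACCGGAAGT", p=0.85):
    counts = np.array([[p if b == c else (1 - p) / 3 for c in consensus] for b in "ACGT"])
    pwm = PWM.from_counts("M", counts * 100, pseudocount=0.0)
    pwm.score_threshold = 0.8 * pwm.max_score
    return pwm


def test_consensus_hits_at_position_zero_with_max_score():
    pwm = _consensus_pwm()
    hits = scan_pwm(pwm.consensus(), pwm)
    assert len(hits) == 1
    assert hits.loc[0, "pos"] == 0 and hits.loc[0, "strand"] == "+"
    assert hits.loc[0, "score"] == pytest.approx(pwm.max_score)


def test_reverse_complement_hits_minus_strand_same_score():
    pwm = _consensus_pwm()
    rc = pwm.consensus().translate(_RC)[::-1]
    hits = scan_pwm(rc, pwm)
    assert len(hits) == 1
    assert hits.loc[0, "strand"] == "-"
    assert hits.loc[0, "score"] == pytest.approx(pwm.max_score)


def test_n_windows_are_skipped():
    pwm = _consensus_pwm()
    seq = pwm.consensus()[:4] + "N" + pwm.consensus()[5:]
    assert scan_pwm(seq, pwm).empty


def test_invalid_alphabet_rejected():
    with pytest.raises(ValueError, match="invalid"):
        scan_pwm("ACGTXACGT", _consensus_pwm())


def _brute_hits(seq, pwm, threshold):
    lo = pwm.log_odds()
    L = pwm.length
    idx = {b: i for i, b in enumerate("ACGT")}
    out = []
    for pos in range(len(seq) - L + 1):
        win = seq[pos:pos + L]
        if "N" in win:
            continue
        fwd = sum(lo[idx[b], j] for j, b in enumerate(win))
        rc = win.translate(_RC)[::-1]
        rev = sum(lo[idx[b], j] for j, b in enumerate(rc))
        if fwd >= threshold:
            out.append((pos, "+", fwd))
        if rev >= threshold:
            out.append((pos, "-", rev))
    return sorted(out)


def test_scan_matches_brute_force_enumeration(rng):
    pwm = _consensus_pwm("ACGTAC", p=0.7)
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=int(rng.integers(50, 400))))
        thr = float(rng.uniform(0.2, 0.9)) * pwm.max_score
        got = scan_pwm(seq, pwm, threshold=thr)
        got_t = sorted((int(r.pos), r.strand, float(r.score)) for r in got.itertuples())
        brute = _brute_hits(seq, pwm, thr)
        assert [(p, s) for p, s, _ in got_t] == [(p, s) for p, s, _ in brute]
        np.testing.assert_allclose([x[2] for x in got_t], [x[2] for x in brute], rtol=1e-9)


def test_scan_is_shift_equivariant(rng):
    pwm = _consensus_pwm()
    core = "".join(rng.choice(list("ACGT"), size=200))
    seq = core[:50] + pwm.consensus() + core[50:]
    base = scan_pwm(seq, pwm)
    shifted = scan_pwm("TTTTT" + seq, pwm)
    assert list(shifted["pos"]) == [p + 5 for p in base["pos"]]


def test_scan_agrees_with_biopython_pssm(rng):
    from Bio.Seq import Seq
    from Bio import motifs as bio_motifs

    pwm = _consensus_pwm()
    seq = "".join(rng.choice(list("ACGT"), size=500))
    m = bio_motifs.Motif(alignment=None, counts={
        b: list(pwm.matrix[i]) for i, b in enumerate("ACGT")
    })
    ref = np.asarray(m.pssm.calculate(Seq(seq)), dtype=float)
    got = scan_pwm(seq, pwm, threshold=-1e9)
    fwd = got[got["strand"] == "+"].set_index("pos")["score"]
    np.testing.assert_allclose(fwd.to_numpy(), ref, atol=1e-4)


def test_jaspar_round_trip(tmp_path):
    pwm = _consensus_pwm()
    path = tmp_path / "m.jaspar"
    write_jaspar([pwm], path)
    back = read_jaspar(path, pseudocount=0.0)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].matrix, pwm.matrix, atol=1e-3)


def test_thirteen_planted_sites_form_one_cluster_of_thirteen(default_sim):
    reg = default_sim.regulatory()
    hits = scan_pwm(reg.sequences["cluster_locus"], reg.pwm)
    clusters = motif_cluster(hits, window=300, min_sites=3, n_shuffle=300, seed=2,
                             region_length=len(reg.sequences["cluster_locus"]))
    assert len(clusters) == 1
    assert int(clusters.loc[0, "n_sites"]) == 13
    assert clusters.loc[0, "p_value"] < 0.05


def test_sites_spaced_400bp_apart_form_no_cluster():
    hits = pd.DataFrame({"pos": [0, 400, 800, 1200]})
    clusters = motif_cluster(hits, window=300, min_sites=2, n_shuffle=100, seed=0,
                             region_length=2000)
    assert clusters.empty


def test_max_window_count_matches_brute_force(rng):
    for _ in range(500):
        n = int(rng.integers(0, 40))
        pos = np.sort(rng.integers(0, 2000, n))
        window = int(rng.integers(10, 500))
        brute = 0
        for p in pos:
            brute = max(brute, int(((pos >= p) & (pos < p + window)).sum()))
        assert max_window_count(pos, window) == brute


def test_end_enrichment_zero_peaks_reports_na():
    transcripts = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [5000]})
    peaks = pd.DataFrame(columns=["chrom", "start", "end"])
    res = end_enrichment(transcripts, peaks, {"c": 100_000}, n_random=100)
    assert np.isnan(res.ratio) and res.message


def test_end_enrichment_requires_100_null_reps():
    transcripts = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [5000]})
    peaks = pd.DataFrame({"chrom": ["c"], "start": [90], "end": [200]})
    with pytest.raises(ValueError, match="n_random"):
        end_enrichment(transcripts, peaks, {"c": 100_000}, n_random=10)


def test_all_peaks_at_ends_gives_minimal_p(default_sim):
    reg = default_sim.regulatory()
    truth = reg.peak_truth
    end_peaks = reg.peaks_mouse.peaks[truth["end_proximal"].to_numpy()]
    res = end_enrichment(reg.transcripts, end_peaks,
                         default_sim.layout.ann.chrom_sizes,
                         window=1000, n_random=200, seed=9)
    assert res.p_value == pytest.approx(1 / 201)
    assert res.ratio > 5


def test_end_enrichment_p_superuniform_under_uniform_null(rng):
    """Under uniform peak placement the empirical p rejects at <= alpha."""
    genome = {"c": 3_000_000}
    rejections = 0
    reps = 120
    for r in range(reps):
        tr = rng.integers(1, 2_900_000, 40)
        transcripts = pd.DataFrame({"chrom": "c", "start": tr, "end": tr + 4000})
        pk = rng.integers(1, 2_990_000, 150)
        peaks = pd.DataFrame({"chrom": "c", "start": pk, "end": pk + 300})
        res = end_enrichment(transcripts, peaks, genome, window=1000,
                             n_random=100, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= 0.05
    assert rejections / reps <= 0.10  # 0.05 nominal + Monte-Carlo slack
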