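"""Coverage segmentation, the five lncRNA filters, positional classes."""

import numpy as np
import pandas as pd
import pytest

from isletkit import io as ikio, lnc_discovery as ld
from isletkit.lnc_discovery import LncFilterConfig, apply_filters, classify_position, segment_coverage
from isletkit.models import GeneModel, GenomeAnnotation


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def test_runs_merge_below_1500bp_gap_and_split_at_1500():
    cfg = LncFilterConfig(min_coverage=1.0)
    merged = segment_coverage(_track([("c", 1, 100, 2.0), ("c", 1600, 1700, 2.0)]), cfg)
    assert len(merged) == 1 and (merged.loc[0, "start"], merged.loc[0, "end"]) == (1, 1700)
    split = segment_coverage(_track([("c", 1, 100, 2.0), ("c", 1601, 1700, 2.0)]), cfg)
    assert len(split) == 2


def test_subthreshold_coverage_ignored():
    cfg = LncFilterConfig(min_coverage=1.0)
    res = segment_coverage(_track([("c", 1, 100, 0.5), ("c", 300, 400, 2.0)]), cfg)
    assert len(res) == 1 and res.loc[0, "start"] == 300


def test_segmentation_matches_brute_force_run_scan(rng):
    cfg = LncFilterConfig(min_coverage=1.0, merge_dist=7)
    for _ in range(500):
        n = int(rng.integers(20, 120))
        depth = rng.choice([0.0, 0.5, 1.0, 2.0], size=n, p=[0.5, 0.1, 0.2, 0.2])
        rows = [("c", i + 1, i + 1, float(v)) for i, v in enumerate(depth) if v > 0]
        got = segment_coverage(_track(rows), cfg) if rows else None
        # brute force: threshold, then merge runs separated by < merge_dist zeros
        above = depth >= cfg.min_coverage
        runs = []
        i = 0
        while i < n:
            if above[i]:
                j = i
                while j + 1 < n and above[j + 1]:
                    j += 1
                runs.append([i + 1, j + 1])
                i = j + 1
            else:
                i += 1
        merged = []
        for r in runs:
            if merged and r[0] - merged[-1][1] - 1 < cfg.merge_dist:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        if not rows:
            continue
        assert [(int(r["start"]), int(r["end"])) for _, r in got.iterrows()] == \
            [(a, b) for a, b in merged]


def _simple_ann():
    genes = [
        GeneModel("coding", "c1", "+", ((100_000, 100_500), (120_000, 120_500))),
        GeneModel("far", "c1", "+", ((400_000, 401_000),)),
    ]
    return GenomeAnnotation(genes, genome_id="t")


def _run_filters(cands, ann=None, cons_score=0.1, alpha=2.0, beta=2.0, rrna_rows=()):
    ann = ann or _simple_ann()
    cons = _track([
        (r["chrom"], int(r["start"]) - 100, int(r["end"]) + 100, cons_score)
        for _, r in cands.iterrows()
    ])
    rrna = pd.DataFrame(list(rrna_rows), columns=["chrom", "start", "end"])
    expr = pd.DataFrame({"alpha": alpha, "beta": beta}, index=cands.index)
    return apply_filters(cands, ann, rrna, cons, expr, LncFilterConfig())


def _cand(chrom, start, end):
    return pd.DataFrame([{"chrom": chrom, "start": start, "end": end, "mean_coverage": 1.0}])


def test_2999bp_candidate_rejected_at_length_only():
    surv, rej = _run_filters(_cand("c1", 200_000, 202_998))
    assert not surv and rej[0].failed_rules == ["length"]
    surv, _ = _run_filters(_cand("c1", 200_000, 203_000))
    assert len(surv) == 1  # 3001 bp passes the strict > 3000 rule


def test_single_base_exon_overlap_rejected():
    surv, rej = _run_filters(_cand("c1", 96_500, 100_000))  # touches exon start
    assert not surv and rej[0].failed_rules == ["exon_overlap"]


def test_mean_phastcon_exactly_0p4_is_kept():
    surv, _ = _run_filters(_cand("c1", 200_000, 204_000), cons_score=0.4)
    assert len(surv) == 1
    _, rej = _run_filters(_cand("c1", 200_000, 204_000), cons_score=0.41)
    assert rej and rej[0].failed_rules == ["conservation"]


def test_rpkm_rule_is_either_population_or():
    surv, _ = _run_filters(_cand("c1", 200_000, 204_000), alpha=0.2, beta=1.5)
    assert len(surv) == 1
    _, rej = _run_filters(_cand("c1", 200_000, 204_000), alpha=0.9, beta=1.0)
    assert rej and rej[0].failed_rules == ["rpkm"]


def test_rrna_overlap_rejected():
    _, rej = _run_filters(
        _cand("c1", 200_000, 204_000), rrna_rows=[("c1", 203_900, 204_400)]
    )
    assert rej and rej[0].failed_rules == ["rrna"]


def test_missing_conservation_is_an_error():
    cands = _cand("c1", 200_000, 204_000)
    cons = _track([("c1", 200_000, 201_000, 0.1)])  # partial cover
    expr = pd.DataFrame({"alpha": [2.0], "beta": [2.0]})
    with pytest.raises(ValueError, match="conservation"):
        apply_filters(cands, _simple_ann(), pd.DataFrame(columns=["chrom", "start", "end"]),
                      cons, expr, LncFilterConfig())


def test_intronic_vs_intergenic_classification():
    ann = _simple_ann()
    inside = ld.NovelTranscript("c1", 105_000, 110_000, 1.0,
                                filter_trace=[(r, True) for r in ld.RULES])
    upstream = ld.NovelTranscript("c1", 360_000, 365_000, 1.0,
                                  filter_trace=[(r, True) for r in ld.RULES])
    classify_position([inside, upstream], ann)
    assert inside.cls == "intronic"
    assert upstream.cls == "intergenic"


def test_output_invariant_to_candidate_order(small_sim):
    lnc = small_sim.lnc_loci()
    combined = ikio.sum_tracks([lnc.coverage["alpha"], lnc.coverage["beta"]])
    cfg = LncFilterConfig()
    cands = segment_coverage(combined, cfg)
    expr = ld.candidate_rpkm(cands, lnc.coverage, lnc.mapped_totals, lnc.read_length)
    shuffled = cands.sample(frac=1.0, random_state=3)
    surv1, _ = apply_filters(cands, small_sim.layout.ann, lnc.rrna, lnc.conservation, expr, cfg)
    surv2, _ = apply_filters(shuffled, small_sim.layout.ann, lnc.rrna, lnc.conservation,
                             expr.loc[shuffled.index], cfg)
    key = lambda t: (t.chrom, t.start, t.end)
    assert sorted(map(key, surv1)) == sorted(map(key, surv2))


def test_small_fixture_recovers_planted_truth_exactly(small_sim):
    lnc = small_sim.lnc_loci()
    combined = ikio.sum_tracks([lnc.coverage["alpha"], lnc.coverage["beta"]])
    cfg = LncFilterConfig()
    cands = segment_coverage(combined, cfg)
    expr = ld.candidate_rpkm(cands, lnc.coverage, lnc.mapped_totals, lnc.read_length)
    surv, rej = apply_filters(cands, small_sim.layout.ann, lnc.rrna, lnc.conservation,
                              expr, cfg)
    classify_position(surv, small_sim.layout.ann)
    truth = lnc.lnc_truth
    true_rows = truth[truth["label"] == "true_lnc"]
    assert {(s.chrom, s.start, s.end) for s in surv} == {
        (r.chrom, r.start, r.end) for r in true_rows.itertuples()
    }
    got_cls = {(s.chrom, s.start, s.end): s.cls for s in surv}
    for r in true_rows.to_dict("records"):
        assert got_cls[(r["chrom"], r["start"], r["end"])] == r["class"]
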