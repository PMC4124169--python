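"""Common core, species-specificity calls, differential peak binding."""

import numpy as np
import pandas as pd
import pytest

from isletkit import diffexpr, quantify, xspecies
from isletkit.models import Block, BlockMap, OrthologMap, PeakSet
from isletkit.xspecies import SpeciesCallConfig, classify_specificity, common_core


def _omap(n):
    return OrthologMap([(f"m{i}", f"h{i}") for i in range(n)], "mouse", "human")


def test_common_core_requires_strictly_above_one_in_both():
    omap = _omap(2)
    rpkm_m = {"m0": 5.0, "m1": 5.0}
    rpkm_h = {"h0": 2.0, "h1": 1.0}
    core = common_core(rpkm_m, rpkm_h, omap)
    assert bool(core.loc["m0|h0", "in_core"])
    assert not bool(core.loc["m1|h1", "in_core"])  # 1.0 is not > 1


def test_common_core_matches_set_comprehension_oracle(rng):
    n = 300
    omap = _omap(n)
    rpkm_m = {f"m{i}": float(10 ** rng.uniform(-1, 2)) for i in range(n)}
    rpkm_h = {f"h{i}": float(10 ** rng.uniform(-1, 2)) for i in range(n)}
    core = common_core(rpkm_m, rpkm_h, omap)
    expected = {
        f"m{i}|h{i}" for i in range(n) if rpkm_m[f"m{i}"] > 1 and rpkm_h[f"h{i}"] > 1
    }
    assert set(core.index[core["in_core"]]) == expected


def test_one_to_one_policy_drops_ambiguous_pairs():
    omap = OrthologMap([("m0", "h0"), ("m0", "h1"), ("m2", "h2")])
    kept = omap.one_to_one().pairs
    assert kept == [("m2", "h2")]


def _de_row(pair, lfc, p):
    return {"gene_id": pair, "log2_fold": lfc, "p_value": p, "q_value": p * 10}


@pytest.mark.parametrize(
    "rpkm_m, rpkm_h, lfc, p, expected",
    [
        (50.0, 0.9, np.log2(55), 1e-9, "mouse_unique"),
        (50.0, 2.0, np.log2(25), 1e-9, "mouse_enriched"),
        (50.0, 2.0, np.log2(8), 1e-12, "shared"),  # fold gate fails, both expressed
        (50.0, 2.0, np.log2(25), 1e-3, "shared"),  # significance gate fails
        (0.9, 50.0, -np.log2(55), 1e-9, "human_unique"),
    ],
)
def test_classification_rules(rpkm_m, rpkm_h, lfc, p, expected):
    omap = _omap(1)
    de = pd.DataFrame([_de_row("m0|h0", lfc, p)])
    res = classify_specificity(
        {"m0": rpkm_m}, {"h0": rpkm_h}, de, omap, species1="mouse", species2="human"
    )
    assert res.loc["m0|h0", "call"] == expected


def _beta_tables(sim):
    c = sim.counts()
    beta = ["beta_1", "beta_2"]
    cm = c.counts_mouse[beta]
    ch = c.counts_human[beta]
    rm = quantify.rpkm_matrix(cm, c.ann_mouse).mean(axis=1)
    rh = quantify.rpkm_matrix(ch, c.ann_human).mean(axis=1)
    return c, cm, ch, rm, rh


def _classify(cm, ch, rm, rh, omap, species1, species2):
    paired = xspecies.paired_counts(cm, ch, omap)
    de = diffexpr.nb_test(
        paired,
        [c for c in paired.columns if c.endswith("_sp1")],
        [c for c in paired.columns if c.endswith("_sp2")],
    )
    return classify_specificity(rm.to_dict(), rh.to_dict(), de, omap,
                                species1=species1, species2=species2)


def test_partition_identity_and_mirror_under_species_swap(small_sim):
    c, cm, ch, rm, rh = _beta_tables(small_sim)
    calls = _classify(cm, ch, rm, rh, c.orthologs, "mouse", "human")
    for sp in ("mouse", "human"):
        side = calls["call"].str.startswith(sp).sum()
        unique = (calls["call"] == f"{sp}_unique").sum()
        enriched = (calls["call"] == f"{sp}_enriched").sum()
        assert side == unique + enriched

    swapped_map = OrthologMap([(b, a) for a, b in c.orthologs.pairs], "human", "mouse")
    swapped = _classify(ch, cm, rh, rm, swapped_map, "human", "mouse")
    mirror = {
        "mouse_unique": "mouse_unique", "mouse_enriched": "mouse_enriched",
        "human_unique": "human_unique", "human_enriched": "human_enriched",
        "shared": "shared", "ns": "ns",
    }
    fwd = {i: mirror[v] for i, v in calls["call"].items()}
    rev = {"|".join(reversed(i.split("|"))): v for i, v in swapped["call"].items()}
    assert fwd == rev


def test_planted_species_unique_genes_recovered(small_sim):
    c, cm, ch, rm, rh = _beta_tables(small_sim)
    calls = _classify(cm, ch, rm, rh, c.orthologs, "mouse", "human").set_index("gene_1")
    truth = c.gene_truth
    for label in ("mouse_unique", "human_unique"):
        planted = truth.index[truth["species_label"] == label]
        recovered = (calls.loc[planted, "call"] == label).mean()
        assert recovered >= 0.95


def _peakset(rows, genome):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "reads"]),
                   genome_id=genome)


def test_species_peak_fourfold_boundary_is_inclusive():
    # identity map; equal totals so per-million reads mirror raw reads
    bmap = BlockMap([Block("c1", 1, 100_000, "c1", 1, 100_000, "+")])
    p1 = _peakset([("c1", 100, 500, "a", 40), ("c1", 5000, 5400, "b", 60)], "g1")
    p2 = _peakset([("c1", 100, 500, "a", 10), ("c1", 5000, 5400, "b", 90)], "g2")
    regions, unmapped = xspecies.species_specific_peaks(p1, p2, bmap)
    assert unmapped.empty
    by_start = regions.set_index("start")
    assert by_start.loc[100, "call"] == "species1_specific"  # 40 vs 10: ratio 4 exactly
    assert by_start.loc[5000, "call"] == "shared"            # 60 vs 90


def test_species_peak_threefold_is_shared():
    bmap = BlockMap([Block("c1", 1, 100_000, "c1", 1, 100_000, "+")])
    p1 = _peakset([("c1", 100, 500, "a", 30), ("c1", 5000, 5400, "b", 70)], "g1")
    p2 = _peakset([("c1", 100, 500, "a", 10), ("c1", 5000, 5400, "b", 90)], "g2")
    regions, _ = xspecies.species_specific_peaks(p1, p2, bmap)
    assert regions.set_index("start").loc[100, "call"] == "shared"


def test_planted_ratio5_peaks_all_called_specific(small_sim):
    reg = small_sim.regulatory()
    regions, unmapped = xspecies.species_specific_peaks(
        reg.peaks_mouse, reg.peaks_human, reg.blockmap_m2h.inverted()
    )
    assert unmapped.empty
    truth = reg.peak_truth
    peaks_m = reg.peaks_mouse.peaks.set_index("name")
    for row in truth.itertuples(index=False):
        if row.species_label == "shared":
            continue
        pk = peaks_m.loc[row.name]
        hit = regions[
            (regions["chrom"] == pk["chrom"])
            & (regions["start"] <= pk["end"])
            & (regions["end"] >= pk["start"])
        ]
        expected = "species1_specific" if row.species_label == "mouse_specific" else "species2_specific"
        assert (hit["call"] == expected).any()
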