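"""Cross-species beta-cell transcriptome comparison.

Ortholog pairs (restricted to 1:1) are compared on replicate-mean beta
RPKM and on an NB test of the ortholog-paired beta counts with species
as the grouping factor. A pair belongs to the common core when beta RPKM
exceeds 1 in both species. A pair is species-specific when the fold on
normalized counts exceeds 10 toward one species with p < 1e-7 and BH
q < 0.001; within a species' side, the gene is "unique" when the other
species' beta RPKM is below 1 and "enriched" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import convert_interval
from .intervals import merge_intervals, overlap_length
from .models import BlockMap, OrthologMap, PeakSet

log = logging.getLogger(__name__)


@dataclass
class SpeciesCallConfig:
    rpkm_core_threshold: float = 1.0
    fold_threshold: float = 10.0
    p_threshold: float = 1e-7
    fdr_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.rpkm_core_threshold, self.fold_threshold,
               self.p_threshold, self.fdr_threshold) <= 0:
            raise ValueError("all thresholds must be positive")


def _paired(
    rpkm_1: Mapping[str, float],
    rpkm_2: Mapping[str, float],
    omap: OrthologMap,
) -> pd.DataFrame:
    """1:1 pairs with RPKM on both sides; unmapped genes dropped (logged)."""
    one2one = omap.one_to_one()
    dropped_ambiguous = len(omap.pairs) - len(one2one.pairs)
    rows, dropped_missing = [], 0
    for g1, g2 in one2one.pairs:
        if g1 in rpkm_1 and g2 in rpkm_2:
            rows.append((g1, g2, float(rpkm_1[g1]), float(rpkm_2[g2])))
        else:
            dropped_missing += 1
    log.info(
        "ortholog pairing: %d pairs kept, %d ambiguous dropped, %d without expression",
        len(rows), dropped_ambiguous, dropped_missing,
    )
    df = pd.DataFrame(rows, columns=["gene_1", "gene_2", "rpkm_1", "rpkm_2"])
    df["pair_id"] = df["gene_1"] + "|" + df["gene_2"]
    return df.set_index("pair_id")


def common_core(
    rpkm_1: Mapping[str, float],
    rpkm_2: Mapping[str, float],
    omap: OrthologMap,
    cfg: SpeciesCallConfig | None = None,
) -> pd.DataFrame:
    """Ortholog pairs with beta RPKM strictly above threshold in BOTH species."""
    cfg = cfg or SpeciesCallConfig()
    df = _paired(rpkm_1, rpkm_2, omap)
    df["in_core"] = (df["rpkm_1"] > cfg.rpkm_core_threshold) & (
        df["rpkm_2"] > cfg.rpkm_core_threshold
    )
    return df


def paired_counts(
    counts_1: pd.DataFrame,
    counts_2: pd.DataFrame,
    omap: OrthologMap,
) -> pd.DataFrame:
    """Join the beta count columns of both species on 1:1 ortholog pairs.

    Species-1 columns are suffixed ``_sp1``, species-2 ``_sp2``; the index
    is the pair id ``gene1|gene2``.
    """
    one2one = omap.one_to_one()
    rows = [
        (g1, g2)
        for g1, g2 in one2one.pairs
        if g1 in counts_1.index and g2 in counts_2.index
    ]
    idx = [f"{a}|{b}" for a, b in rows]
    left = counts_1.loc[[a for a, _ in rows]].add_suffix("_sp1")
    right = counts_2.loc[[b for _, b in rows]].add_suffix("_sp2")
    left.index = idx
    right.index = idx
    return left.join(right)


def classify_specificity(
    rpkm_1: Mapping[str, float],
    rpkm_2: Mapping[str, float],
    de: pd.DataFrame,
    omap: OrthologMap,
    cfg: SpeciesCallConfig | None = None,
    species1: str = "species1",
    species2: str = "species2",
) -> pd.DataFrame:
    """Call each ortholog pair unique/enriched per species, shared, or ns.

    ``de`` is the NB result on :func:`paired_counts` (log2_fold positive
    toward species 1), indexed or keyed by pair id. The significance side
    requires fold > ``fold_threshold`` AND p < p_threshold AND
    q < fdr_threshold; within a side, "unique" means the other species'
    RPKM is below the core threshold, otherwise "enriched". Pairs that
    fail the gate are "shared" when both RPKMs clear the core threshold,
    else "ns".
    """
    cfg = cfg or SpeciesCallConfig()
    df = _paired(rpkm_1, rpkm_2, omap)
    de_idx = de.set_index("gene_id") if "gene_id" in de.columns else de
    missing = [p for p in df.index if p not in de_idx.index]
    if missing:
        raise KeyError(f"pairs missing from DE table: {missing[:5]}")
    df = df.join(de_idx[["log2_fold", "p_value", "q_value"]])
    if df[["rpkm_1", "rpkm_2"]].isna().any().any():
        raise ValueError("missing RPKM for a tested pair")

    log2_gate = np.log2(cfg.fold_threshold)
    sig = (df["p_value"] < cfg.p_threshold) & (df["q_value"] < cfg.fdr_threshold)
    side1 = sig & (df["log2_fold"] > log2_gate)
    side2 = sig & (df["log2_fold"] < -log2_gate)
    thr = cfg.rpkm_core_threshold

    call = pd.Series("ns", index=df.index, dtype=object)
    call[side1 & (df["rpkm_2"] < thr)] = f"{species1}_unique"
    call[side1 & (df["rpkm_2"] >= thr)] = f"{species1}_enriched"
    call[side2 & (df["rpkm_1"] < thr)] = f"{species2}_unique"
    call[side2 & (df["rpkm_1"] >= thr)] = f"{species2}_enriched"
    neither = ~side1 & ~side2
    call[neither & (df["rpkm_1"] > thr) & (df["rpkm_2"] > thr)] = "shared"
    df["call"] = call
    return df


def species_specific_peaks(
    peaks_1: PeakSet,
    peaks_2: PeakSet,
    bmap_2_to_1: BlockMap,
    fold: float = 4.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential TF binding after projecting species-2 peaks onto genome 1.

    Species-2 peaks are converted through the block map (unconvertible
    peaks are returned separately). Peak intervals of both species are
    unioned into regions on the common genome; per region, each species'
    overlapping peak reads are summed and normalized per million peak
    reads. A region is species-specific when the normalized-read ratio
    is at least ``fold`` (inclusive boundary, so 40 vs 10 reads per
    million is already specific); the denominator is floored at
    ``pseudocount`` so empty regions do not divide by zero.

    Returns ``(regions, unmapped_species2_peaks)``.
    """
    mapped_rows = []
    unmapped = []
    for row in peaks_2.peaks.itertuples(index=False):
        res = convert_interval((row.chrom, int(row.start), int(row.end)), bmap_2_to_1)
        if res is None:
            unmapped.append(row)
        else:
            mapped_rows.append((res.chrom, res.start, res.end, row.name, float(row.reads)))
    mapped2 = pd.DataFrame(mapped_rows, columns=["chrom", "start", "end", "name", "reads"])
    unmapped_df = pd.DataFrame(unmapped, columns=peaks_2.peaks.columns)
    if len(unmapped):
        log.info("species_specific_peaks: %d species-2 peaks not convertible", len(unmapped))

    p1 = peaks_1.peaks
    all_ivs = pd.concat(
        [p1[["chrom", "start", "end"]], mapped2[["chrom", "start", "end"]]],
        ignore_index=True,
    )
    total_1 = max(peaks_1.total_reads, 1.0)
    total_2 = max(peaks_2.total_reads, 1.0)

    regions = []
    for chrom, sub in all_ivs.groupby("chrom"):
        for s, e in merge_intervals(list(zip(sub["start"], sub["end"]))):
            r1 = p1[(p1["chrom"] == chrom)]
            reads_1 = sum(
                float(r.reads)
                for r in r1.itertuples(index=False)
                if overlap_length((s, e), (int(r.start), int(r.end))) > 0
            )
            r2 = mapped2[(mapped2["chrom"] == chrom)]
            reads_2 = sum(
                float(r.reads)
                for r in r2.itertuples(index=False)
                if overlap_length((s, e), (int(r.start), int(r.end))) > 0
            )
            rpm_1 = reads_1 / total_1 * 1e6
            rpm_2 = reads_2 / total_2 * 1e6
            ratio_1 = rpm_1 / max(rpm_2, pseudocount)
            ratio_2 = rpm_2 / max(rpm_1, pseudocount)
            if ratio_1 >= fold:
                call = "species1_specific"
            elif ratio_2 >= fold:
                call = "species2_specific"
            else:
                call = "shared"
            regions.append((chrom, s, e, rpm_1, rpm_2, max(ratio_1, ratio_2), call))
    out = pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "rpm_1", "rpm_2", "ratio", "call"],
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out, unmapped_df
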