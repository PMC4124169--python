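"""Link novel transcripts to their nearest protein-coding gene and test
whether beta/alpha enrichment is shared between the two.

The per-feature statistic is the log2 ratio of beta over alpha RPKM with
a pseudocount of 0.1 RPKM; co-regulation is quantified with Spearman's
rank correlation (the ratio distributions are heavy-tailed, so a rank
statistic is the safer choice), which also makes the result invariant
to any common monotone rescaling of the RPKM values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import gap_between
from .models import GenomeAnnotation

log = logging.getLogger(__name__)

RPKM_EPS = 0.1


@dataclass
class NeighborPair:
    lnc_id: str
    gene_id: str
    distance: int
    lnc_log_ratio: float = float("nan")
    gene_log_ratio: float = float("nan")


def log_ratio(beta_rpkm: float, alpha_rpkm: float, eps: float = RPKM_EPS) -> float:
    return float(np.log2((beta_rpkm + eps) / (alpha_rpkm + eps)))


def nearest_gene(
    lnc: pd.DataFrame,
    ann: GenomeAnnotation,
    lnc_rpkm: Optional[pd.DataFrame] = None,
    gene_rpkm: Optional[pd.DataFrame] = None,
    eps: float = RPKM_EPS,
) -> list[NeighborPair]:
    """Pair each lncRNA interval with its closest protein-coding gene.

    Distance is the gap between the lncRNA interval and the gene-body
    span (0 when they overlap, e.g. intronic lncRNAs inside their host).
    Ties break toward the gene with the smaller body start, then the
    lexicographically smaller gene_id; strand is ignored. lncRNAs on
    chromosomes without any protein-coding gene are dropped with a
    warning. ``lnc_rpkm`` / ``gene_rpkm`` (columns ``beta``, ``alpha``,
    indexed by id) fill in the log ratios when provided.
    """
    by_chrom: dict[str, list] = {}
    for g in ann.genes:
        if g.biotype == "protein_coding":
            by_chrom.setdefault(g.chrom, []).append(g)
    pairs: list[NeighborPair] = []
    for row in lnc.itertuples(index=False):
        chrom, s, e = str(row.chrom), int(row.start), int(row.end)
        lnc_id = getattr(row, "lnc_id", None) or f"{chrom}:{s}-{e}"
        genes = by_chrom.get(chrom)
        if not genes:
            log.warning("lncRNA %s: no protein-coding gene on %s; dropped", lnc_id, chrom)
            continue
        best = min(
            genes,
            key=lambda g: (gap_between((s, e), g.span), g.span[0], g.gene_id),
        )
        pair = NeighborPair(
            lnc_id=lnc_id,
            gene_id=best.gene_id,
            distance=gap_between((s, e), best.span),
        )
        if lnc_rpkm is not None and lnc_id in lnc_rpkm.index:
            pair.lnc_log_ratio = log_ratio(
                float(lnc_rpkm.loc[lnc_id, "beta"]), float(lnc_rpkm.loc[lnc_id, "alpha"]), eps
            )
        if gene_rpkm is not None and best.gene_id in gene_rpkm.index:
            pair.gene_log_ratio = log_ratio(
                float(gene_rpkm.loc[best.gene_id, "beta"]),
                float(gene_rpkm.loc[best.gene_id, "alpha"]),
                eps,
            )
        pairs.append(pair)
    return pairs


def coreg_correlation(pairs: list[NeighborPair]) -> tuple[float, float, int]:
    """Spearman correlation of lncRNA vs. neighbor-gene beta/alpha log ratios.

    Returns (rho, two-sided p, n). Requires at least 10 pairs with finite
    ratios on both sides.
    """
    x = np.array([p.lnc_log_ratio for p in pairs])
    y = np.array([p.gene_log_ratio for p in pairs])
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need >= 10 pairs with finite ratios, got {n}")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p), n


def pairs_table(pairs: list[NeighborPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "gene_id": p.gene_id,
                "distance": p.distance,
                "lnc_log_ratio": p.lnc_log_ratio,
                "gene_log_ratio": p.gene_log_ratio,
            }
            for p in sorted(pairs, key=lambda q: q.lnc_id)
        ]
    )
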