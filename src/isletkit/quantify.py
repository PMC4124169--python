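"""RPKM quantification and per-gene read fractions.

RPKM (reads per kilobase of exon model per million mapped reads) divides
each gene's count by the length of its exon model — the union of all its
exons — in kb and the sample's mapped-read total in millions. Unless a
per-sample total is supplied, the column sum of the count table is used
as the mapped total.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .models import GenomeAnnotation


def _mapped_totals(counts: pd.DataFrame, mapped_total) -> pd.Series:
    if mapped_total is None:
        totals = counts.sum(axis=0).astype(float)
    elif isinstance(mapped_total, (int, float)):
        totals = pd.Series(float(mapped_total), index=counts.columns)
    else:
        totals = pd.Series({s: float(mapped_total[s]) for s in counts.columns})
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"mapped totals must be positive; offending samples: {bad}")
    return totals


def compute_rpkm(
    counts: pd.DataFrame,
    ann: GenomeAnnotation,
    mapped_total: Optional[Mapping[str, float] | float] = None,
) -> pd.DataFrame:
    """Tidy expression table with one row per (gene, sample).

    Parameters
    ----------
    counts
        Genes x samples integer table.
    ann
        Annotation providing the exon model for every gene in ``counts``.
    mapped_total
        Per-sample mapped-read totals; defaults to column sums.

    Returns
    -------
    DataFrame with columns gene_id, sample, count, rpkm, fraction.
    """
    unknown = [g for g in counts.index if g not in ann.by_id]
    if unknown:
        raise KeyError(f"gene_ids missing from annotation: {unknown[:10]}"
                       + ("..." if len(unknown) > 10 else ""))
    totals = _mapped_totals(counts, mapped_total)
    lengths_kb = pd.Series(
        {g: ann.by_id[g].merged_exon_length / 1000.0 for g in counts.index}
    )
    rows = []
    for sample in counts.columns:
        per_million = totals[sample] / 1e6
        rpkm = counts[sample] / (lengths_kb * per_million)
        frac = counts[sample] / totals[sample]
        for gene in counts.index:
            rows.append((gene, sample, int(counts.at[gene, sample]),
                         float(rpkm[gene]), float(frac[gene])))
    out = pd.DataFrame(rows, columns=["gene_id", "sample", "count", "rpkm", "fraction"])
    return out.sort_values(["gene_id", "sample"], kind="mergesort").reset_index(drop=True)


def rpkm_matrix(
    counts: pd.DataFrame,
    ann: GenomeAnnotation,
    mapped_total=None,
) -> pd.DataFrame:
    """Genes x samples RPKM matrix (wide companion of :func:`compute_rpkm`)."""
    totals = _mapped_totals(counts, mapped_total)
    lengths_kb = pd.Series(
        {g: ann.by_id[g].merged_exon_length / 1000.0 for g in counts.index}
    )
    unknown = lengths_kb.index[lengths_kb.isna()] if lengths_kb.isna().any() else []
    if len(unknown):
        raise KeyError(f"gene_ids missing from annotation: {list(unknown)[:10]}")
    return counts.div(totals / 1e6, axis=1).div(lengths_kb, axis=0)


def read_fractions(
    counts: pd.DataFrame,
    groups: Optional[Mapping[str, str]] = None,
    mapped_total=None,
) -> pd.DataFrame:
    """Per-gene fraction of mapped reads in each sample.

    With ``groups`` (sample -> group label), fractions are averaged across
    the replicates of each group, mirroring statements like "Ins2 holds
    13.0% of all mapped reads on average".
    """
    totals = _mapped_totals(counts, mapped_total)
    frac = counts.div(totals, axis=1)
    if groups is None:
        return frac
    grouping = pd.Series({s: groups[s] for s in counts.columns})
    return frac.T.groupby(grouping).mean().T
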