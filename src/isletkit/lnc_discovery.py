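"""Novel lncRNA discovery: coverage segmentation plus five filtering rules.

Candidates are maximal runs of read density at or above a coverage
threshold, with runs separated by gaps shorter than ``merge_dist``
(default 1,500 bp) merged. Each candidate is then screened by five rules
applied in a fixed order:

1. ``exon_overlap`` — no base may overlap any annotated gene exon;
2. ``length``       — total length strictly greater than 3 kb;
3. ``rpkm``         — alpha OR beta replicate-mean RPKM strictly above 1;
4. ``rrna``         — no base may overlap a known rRNA locus;
5. ``conservation`` — mean PhastCon must not exceed 0.4 (a mean of
   exactly 0.4 passes; high conservation flags likely pseudogene
   mapping artifacts rather than genuine novel transcripts).

Survivors are classified as intronic (fully inside the gene-body span of
a protein-coding gene) or intergenic. The full pass/fail trace of every
candidate is kept, so rejected candidates document exactly which rule
removed them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .intervals import IntervalIndex, overlap_length
from .models import GenomeAnnotation

log = logging.getLogger(__name__)

RULES = ("exon_overlap", "length", "rpkm", "rrna", "conservation")


@dataclass
class LncFilterConfig:
    min_length: int = 3000          # bp, strict >
    min_rpkm: float = 1.0           # strict >, either population
    max_phastcon: float = 0.4       # strict > fails
    merge_dist: int = 1500          # bp; gaps >= merge_dist split runs
    min_coverage: float = 0.02      # read depth threshold for segmentation

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_rpkm, self.max_phastcon,
               self.merge_dist, self.min_coverage) <= 0:
            raise ValueError("all filter parameters must be positive")


@dataclass
class NovelTranscript:
    chrom: str
    start: int
    end: int
    mean_coverage: float
    rpkm: dict[str, float] = field(default_factory=dict)
    conservation_mean: float = float("nan")
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)
    cls: str | None = None  # "intronic" / "intergenic", survivors only

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.filter_trace)

    @property
    def failed_rules(self) -> list[str]:
        return [rule for rule, ok in self.filter_trace if not ok]

    @property
    def transcript_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def segment_coverage(cov: pd.DataFrame, cfg: LncFilterConfig | None = None) -> pd.DataFrame:
    """Maximal high-density runs from a coverage track (1-based closed).

    Rows with score >= ``min_coverage`` seed runs; consecutive runs whose
    gap is strictly below ``merge_dist`` are merged (a 1,499 bp gap
    merges, a 1,500 bp gap splits). ``mean_coverage`` averages depth over
    the full merged span, counting gap bases as zero.
    """
    cfg = cfg or LncFilterConfig()
    rows = []
    dense = cov[cov["score"] >= cfg.min_coverage]
    for chrom, sub in dense.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        mass = 0.0
        for s, e, v in sub[["start", "end", "score"]].itertuples(index=False):
            s, e = int(s), int(e)
            if cur_e is not None and s - cur_e - 1 < cfg.merge_dist:
                cur_e = max(cur_e, e)
                mass += float(v) * (e - s + 1)
            else:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, mass / (cur_e - cur_s + 1)))
                cur_s, cur_e = s, e
                mass = float(v) * (e - s + 1)
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, mass / (cur_e - cur_s + 1)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_coverage"])
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def candidate_rpkm(
    cands: pd.DataFrame,
    coverage_by_pop: Mapping[str, pd.DataFrame],
    mapped_total: Mapping[str, float],
    read_length: float = 50.0,
) -> pd.DataFrame:
    """Per-candidate RPKM from per-population coverage tracks.

    The read count over an interval is approximated as the coverage mass
    (depth x bases) divided by the read length; RPKM then normalizes by
    interval length in kb and the population's mapped total in millions.
    """
    out = {}
    for pop, track in coverage_by_pop.items():
        total_m = mapped_total[pop] / 1e6
        vals = []
        for chrom, s, e in cands[["chrom", "start", "end"]].itertuples(index=False):
            sub = track[track["chrom"] == chrom]
            mass = sum(
                float(v) * overlap_length((int(s), int(e)), (int(ts), int(te)))
                for ts, te, v in sub[["start", "end", "score"]].itertuples(index=False)
            )
            count = mass / read_length
            length_kb = (int(e) - int(s) + 1) / 1000.0
            vals.append(count / (length_kb * total_m))
        out[pop] = vals
    return pd.DataFrame(out, index=cands.index)


def _conservation_mean(
    chrom: str, start: int, end: int, cons: pd.DataFrame
) -> float:
    sub = cons[cons["chrom"] == chrom]
    covered = 0
    mass = 0.0
    for ts, te, v in sub[["start", "end", "score"]].itertuples(index=False):
        ov = overlap_length((start, end), (int(ts), int(te)))
        covered += ov
        mass += float(v) * ov
    length = end - start + 1
    if covered < length:
        raise ValueError(
            f"conservation track does not cover {chrom}:{start}-{end} "
            f"({covered}/{length} bases)"
        )
    return mass / length


def apply_filters(
    cands: pd.DataFrame,
    ann: GenomeAnnotation,
    rrna: pd.DataFrame,
    cons: pd.DataFrame,
    expr: pd.DataFrame,
    cfg: LncFilterConfig | None = None,
) -> tuple[list[NovelTranscript], list[NovelTranscript]]:
    """Run the five rules over segmentation candidates.

    Parameters
    ----------
    cands
        Candidate table (chrom, start, end, mean_coverage).
    rrna
        rRNA loci as a 1-based closed interval table (chrom, start, end).
    cons
        Conservation track (chrom, start, end, score in [0, 1]).
    expr
        Per-candidate RPKM with columns ``alpha`` and ``beta``, aligned
        to ``cands`` by position.

    Returns
    -------
    (survivors, rejected); every transcript carries its full filter trace.
    """
    cfg = cfg or LncFilterConfig()
    exon_idx = ann.exon_index()
    rrna_idx = IntervalIndex.from_tuples(
        [(c, int(s), int(e)) for c, s, e in rrna[["chrom", "start", "end"]].itertuples(index=False)]
    )
    order = cands.sort_values(["chrom", "start"], kind="mergesort")
    survivors: list[NovelTranscript] = []
    rejected: list[NovelTranscript] = []
    for i, row in order.iterrows():
        chrom, s, e = str(row["chrom"]), int(row["start"]), int(row["end"])
        alpha_rpkm = float(expr.loc[i, "alpha"])
        beta_rpkm = float(expr.loc[i, "beta"])
        cons_mean = _conservation_mean(chrom, s, e, cons)
        trace = [
            ("exon_overlap", not exon_idx.overlaps_any(chrom, s, e)),
            ("length", (e - s + 1) > cfg.min_length),
            ("rpkm", alpha_rpkm > cfg.min_rpkm or beta_rpkm > cfg.min_rpkm),
            ("rrna", not rrna_idx.overlaps_any(chrom, s, e)),
            ("conservation", not (cons_mean > cfg.max_phastcon)),
        ]
        nt = NovelTranscript(
            chrom=chrom,
            start=s,
            end=e,
            mean_coverage=float(row.get("mean_coverage", float("nan"))),
            rpkm={"alpha": alpha_rpkm, "beta": beta_rpkm},
            conservation_mean=cons_mean,
            filter_trace=trace,
        )
        (survivors if nt.passed else rejected).append(nt)
    log.info("lncRNA filtering: %d survivors, %d rejected", len(survivors), len(rejected))
    return survivors, rejected


def classify_position(
    survivors: list[NovelTranscript], ann: GenomeAnnotation
) -> list[NovelTranscript]:
    """Label each survivor intronic or intergenic (in place, also returned).

    Intronic means fully contained within the gene-body span (first exon
    start to last exon end) of at least one protein-coding gene; by
    construction survivors are non-exonic, so containment implies the
    transcript sits in introns.
    """
    body_idx = IntervalIndex()
    for g in ann.genes:
        if g.biotype == "protein_coding":
            body_idx.add(g.chrom, g.span[0], g.span[1], g.gene_id)
    for nt in survivors:
        hits = body_idx.overlapping(nt.chrom, nt.start, nt.end)
        contained = any(s <= nt.start and nt.end <= e for s, e, _ in hits)
        nt.cls = "intronic" if contained else "intergenic"
    return survivors


def transcripts_table(transcripts: list[NovelTranscript]) -> pd.DataFrame:
    """Flat TSV-ready view (coordinates, class, RPKM, trace)."""
    rows = []
    for nt in sorted(transcripts, key=lambda t: (t.chrom, t.start)):
        rows.append(
            {
                "transcript_id": nt.transcript_id,
                "chrom": nt.chrom,
                "start": nt.start,
                "end": nt.end,
                "length": nt.length,
                "class": nt.cls or "",
                "alpha_rpkm": nt.rpkm.get("alpha", float("nan")),
                "beta_rpkm": nt.rpkm.get("beta", float("nan")),
                "mean_coverage": nt.mean_coverage,
                "conservation_mean": nt.conservation_mean,
                "failed_rules": ",".join(nt.failed_rules),
            }
        )
    return pd.DataFrame(rows)
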