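"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* In memory, every interval is 1-based and closed (GTF convention).
* BED and bedGraph files are 0-based half-open on disk and converted here.
* All tabular outputs are TSV with a header row and deterministic row
  order (chrom, start, then identifier), so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Block,
    BlockMap,
    GeneModel,
    GenomeAnnotation,
    MappedInterval,
    OrthologMap,
    PeakSet,
    ValidationError,
)

log = logging.getLogger(__name__)

GTF_COLUMNS = 9


class ParseError(ValueError):
    """A malformed line in an input file (message carries the line number)."""


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{i}: expected 'chrom<TAB>length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _prevalidate_gtf(path) -> None:
    """Cheap structural check so errors carry a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != GTF_COLUMNS:
                raise ParseError(f"{path}:{i}: expected {GTF_COLUMNS} tab-separated fields")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer coordinates") from exc
            if end < start:
                raise ValidationError(f"{path}:{i}: exon end {end} < start {start}")


def read_annotation(
    path,
    chrom_sizes: Optional[dict[str, int] | str | Path] = None,
    genome_id: str = "genome",
) -> GenomeAnnotation:
    """Parse a GTF (exon features) into a :class:`GenomeAnnotation`.

    Exon coordinates are kept 1-based closed as printed. Genes inherit the
    ``gene_biotype`` attribute when present, otherwise ``protein_coding``.
    """
    _prevalidate_gtf(path)
    if chrom_sizes is not None and not isinstance(chrom_sizes, dict):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    with open(path) as fh:
        has_data = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_data:
        return GenomeAnnotation(genes=[], genome_id=genome_id, chrom_sizes=chrom_sizes or {})
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ParseError(f"{path}: exon feature without gene_id attribute")
        rec = per_gene.setdefault(
            gid,
            {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": feat.attributes.get("gene_biotype", ["protein_coding"])[0],
                "exons": [],
            },
        )
        if feat.seqid != rec["chrom"] or feat.strand != rec["strand"]:
            raise ValidationError(f"{gid}: exons disagree on chrom/strand")
        rec["exons"].append((feat.start, feat.end))
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"] if rec["biotype"] in ("protein_coding", "rRNA") else "other",
        )
        for gid, rec in per_gene.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return GenomeAnnotation(genes=genes, genome_id=genome_id, chrom_sizes=chrom_sizes or {})


def write_annotation(ann: GenomeAnnotation, path, source: str = "isletkit") -> None:
    """Write exon features, one transcript per gene, sorted deterministically."""
    genes = sorted(ann.genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            for s, e in g.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph (0-based half-open on disk)
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a 1-based closed interval table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based closed
    df["end"] = df["end"].astype(int)
    if (df["end"] < df["start"]).any():
        raise ValidationError(f"{path}: empty or inverted BED interval")
    return df[BED6_COLUMNS]


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out = out[BED6_COLUMNS].sort_values(["chrom", "start", "end", "name"], kind="mergesort")
    out["start"] = out["start"].astype(int) - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph-like TSV (chrom, start0, end, score) -> 1-based closed table."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "score"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    if (df["end"] < df["start"]).any():
        raise ValidationError(f"{path}: empty or inverted bedGraph interval")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "score"]].sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).copy()
    out["start"] = out["start"].astype(int) - 1
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def sum_tracks(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Base-wise sum of several coverage tracks (1-based closed tables).

    Used to pool alpha and beta replicate coverage into a single
    meta-experiment before segmentation.
    """
    events: dict[str, list[tuple[int, float]]] = {}
    for track in tracks:
        for chrom, s, e, v in track[["chrom", "start", "end", "score"]].itertuples(index=False):
            events.setdefault(chrom, []).append((int(s), float(v)))
            events[chrom].append((int(e) + 1, -float(v)))
    rows = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        level = 0.0
        prev = None
        for pos, delta in pts:
            if prev is not None and pos > prev and abs(level) > 1e-12:
                rows.append((chrom, prev, pos - 1, level))
            level += delta
            prev = pos
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


# ---------------------------------------------------------------------------
# counts / ortholog / block-map / peak tables
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Counts TSV: gene_id column plus one integer column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.sort_index().to_csv(path, sep="\t", index_label="gene_id")


def read_orthologs(path, species1: str = "species1", species2: str = "species2") -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog table needs two columns")
    pairs = list(df.iloc[:, :2].itertuples(index=False, name=None))
    return OrthologMap(pairs=pairs, species1=species1, species2=species2)


def write_orthologs(omap: OrthologMap, path) -> None:
    pd.DataFrame(sorted(omap.pairs), columns=[omap.species1, omap.species2]).to_csv(
        path, sep="\t", index=False
    )


BLOCKMAP_COLUMNS = [
    "src_chrom", "src_start", "src_end",
    "dst_chrom", "dst_start", "dst_end", "dst_strand",
]


def read_block_map(path, src_genome: str = "src", dst_genome: str = "dst") -> BlockMap:
    df = pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "dst_chrom": str})
    missing = set(BLOCKMAP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: block map missing columns {sorted(missing)}")
    blocks = [Block(**row._asdict()) for row in df[BLOCKMAP_COLUMNS].itertuples(index=False)]
    return BlockMap(blocks, src_genome=src_genome, dst_genome=dst_genome)


def write_block_map(bmap: BlockMap, path) -> None:
    rows = [
        (b.src_chrom, b.src_start, b.src_end, b.dst_chrom, b.dst_start, b.dst_end, b.dst_strand)
        for b in sorted(bmap.blocks, key=lambda b: (b.src_chrom, b.src_start))
    ]
    pd.DataFrame(rows, columns=BLOCKMAP_COLUMNS).to_csv(path, sep="\t", index=False)


PEAK_COLUMNS = ["chrom", "start", "end", "name", "reads"]


def read_peaks(path, tf_name: str = "TF", genome_id: str = "genome") -> PeakSet:
    """Peak TSV with header (chrom, start, end, name, reads), 1-based closed."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str})
    return PeakSet(peaks=df[PEAK_COLUMNS], tf_name=tf_name, genome_id=genome_id)


def write_peaks(peaks: PeakSet, path) -> None:
    peaks.peaks[PEAK_COLUMNS].sort_values(
        ["chrom", "start", "end", "name"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# cross-genome interval conversion
# ---------------------------------------------------------------------------

def convert_interval(
    iv: tuple[str, int, int],
    bmap: BlockMap,
    min_fraction: float = 0.5,
) -> Optional[MappedInterval]:
    """Convert a closed interval through a block map (liftOver-style).

    Returns the destination span covering all mapped bases when at least
    ``min_fraction`` of the interval's bases fall inside blocks and all
    touched blocks agree on destination chromosome and strand; otherwise
    ``None`` (the interval is unmapped — a value, not an error).
    """
    chrom, start, end = iv
    if end < start:
        raise ValidationError(f"invalid interval ({start}, {end})")
    length = end - start + 1
    pieces = []
    for b in bmap.blocks:
        if b.src_chrom != chrom:
            continue
        lo, hi = max(start, b.src_start), min(end, b.src_end)
        if lo > hi:
            continue
        if b.dst_strand == "+":
            d_lo = b.dst_start + (lo - b.src_start)
            d_hi = b.dst_start + (hi - b.src_start)
        else:
            d_hi = b.dst_end - (lo - b.src_start)
            d_lo = b.dst_end - (hi - b.src_start)
        pieces.append((b.dst_chrom, d_lo, d_hi, b.dst_strand, hi - lo + 1))
    mapped = sum(p[4] for p in pieces)
    if mapped / length < min_fraction or not pieces:
        return None
    chroms = {p[0] for p in pieces}
    strands = {p[3] for p in pieces}
    if len(chroms) > 1 or len(strands) > 1:
        return None  # split across chromosomes or inverted segments
    return MappedInterval(
        chrom=pieces[0][0],
        start=min(p[1] for p in pieces),
        end=max(p[2] for p in pieces),
        strand=pieces[0][3],
    )
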