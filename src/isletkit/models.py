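"""Core domain types: gene models, genome annotations, block maps, peak sets.

Coordinates are 1-based and closed everywhere in memory (the GTF
convention); conversions for 0-based half-open formats happen in
:mod:`isletkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

import pandas as pd

from .intervals import IntervalIndex, merge_intervals, union_length

VALID_STRANDS = ("+", "-")
BIOTYPES = ("protein_coding", "rRNA", "other")


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure in one genome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene has no exons")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        for s, e in self.exons:
            if s < 1 or e < s:
                raise ValidationError(f"{self.gene_id}: invalid exon ({s}, {e})")
        object.__setattr__(self, "exons", tuple(sorted(self.exons)))

    @cached_property
    def merged_exons(self) -> tuple[tuple[int, int], ...]:
        return tuple(merge_intervals(self.exons))

    @cached_property
    def merged_exon_length(self) -> int:
        """Length of the exon model: base count of the union of all exons."""
        return union_length(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Gene-body span from first exon start to last exon end."""
        return (self.exons[0][0], max(e for _, e in self.exons))


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel]
    genome_id: str = "genome"
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if self.chrom_sizes:
                size = self.chrom_sizes.get(g.chrom)
                if size is None:
                    raise ValidationError(f"{g.gene_id}: chrom {g.chrom!r} not in chrom_sizes")
                if g.span[1] > size:
                    raise ValidationError(
                        f"{g.gene_id}: exon ends at {g.span[1]} beyond {g.chrom} length {size}"
                    )

    @cached_property
    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def exon_index(self, biotypes: Optional[Iterable[str]] = None) -> IntervalIndex:
        keep = set(biotypes) if biotypes is not None else None
        idx = IntervalIndex()
        for g in self.genes:
            if keep is not None and g.biotype not in keep:
                continue
            for s, e in g.merged_exons:
                idx.add(g.chrom, s, e, g.gene_id)
        return idx

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Block:
    """One colinear alignment block between two genomes (equal-length spans)."""

    src_chrom: str
    src_start: int
    src_end: int
    dst_chrom: str
    dst_start: int
    dst_end: int
    dst_strand: str

    def __post_init__(self) -> None:
        if self.dst_strand not in VALID_STRANDS:
            raise ValidationError(f"block strand must be + or -, got {self.dst_strand!r}")
        src_len = self.src_end - self.src_start + 1
        dst_len = self.dst_end - self.dst_start + 1
        if src_len < 1:
            raise ValidationError("block src span empty")
        if src_len != dst_len:
            raise ValidationError(
                f"block src span ({src_len} bp) != dst span ({dst_len} bp)"
            )


@dataclass
class BlockMap:
    """liftOver-style coordinate map between two genome assemblies."""

    blocks: list[Block]
    src_genome: str = "src"
    dst_genome: str = "dst"

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Block]] = {}
        for b in self.blocks:
            by_chrom.setdefault(b.src_chrom, []).append(b)
        for chrom, blocks in by_chrom.items():
            blocks = sorted(blocks, key=lambda b: b.src_start)
            for a, b in zip(blocks, blocks[1:]):
                if b.src_start <= a.src_end:
                    raise ValidationError(
                        f"overlapping src blocks on {chrom}: "
                        f"({a.src_start},{a.src_end}) and ({b.src_start},{b.src_end})"
                    )

    def inverted(self) -> "BlockMap":
        """Map in the opposite direction (dst coordinates become src)."""
        inv = []
        for b in self.blocks:
            inv.append(
                Block(
                    src_chrom=b.dst_chrom,
                    src_start=b.dst_start,
                    src_end=b.dst_end,
                    dst_chrom=b.src_chrom,
                    dst_start=b.src_start,
                    dst_end=b.src_end,
                    dst_strand=b.dst_strand,
                )
            )
        return BlockMap(inv, src_genome=self.dst_genome, dst_genome=self.src_genome)


@dataclass(frozen=True)
class MappedInterval:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class OrthologMap:
    """Gene-identifier correspondence between two species (Homologene-style)."""

    pairs: list[tuple[str, str]]
    species1: str = "species1"
    species2: str = "species2"

    def one_to_one(self) -> "OrthologMap":
        """Drop every identifier involved in more than one pair."""
        from collections import Counter

        c1 = Counter(a for a, _ in self.pairs)
        c2 = Counter(b for _, b in self.pairs)
        kept = [(a, b) for a, b in self.pairs if c1[a] == 1 and c2[b] == 1]
        return OrthologMap(kept, self.species1, self.species2)


@dataclass
class PeakSet:
    """TF ChIP peaks with per-peak read counts.

    ``peaks`` columns: chrom, start, end (1-based closed), name, reads.
    """

    peaks: pd.DataFrame
    tf_name: str = "TF"
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "name", "reads"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValidationError(f"peak table missing columns: {sorted(missing)}")
        if (self.peaks["reads"] < 0).any():
            raise ValidationError("peak read counts must be non-negative")
        if (self.peaks["end"] < self.peaks["start"]).any():
            raise ValidationError("peak end < start")

    @property
    def total_reads(self) -> float:
        return float(self.peaks["reads"].sum())
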