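"""Core genomic domain types shared across the package.

All coordinates are 0-based half-open on the forward genome strand,
regardless of gene orientation.  GTF input/output converts at the
boundary; BED-style intervals pass through natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

STRANDS = ("+", "-")

#: Junction records shorter than this are rejected as indel artifacts.
MIN_INTRON_LENGTH = 30


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping nucleotides (strand-blind)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval", strict: bool = False) -> bool:
        """Whether ``other`` lies within this interval.

        With ``strict`` the containment must leave at least one
        nucleotide of margin on both sides.
        """
        if self.chrom != other.chrom:
            return False
        if strict:
            return self.start < other.start and other.end < self.end
        return self.start <= other.start and other.end <= self.end

    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction (the intron interval) in one sample.

    ``unique_count``/``multi_count`` are uniquely- and multi-mapped
    read-pair counts supporting the junction.
    """

    interval: GenomicInterval
    sample_id: str
    unique_count: int
    multi_count: int = 0

    def __post_init__(self) -> None:
        if self.unique_count < 0 or self.multi_count < 0:
            raise ValueError("junction read counts must be non-negative")
        if self.interval.length < MIN_INTRON_LENGTH:
            raise ValueError(
                f"junction {self.interval} shorter than minimum intron "
                f"length {MIN_INTRON_LENGTH}"
            )


@dataclass
class GeneModel:
    """A gene with its transcripts' exon structures and derived introns."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    span: GenomicInterval
    #: transcript_id -> exons sorted by genomic start
    transcripts: dict[str, tuple[GenomicInterval, ...]] = field(default_factory=dict)

    @property
    def tss(self) -> int:
        """Transcription start site: span start on +, span end − 1 on −."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    def introns_of(self, transcript_id: str) -> tuple[GenomicInterval, ...]:
        exons = self.transcripts[transcript_id]
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
        )

    def all_introns(self) -> set[GenomicInterval]:
        out: set[GenomicInterval] = set()
        for tid in self.transcripts:
            out.update(self.introns_of(tid))
        return out

    def exon_starts(self) -> set[int]:
        return {e.start for exons in self.transcripts.values() for e in exons}

    def exon_ends(self) -> set[int]:
        return {e.end for exons in self.transcripts.values() for e in exons}


class JunctionCatalog:
    """The annotated splice-junction set, exact-match on all four fields."""

    def __init__(self, genes: Mapping[str, GeneModel]):
        self._keys: set[tuple[str, int, int, str]] = set()
        self._by_gene: dict[str, set[GenomicInterval]] = {}
        for gene in genes.values():
            introns = gene.all_introns()
            self._by_gene[gene.gene_id] = introns
            self._keys.update(i.key() for i in introns)

    def __contains__(self, interval: GenomicInterval) -> bool:
        return interval.key() in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(sorted(self._keys))

    def of_gene(self, gene_id: str) -> set[GenomicInterval]:
        return self._by_gene.get(gene_id, set())


@dataclass
class AnnotationBundle:
    """Parsed annotation: gene models plus the junction catalog."""

    genes: dict[str, GeneModel]
    catalog: JunctionCatalog

    def gene_of_interval(self, interval: GenomicInterval) -> GeneModel | None:
        """Host gene whose span contains the interval (same strand)."""
        for gene in self.genes.values():
            if gene.strand == interval.strand and gene.span.contains(interval):
                return gene
        return None

    def annotated_introns(self) -> list[tuple[str, GenomicInterval]]:
        """(gene_id, intron) pairs for every annotated intron, sorted."""
        out = []
        for gene_id in sorted(self.genes):
            for intron in sorted(self.catalog.of_gene(gene_id)):
                out.append((gene_id, intron))
        return out
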