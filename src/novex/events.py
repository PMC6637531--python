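"""Exonization-event record types and the six-criterion verdict."""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import GenomicInterval

#: Criterion ids, in the order they are reported.
CRITERIA = (
    "reads>=5",
    "CE-event",
    "absent-in-controls",
    "not-annotated",
    "PSI>=0.05",
    "EEJ-links-novel-to-known",
)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of one acceptance criterion for a candidate event."""

    criterion: str
    passed: bool
    detail: str = ""

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class RepeatOverlap:
    """Best repeat element overlapping a novel exon (>= 20% of its length)."""

    family: str
    repeat_class: str
    overlap_fraction: float


@dataclass
class ExonizationEvent:
    """A candidate novel internal (cassette) exon with its evidence.

    ``i_up``/``i_down`` are inclusion junction reads at the upstream and
    downstream novel junctions; ``e`` is the exclusion (host-intron)
    junction count.  ``psi`` is the percent-spliced-in estimate
    m/(m+e) with m = (i_up + i_down)/2, or None when undefined.
    """

    gene_id: str
    host_intron: GenomicInterval
    novel_exon: GenomicInterval
    upstream_junction: GenomicInterval
    downstream_junction: GenomicInterval
    i_up: int
    i_down: int
    e: int
    psi: float | None = None
    verdicts: dict[str, FilterVerdict] = field(default_factory=dict)
    repeat_overlap: RepeatOverlap | None = None

    def __post_init__(self) -> None:
        if min(self.i_up, self.i_down, self.e) < 0:
            raise ValueError("junction counts must be non-negative")
        if not self.host_intron.contains(self.novel_exon, strict=True):
            raise ValueError(
                f"novel exon {self.novel_exon} not strictly inside host "
                f"intron {self.host_intron}"
            )

    @property
    def accepted(self) -> bool:
        return len(self.verdicts) == len(CRITERIA) and all(
            v.passed for v in self.verdicts.values()
        )

    @property
    def event_id(self) -> str:
        ne = self.novel_exon
        return f"{self.gene_id}:{ne.chrom}:{ne.start}-{ne.end}:{ne.strand}"
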