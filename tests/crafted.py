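"""Hand-built annotation and candidates that each violate exactly one
of the six acceptance criteria (shared by unit and acceptance tests)."""

from __future__ import annotations

from novex.events import ExonizationEvent
from novex.types import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    JunctionCatalog,
    JunctionRecord,
)


def toy_annotation() -> AnnotationBundle:
    """Gene gA: exons [100,200) [500,600) [900,1000); gene gB (overlapping
    coordinates, same strand) provides the annotated junction used by the
    criterion-4 candidate."""
    chrom = "chrT"
    ga = GeneModel(
        "gA", "GA", chrom, "+", GenomicInterval(chrom, 100, 1000, "+"),
        transcripts={
            "tA": (
                GenomicInterval(chrom, 100, 200, "+"),
                GenomicInterval(chrom, 500, 600, "+"),
                GenomicInterval(chrom, 900, 1000, "+"),
            )
        },
    )
    gb = GeneModel(
        "gB", "GB", chrom, "+", GenomicInterval(chrom, 440, 520, "+"),
        transcripts={
            "tB": (
                GenomicInterval(chrom, 440, 460, "+"),
                GenomicInterval(chrom, 500, 520, "+"),
            )
        },
    )
    genes = {"gA": ga, "gB": gb}
    return AnnotationBundle(genes=genes, catalog=JunctionCatalog(genes))


def _event(host, exon, up, down, i_up, i_down, e):
    chrom = "chrT"
    return ExonizationEvent(
        gene_id="gA",
        host_intron=GenomicInterval(chrom, *host, "+"),
        novel_exon=GenomicInterval(chrom, *exon, "+"),
        upstream_junction=GenomicInterval(chrom, *up, "+"),
        downstream_junction=GenomicInterval(chrom, *down, "+"),
        i_up=i_up,
        i_down=i_down,
        e=e,
        psi=None,
    )


def crafted_candidates() -> dict[str, ExonizationEvent]:
    """One candidate per criterion; each fails only that criterion.

    Host intron (200, 500) of gA is annotated; the standard geometry is
    novel exon [300, 400) with flanking junctions (200, 300)/(400, 500)
    replaced per scenario.
    """
    from novex.exonization import compute_psi

    candidates = {
        # (1) only 4 supporting inclusion reads
        "reads>=5": _event((200, 500), (300, 400), (200, 300), (400, 500), 2, 2, 2),
        # (2) host interval spans two annotated introns -> not a cassette
        "CE-event": _event((200, 900), (380, 420), (200, 380), (420, 900), 10, 10, 10),
        # (3) a control sample carries one read at the upstream junction
        # (junctions unique to this candidate so one control set serves all)
        "absent-in-controls": _event(
            (200, 500), (320, 380), (200, 320), (380, 500), 10, 10, 10
        ),
        # (4) downstream junction (460, 500) is annotated (gene gB intron)
        "not-annotated": _event(
            (200, 500), (300, 460), (200, 300), (460, 500), 10, 10, 10
        ),
        # (5) PSI = 25/(25+600) = 0.04 despite 50 supporting reads
        "PSI>=0.05": _event((200, 500), (290, 410), (200, 290), (410, 500), 25, 25, 600),
        # (6) upstream junction starts inside the intron, not at a known
        # exon boundary
        "EEJ-links-novel-to-known": _event(
            (200, 500), (310, 390), (210, 310), (390, 500), 10, 10, 10
        ),
    }
    for ev in candidates.values():
        ev.psi = compute_psi(ev.i_up, ev.i_down, ev.e)
    return candidates


def control_leak() -> dict[str, list[JunctionRecord]]:
    """A single control read at the criterion-3 candidate's upstream
    junction."""
    return {
        "ctrl_1": [
            JunctionRecord(GenomicInterval("chrT", 200, 320, "+"), "ctrl_1", 1)
        ]
    }
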