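"""Novel cassette-exon (exonization) calling from splice-junction evidence.

A candidate is a pair of unannotated junctions that subdivide one
annotated host intron, linking a putative novel internal exon to the
flanking annotated exons.  Candidates are screened by six criteria:

1. inclusion support: i_up + i_down >= 5 with both junctions observed;
2. the event is a cassette (core exon) inside a single annotated intron;
3. neither flanking junction carries any read in any control sample;
4. neither flanking junction is itself annotated;
5. percent spliced in (PSI) >= 0.05;
6. each flanking junction joins the novel exon to a known exon boundary.

PSI is estimated junction-only as m/(m+e) with m = (i_up + i_down)/2
and e the exclusion (host-intron) junction count.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import ExonizationEvent, FilterVerdict, RepeatOverlap
from .types import AnnotationBundle, GenomicInterval, JunctionRecord

JunctionsBySample = Mapping[str, Sequence[JunctionRecord]]


def compute_psi(i_up: int, i_down: int, e: int) -> float | None:
    """PSI = m/(m+e), m = (i_up + i_down)/2; None when no evidence."""
    if min(i_up, i_down, e) < 0:
        raise ValueError("junction counts must be non-negative")
    m = (i_up + i_down) / 2.0
    if m + e == 0:
        return None
    return m / (m + e)


def aggregate_counts(
    junctions: JunctionsBySample,
) -> dict[tuple[str, int, int, str], int]:
    """Sum uniquely-mapped junction reads across samples (order-free)."""
    counts: dict[tuple[str, int, int, str], int] = defaultdict(int)
    for records in junctions.values():
        for rec in records:
            counts[rec.interval.key()] += rec.unique_count
    return dict(counts)


def enumerate_candidates(
    junctions: JunctionsBySample, annotation: AnnotationBundle
) -> list[ExonizationEvent]:
    """Form candidate events from paired unannotated junctions.

    Within an annotated host intron (A_end, B_start) of a gene, an
    unannotated junction J1 = (A_end, x) paired with an unannotated
    J2 = (y, B_start), x < y, defines the candidate novel exon [x, y).
    Candidates are deduplicated across samples by coordinates.
    """
    counts = aggregate_counts(junctions)
    novel = {k: c for k, c in counts.items() if _as_interval(k) not in annotation.catalog}

    by_start: dict[tuple[str, str, int], list[tuple[int, int]]] = defaultdict(list)
    by_end: dict[tuple[str, str, int], list[tuple[int, int]]] = defaultdict(list)
    for (chrom, start, end, strand), c in novel.items():
        by_start[(chrom, strand, start)].append((end, c))
        by_end[(chrom, strand, end)].append((start, c))

    candidates: dict[tuple, ExonizationEvent] = {}
    for gene_id, intron in annotation.annotated_introns():
        ups = [
            (x, c)
            for x, c in by_start[(intron.chrom, intron.strand, intron.start)]
            if intron.start < x < intron.end
        ]
        downs = [
            (y, c)
            for y, c in by_end[(intron.chrom, intron.strand, intron.end)]
            if intron.start < y < intron.end
        ]
        for x, c_up in ups:
            for y, c_down in downs:
                if x >= y:
                    continue
                exon = GenomicInterval(intron.chrom, x, y, intron.strand)
                ckey = (gene_id, intron.key(), exon.key())
                if ckey in candidates:
                    continue
                e_count = counts.get(intron.key(), 0)
                candidates[ckey] = ExonizationEvent(
                    gene_id=gene_id,
                    host_intron=intron,
                    novel_exon=exon,
                    upstream_junction=GenomicInterval(
                        intron.chrom, intron.start, x, intron.strand
                    ),
                    downstream_junction=GenomicInterval(
                        intron.chrom, y, intron.end, intron.strand
                    ),
                    i_up=c_up,
                    i_down=c_down,
                    e=e_count,
                    psi=compute_psi(c_up, c_down, e_count),
                )
    return [candidates[k] for k in sorted(candidates)]


def _as_interval(key: tuple[str, int, int, str]) -> GenomicInterval:
    return GenomicInterval(*key)


def apply_filters(
    candidates: Iterable[ExonizationEvent],
    control_junctions: JunctionsBySample,
    annotation: AnnotationBundle,
    min_reads: int = 5,
    min_psi: float = 0.05,
) -> tuple[list[ExonizationEvent], list[ExonizationEvent]]:
    """Apply the six criteria; returns (accepted, all-with-verdicts).

    Rejection is data: every candidate comes back carrying a complete
    per-criterion verdict record.
    """
    control_counts = aggregate_counts(control_junctions)
    out: list[ExonizationEvent] = []
    for ev in candidates:
        gene = annotation.genes.get(ev.gene_id)
        v: dict[str, FilterVerdict] = {}

        support = ev.i_up + ev.i_down
        ok1 = support >= min_reads and ev.i_up >= 1 and ev.i_down >= 1
        v["reads>=5"] = FilterVerdict(
            "reads>=5", ok1, f"i_up={ev.i_up}, i_down={ev.i_down}, sum={support}"
        )

        in_catalog = ev.host_intron in annotation.catalog
        cassette = in_catalog and ev.host_intron.contains(ev.novel_exon, strict=True)
        if cassette and gene is not None:
            for exons in gene.transcripts.values():
                if any(ev.novel_exon.overlap(x) > 0 for x in exons):
                    cassette = False
                    break
        v["CE-event"] = FilterVerdict(
            "CE-event",
            cassette,
            "cassette within one annotated host intron"
            if cassette
            else "not a cassette within a single annotated intron",
        )

        leak = control_counts.get(
            ev.upstream_junction.key(), 0
        ) + control_counts.get(ev.downstream_junction.key(), 0)
        v["absent-in-controls"] = FilterVerdict(
            "absent-in-controls", leak == 0, f"control reads at flanking junctions: {leak}"
        )

        annotated = (
            ev.upstream_junction in annotation.catalog
            or ev.downstream_junction in annotation.catalog
        )
        v["not-annotated"] = FilterVerdict(
            "not-annotated",
            not annotated,
            "a flanking junction is annotated" if annotated else "both junctions novel",
        )

        ok5 = ev.psi is not None and ev.psi >= min_psi
        v["PSI>=0.05"] = FilterVerdict(
            "PSI>=0.05", ok5, f"psi={'NA' if ev.psi is None else round(ev.psi, 4)}"
        )

        anchored = (
            gene is not None
            and ev.upstream_junction.start in gene.exon_ends()
            and ev.downstream_junction.end in gene.exon_starts()
        )
        v["EEJ-links-novel-to-known"] = FilterVerdict(
            "EEJ-links-novel-to-known",
            anchored,
            "junctions anchor to annotated exon boundaries"
            if anchored
            else "a junction does not anchor to a known exon boundary",
        )

        ev.verdicts = v
        out.append(ev)
    accepted = [ev for ev in out if ev.accepted]
    return accepted, out


def classify_repeat_overlap(
    event: ExonizationEvent,
    repeats: Sequence[tuple[GenomicInterval, str]],
    min_fraction: float = 0.2,
) -> ExonizationEvent:
    """Annotate the event with the repeat covering >= 20% of the novel
    exon (largest overlap wins; ties broken alphabetically by family);
    families whose name contains "Alu" are grouped into class "Alu"."""
    exon = event.novel_exon
    best: tuple[int, str] | None = None
    for interval, family in repeats:
        ov = exon.overlap(interval)
        if ov / exon.length >= min_fraction:
            cand = (ov, family)
            if best is None or ov > best[0] or (ov == best[0] and family < best[1]):
                best = cand
    if best is None:
        event.repeat_overlap = None
    else:
        ov, family = best
        repeat_class = "Alu" if "Alu" in family else family
        event.repeat_overlap = RepeatOverlap(family, repeat_class, ov / exon.length)
    return event


def call_events(
    perturbed: JunctionsBySample,
    controls: JunctionsBySample,
    annotation: AnnotationBundle,
    repeats: Sequence[tuple[GenomicInterval, str]] = (),
    min_reads: int = 5,
    min_psi: float = 0.05,
    overlap_fraction: float = 0.2,
) -> tuple[list[ExonizationEvent], list[ExonizationEvent]]:
    """Full calling pipeline: enumerate, filter, classify repeats.

    Returns (accepted events, all candidates with verdicts).
    """
    candidates = enumerate_candidates(perturbed, annotation)
    accepted, everything = apply_filters(
        candidates, controls, annotation, min_reads=min_reads, min_psi=min_psi
    )
    for ev in everything:
        classify_repeat_overlap(ev, repeats, min_fraction=overlap_fraction)
    return accepted, everything


def _thin(
    junctions: JunctionsBySample, p: float, rng: np.random.Generator
) -> dict[str, list[JunctionRecord]]:
    out: dict[str, list[JunctionRecord]] = {}
    for sample in sorted(junctions):
        thinned = []
        for rec in junctions[sample]:
            u = int(rng.binomial(rec.unique_count, p)) if p < 1.0 else rec.unique_count
            m = int(rng.binomial(rec.multi_count, p)) if p < 1.0 else rec.multi_count
            if u + m > 0:
                thinned.append(JunctionRecord(rec.interval, sample, u, m))
        out[sample] = thinned
    return out


def saturation_curve(
    perturbed: JunctionsBySample,
    controls: JunctionsBySample,
    annotation: AnnotationBundle,
    repeats: Sequence[tuple[GenomicInterval, str]],
    fractions: Sequence[float],
    seed: int = 0,
    repeat_class: str | None = "Alu",
    **call_kwargs,
) -> pd.DataFrame:
    """Read-depth saturation: binomially subsample junction reads at each
    fraction, re-run the caller, and report the percentage of
    full-depth reference events (optionally restricted to one repeat
    class, Alu by default) that are recovered."""
    for p in fractions:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"subsampling fraction {p} outside (0, 1]")
    reference, _ = call_events(perturbed, controls, annotation, repeats, **call_kwargs)
    if repeat_class is not None:
        reference = [
            ev
            for ev in reference
            if ev.repeat_overlap is not None
            and ev.repeat_overlap.repeat_class == repeat_class
        ]
    ref_keys = {ev.novel_exon.key() for ev in reference}
    rows = []
    for k, p in enumerate(fractions):
        rng = np.random.default_rng([seed, k])
        accepted, _ = call_events(
            _thin(perturbed, p, rng), _thin(controls, p, rng), annotation, repeats,
            **call_kwargs,
        )
        got = {ev.novel_exon.key() for ev in accepted}
        if repeat_class is not None:
            got = {
                ev.novel_exon.key()
                for ev in accepted
                if ev.repeat_overlap is not None
                and ev.repeat_overlap.repeat_class == repeat_class
            }
        pct = 100.0 * len(got & ref_keys) / len(ref_keys) if ref_keys else float("nan")
        rows.append(dict(fraction=p, percent_detected=pct, n_reference=len(ref_keys)))
    return pd.DataFrame(rows)
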