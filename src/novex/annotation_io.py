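"""Annotation and junction-table I/O.

Reads Ensembl-dialect GTF (1-based inclusive) into 0-based half-open
gene models, derives per-transcript introns and the annotated-junction
catalog, reads STAR-style splice-junction tables, and round-trips
exonization events through BED12 + TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .events import CRITERIA, ExonizationEvent, FilterVerdict, RepeatOverlap
from .types import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    JunctionCatalog,
    JunctionRecord,
    MIN_INTRON_LENGTH,
)


class GtfParseError(ValueError):
    pass


def _prevalidate_gtf(path: str | Path) -> None:
    """Cheap line-level validation so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            feature, attrs = fields[2], fields[8]
            if "gene_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature in ("transcript", "exon") and "transcript_id" not in attrs:
                raise GtfParseError(f"{path}:{lineno}: missing transcript_id attribute")


def parse_gtf(gtf_path: str | Path, fasta_path: str | Path | None = None) -> AnnotationBundle:
    """Parse a GTF (and optionally validate against a FASTA) into a bundle.

    Coordinates are converted from GTF's 1-based inclusive convention to
    the internal 0-based half-open one.  When ``fasta_path`` is given,
    every exon must lie within its chromosome's bounds.
    """
    _prevalidate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    chrom_sizes: dict[str, int] = {}
    if fasta_path is not None:
        fa = Fasta(str(fasta_path))
        chrom_sizes = {name: len(fa[name]) for name in fa.keys()}

    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        name = (g.attributes.get("gene_name") or [g.id])[0]
        model = GeneModel(g.id, name, g.seqid, g.strand, span)
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = tuple(
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            if not exons:
                continue
            for e in exons:
                if not span.contains(e):
                    raise GtfParseError(f"exon {e} outside gene span of {g.id}")
                if chrom_sizes and e.end > chrom_sizes.get(e.chrom, 0):
                    raise GtfParseError(
                        f"exon {e} outside chromosome bounds "
                        f"({e.chrom} has {chrom_sizes.get(e.chrom, 0)} nt)"
                    )
            model.transcripts[t.id] = exons
        genes[g.id] = model

    return AnnotationBundle(genes=genes, catalog=JunctionCatalog(genes))


def write_gtf(bundle: AnnotationBundle, path: str | Path, source: str = "novex") -> None:
    """Export the bundle back to GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene_id in sorted(bundle.genes):
            g = bundle.genes[gene_id]
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid in sorted(g.transcripts):
                exons = g.transcripts[tid]
                tattrs = attrs + f' transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{exons[0].start + 1}\t{exons[-1].end}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for e in exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


_STRAND_CODES = {"0": None, "1": "+", "2": "-", "+": "+", "-": "-", ".": None}


def read_junction_table(
    path: str | Path,
    sample_id: str,
    annotation: AnnotationBundle | None = None,
) -> list[JunctionRecord]:
    """Read a STAR SJ.out.tab-style junction table for one sample.

    Columns (tab-separated, no header): chrom, intron start, intron end
    (both 1-based inclusive), strand (0/1/2 or +/−/.), unique-read
    count, multimapped-read count.  Zero-count rows are dropped.
    Unstranded rows inherit the strand of the host gene when an
    annotation bundle is supplied.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start1, end1 = int(fields[1]), int(fields[2])
                unique, multi = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if fields[3] not in _STRAND_CODES:
                raise ValueError(f"{path}:{lineno}: unknown strand code {fields[3]!r}")
            strand = _STRAND_CODES[fields[3]]
            if unique + multi == 0:
                continue
            start, end = start1 - 1, end1  # to 0-based half-open
            if strand is None:
                strand = _infer_strand(chrom, start, end, annotation)
                if strand is None:
                    raise ValueError(
                        f"{path}:{lineno}: unstranded junction with no host gene "
                        "to inherit strand from"
                    )
            interval = GenomicInterval(chrom, start, end, strand)
            if interval.length < MIN_INTRON_LENGTH:
                raise ValueError(
                    f"{path}:{lineno}: junction shorter than {MIN_INTRON_LENGTH} nt"
                )
            records.append(JunctionRecord(interval, sample_id, unique, multi))
    return records


def _infer_strand(chrom: str, start: int, end: int, annotation: AnnotationBundle | None) -> str | None:
    if annotation is None:
        return None
    for strand in ("+", "-"):
        gene = annotation.gene_of_interval(GenomicInterval(chrom, start, end, strand))
        if gene is not None:
            return gene.strand
    return None


# ---------------------------------------------------------------------------
# event output

_TSV_COLUMNS = [
    "event_id", "gene_id", "chrom", "strand",
    "host_intron_start", "host_intron_end", "exon_start", "exon_end",
    "up_junction_start", "up_junction_end",
    "down_junction_start", "down_junction_end",
    "i_up", "i_down", "e", "psi", "accepted",
    "repeat_family", "repeat_class", "repeat_overlap_fraction",
] + [f"pass_{c}" for c in CRITERIA] + ["verdict_details"]


def write_events(
    events: list[ExonizationEvent], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write events as BED12 (novel exon as the middle block) plus a TSV
    that round-trips losslessly through :func:`read_events`."""
    rows = []
    with open(bed_path, "w") as bed:
        for ev in sorted(events, key=lambda e: e.novel_exon.key()):
            ne, up, down = ev.novel_exon, ev.upstream_junction, ev.downstream_junction
            chrom_start, chrom_end = up.start - 1, down.end + 1
            score = 0 if ev.psi is None else int(round(1000 * ev.psi))
            block_sizes = f"1,{ne.length},1"
            block_starts = f"0,{ne.start - chrom_start},{chrom_end - 1 - chrom_start}"
            bed.write(
                "\t".join(
                    str(x)
                    for x in (
                        ne.chrom, chrom_start, chrom_end, ev.event_id, score,
                        ne.strand, ne.start, ne.end, "0,0,0", 3,
                        block_sizes, block_starts,
                    )
                )
                + "\n"
            )
            row = {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "chrom": ne.chrom,
                "strand": ne.strand,
                "host_intron_start": ev.host_intron.start,
                "host_intron_end": ev.host_intron.end,
                "exon_start": ne.start,
                "exon_end": ne.end,
                "up_junction_start": up.start,
                "up_junction_end": up.end,
                "down_junction_start": down.start,
                "down_junction_end": down.end,
                "i_up": ev.i_up,
                "i_down": ev.i_down,
                "e": ev.e,
                "psi": "NA" if ev.psi is None else repr(ev.psi),
                "accepted": int(ev.accepted),
                "repeat_family": ev.repeat_overlap.family if ev.repeat_overlap else "NA",
                "repeat_class": ev.repeat_overlap.repeat_class if ev.repeat_overlap else "NA",
                "repeat_overlap_fraction": (
                    repr(ev.repeat_overlap.overlap_fraction) if ev.repeat_overlap else "NA"
                ),
            }
            for c in CRITERIA:
                row[f"pass_{c}"] = (
                    int(ev.verdicts[c].passed) if c in ev.verdicts else "NA"
                )
            row["verdict_details"] = json.dumps(
                {c: v.detail for c, v in sorted(ev.verdicts.items())}, sort_keys=True
            )
            rows.append(row)
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)


def read_events(tsv_path: str | Path) -> list[ExonizationEvent]:
    """Read back events written by :func:`write_events`."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    events = []
    for _, r in df.iterrows():
        chrom, strand = r["chrom"], r["strand"]
        verd_details = json.loads(r["verdict_details"])
        verdicts = {}
        for c in CRITERIA:
            cell = r[f"pass_{c}"]
            if cell != "NA":
                verdicts[c] = FilterVerdict(c, bool(int(cell)), verd_details.get(c, ""))
        rep = None
        if r["repeat_family"] != "NA":
            rep = RepeatOverlap(
                r["repeat_family"], r["repeat_class"], float(r["repeat_overlap_fraction"])
            )
        events.append(
            ExonizationEvent(
                gene_id=r["gene_id"],
                host_intron=GenomicInterval(
                    chrom, int(r["host_intron_start"]), int(r["host_intron_end"]), strand
                ),
                novel_exon=GenomicInterval(
                    chrom, int(r["exon_start"]), int(r["exon_end"]), strand
                ),
                upstream_junction=GenomicInterval(
                    chrom, int(r["up_junction_start"]), int(r["up_junction_end"]), strand
                ),
                downstream_junction=GenomicInterval(
                    chrom, int(r["down_junction_start"]), int(r["down_junction_end"]), strand
                ),
                i_up=int(r["i_up"]),
                i_down=int(r["i_down"]),
                e=int(r["e"]),
                psi=None if r["psi"] == "NA" else float(r["psi"]),
                verdicts=verdicts,
                repeat_overlap=rep,
            )
        )
    return events


def read_repeats(bed_path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a RepeatMasker-style BED6 into (interval, family) pairs."""
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{bed_path}:{lineno}: BED needs >=4 columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "+"
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), f[3]))
    return out


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a two-column gene_id → TPM table (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] is not None:
        try:
            float(df.iloc[0, 1])
        except ValueError:
            df = df.iloc[1:]
    return {str(g): float(t) for g, t in zip(df.iloc[:, 0], df.iloc[:, 1])}
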