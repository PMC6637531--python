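"""Synthetic fixture-bundle generator with full ground truth.

Builds a toy genome of multi-exon genes whose designated host introns
are long and GC-rich and carry Alu-like repeat copies; novel cassette
exons are planted inside host introns with known inclusion levels ψ*,
and every downstream stage (junction counts for control/perturbed
samples, pulse-chase time-course counts, multimapped reads over repeat
copies, expression tables) is emitted together with a manifest that
records the truth.

Two count modes are supported: ``exact`` writes deterministic rounded
counts so recovery tests have a closed-form expectation; ``poisson``
draws counts from the corresponding Poisson/binomial laws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

#: splice-site consensus sequences used both by the generator and as the
#: strongest-scoring words of the trained PWMs (3 exonic + 6 intronic nt
#: for the donor; 20 intronic + 3 exonic nt for the acceptor).
DONOR_CONSENSUS = "CAGGTAAGT"
ACCEPTOR_INTRON = "TTTCTTTTCTTCTTTTTCAG"
ACCEPTOR_EXON = "GTT"
ACCEPTOR_CONSENSUS = ACCEPTOR_INTRON + ACCEPTOR_EXON
BRANCH_CONSENSUS = "TACTAAC"

#: offsets of the cryptic splice machinery inside the repeat consensus;
#: the planted exon is [100, 210) in repeat coordinates (110 nt).
_REPEAT_BRANCH = 70
_REPEAT_ACCEPTOR = 80
_REPEAT_EXON_START = 100
_REPEAT_EXON_END = 210
REPEAT_LENGTH = 300
PLANT_EXON_LENGTH = _REPEAT_EXON_END - _REPEAT_EXON_START

#: pulse-chase time points (minutes) and per-class excision kinetics
#: θ*(t) = θ0 + θmax·(1 − exp(−t/τ)).
TIMEPOINTS = (0, 15, 30, 60)
CLASS_KINETICS = {
    "very fast": (0.60, 0.40, 15.0),
    "fast": (0.40, 0.50, 25.0),
    "medium": (0.20, 0.55, 60.0),
    "slow": (0.10, 0.40, 120.0),
    "very slow": (0.03, 0.10, 240.0),
}
SPEED_CLASSES = tuple(CLASS_KINETICS)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=1)
def alu_consensus() -> str:
    """The fixed 300-nt synthetic Alu-like repeat consensus.

    A deterministic random backbone with a cryptic branchpoint,
    acceptor, and donor embedded so that repeat copies carry latent
    splice sites at fixed offsets (this is a synthetic stand-in, not a
    Repbase consensus).
    """
    rng = np.random.default_rng(19870412)
    seq = list(rng.choice(BASES, size=REPEAT_LENGTH, p=[0.2, 0.3, 0.3, 0.2]))
    seq[_REPEAT_BRANCH:_REPEAT_BRANCH + 7] = BRANCH_CONSENSUS
    seq[_REPEAT_ACCEPTOR:_REPEAT_EXON_START] = ACCEPTOR_INTRON
    seq[_REPEAT_EXON_START:_REPEAT_EXON_START + 3] = ACCEPTOR_EXON
    seq[_REPEAT_EXON_END - 3:_REPEAT_EXON_END + 6] = DONOR_CONSENSUS
    return "".join(seq)


@dataclass
class PlantSpec:
    """Ground truth for one planted novel exon."""

    gene_id: str
    host_intron_index: int
    host_intron: tuple[int, int]
    novel_exon: tuple[int, int]
    junction_up: tuple[int, int]
    junction_down: tuple[int, int]
    chrom: str
    strand: str
    psi_star: float
    repeat_family: str | None
    ss_class: str  # strong | weak

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_star <= 1.0:
            raise ValueError("psi_star must be in [0, 1]")
        hs, he = self.host_intron
        ns, ne = self.novel_exon
        if not (hs + 30 <= ns and ne + 30 <= he):
            raise ValueError(
                f"novel exon {self.novel_exon} too close to host intron "
                f"boundary {self.host_intron} in {self.gene_id}"
            )


@dataclass
class SimConfig:
    seed: int = 7
    n_genes: int = 20
    n_plants: int = 10
    exons_per_gene: int = 4
    exon_length: int = 120
    intron_length: int = 400
    host_intron_length: int = 1600
    intergenic: int = 300
    gc_background: float = 0.45
    gc_host_intron: float = 0.60
    mean_depth: int = 20
    count_mode: str = "exact"  # exact | poisson
    psi_values: tuple[float, ...] = (0.5, 0.3, 0.7, 0.15, 0.9)
    repeat_families: tuple[str, ...] = ("AluSx", "AluY", "AluJb", "L1MC4", "AluSq")
    decoy_families: tuple[str, ...] = ("AluJo", "MIRb", "L1MB7")
    repeat_mutation_rate: float = 0.05
    splice_noise: float = 0.15
    weak_fraction: float = 0.0
    n_control: int = 3
    n_perturbed: int = 3
    # time-course
    timecourse_depth: int = 20
    n_lowdepth: int = 3
    lowdepth_depth: int = 2
    # multimapped m6a reads
    em_n_reads: int = 1000
    em_read_length: int = 50
    em_tpm: tuple[float, ...] = (30.0, 10.0)
    em_unique_fraction: float = 0.3
    em_max_loci: int = 10

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.timecourse_depth <= 0:
            raise ValueError("depths must be positive")
        if self.count_mode not in ("exact", "poisson"):
            raise ValueError(f"unknown count mode {self.count_mode!r}")
        if self.em_max_loci > 10:
            raise ValueError("at most 10 candidate loci per read")
        if self.host_intron_length < 400 + REPEAT_LENGTH + 60:
            raise ValueError("host_intron_length too short to fit a planted repeat")
        n_introns = self.exons_per_gene - 1
        if self.n_plants > self.n_genes * n_introns:
            raise ValueError(
                f"cannot fit {self.n_plants} plants into "
                f"{self.n_genes} genes x {n_introns} introns"
            )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(BASES, size=n, p=p))


def _mutate(seq: str, rate: float, rng: np.random.Generator, keep: set[int] | None = None) -> str:
    out = list(seq)
    for i in range(len(out)):
        if keep and i in keep:
            continue
        if rng.random() < rate:
            out[i] = str(rng.choice(BASES[BASES != out[i]]))
    return "".join(out)


def _write_motif(seq: list[str], pos: int, motif: str) -> None:
    seq[pos:pos + len(motif)] = list(motif)


# host-intron slots are filled middle-first so single-plant-per-gene
# configurations use the central (longest-context) intron
def _intron_slot_order(n_introns: int) -> list[int]:
    order = sorted(range(n_introns), key=lambda i: (abs(i - n_introns // 2), i))
    return order


def generate_reference(config: SimConfig, outdir: str | Path) -> dict:
    """Write genome FASTA, GTF, repeat BED, expression table and the
    ground-truth manifest; return the manifest as a dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_introns = config.exons_per_gene - 1
    slot_order = _intron_slot_order(n_introns)

    # plant k -> (gene index, host intron index)
    plant_slots: dict[tuple[int, int], int] = {}
    for k in range(config.n_plants):
        gi = k % config.n_genes
        slot = slot_order[k // config.n_genes]
        plant_slots[(gi, slot)] = k
    host_slots = set(plant_slots)

    chrom = "chrS"
    genome: list[str] = []
    plants: list[PlantSpec] = []
    repeats: list[tuple[int, int, str, str]] = []  # start, end, family, strand
    genes_out: list[dict] = []
    junctions: list[tuple[int, int, str, str, int]] = []  # start, end, strand, gene, idx
    cursor = 0
    fam_cycle = 0
    decoy_cycle = 0

    for gi in range(config.n_genes):
        gene_id = f"G{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        cursor += config.intergenic
        origin = cursor

        # sense-coordinate layout
        intron_lens = [
            config.host_intron_length if (gi, i) in host_slots or (gi, i) in plant_slots
            else config.intron_length
            for i in range(n_introns)
        ]
        # some non-host introns get a decoy repeat (every third one)
        exon_bounds: list[tuple[int, int]] = []
        pos = 0
        parts: list[tuple[str, int, int, int | None]] = []  # kind, start, end, intron idx
        for i in range(config.exons_per_gene):
            exon_bounds.append((pos, pos + config.exon_length))
            pos += config.exon_length
            if i < n_introns:
                parts.append(("intron", pos, pos + intron_lens[i], i))
                pos += intron_lens[i]
        gene_len = pos

        seq = _random_seq(rng, gene_len, config.gc_background)
        sense_repeats: list[tuple[int, int, str]] = []
        sense_plants: list[dict] = []

        for _, istart, iend, idx in parts:
            is_host = (gi, idx) in host_slots
            if is_host:
                gc = config.gc_host_intron
                seq[istart:iend] = _random_seq(rng, iend - istart, gc)
            # annotated splice sites with per-position noise (GT/AG fixed)
            donor = _mutate(DONOR_CONSENSUS, config.splice_noise, rng, keep={3, 4})
            _write_motif(seq, istart - 3, donor)
            acceptor = _mutate(ACCEPTOR_CONSENSUS, config.splice_noise, rng, keep={18, 19})
            _write_motif(seq, iend - 20, acceptor)
            _write_motif(seq, iend - 30, _mutate(BRANCH_CONSENSUS, config.splice_noise, rng))

            if (gi, idx) in plant_slots:
                k = plant_slots[(gi, idx)]
                r0 = istart + 400
                family = config.repeat_families[fam_cycle % len(config.repeat_families)]
                fam_cycle += 1
                copy = _mutate(alu_consensus(), config.repeat_mutation_rate, rng)
                _write_motif(seq, r0, copy)
                ss_class = "weak" if rng.random() < config.weak_fraction else "strong"
                if ss_class == "strong":
                    # restore exact cryptic splice machinery
                    _write_motif(seq, r0 + _REPEAT_BRANCH, BRANCH_CONSENSUS)
                    _write_motif(seq, r0 + _REPEAT_ACCEPTOR, ACCEPTOR_CONSENSUS)
                    _write_motif(seq, r0 + _REPEAT_EXON_END - 3, DONOR_CONSENSUS)
                sense_repeats.append((r0, r0 + REPEAT_LENGTH, family))
                sense_plants.append(
                    dict(
                        k=k,
                        intron_idx=idx,
                        host=(istart, iend),
                        exon=(r0 + _REPEAT_EXON_START, r0 + _REPEAT_EXON_END),
                        family=family,
                        ss_class=ss_class,
                    )
                )
            elif not is_host and idx % 3 == 1 and (iend - istart) >= REPEAT_LENGTH + 100:
                family = config.decoy_families[decoy_cycle % len(config.decoy_families)]
                decoy_cycle += 1
                r0 = istart + 50
                _write_motif(seq, r0, _mutate(alu_consensus(), config.repeat_mutation_rate, rng))
                sense_repeats.append((r0, r0 + REPEAT_LENGTH, family))

        block = "".join(seq)
        if strand == "-":
            block = revcomp(block)

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return origin + a, origin + b
            return origin + gene_len - b, origin + gene_len - a

        genome.append(block)
        exons_genomic = sorted(to_genomic(a, b) for a, b in exon_bounds)
        genes_out.append(
            dict(gene_id=gene_id, strand=strand, span=to_genomic(0, gene_len), exons=exons_genomic)
        )
        for _, istart, iend, idx in parts:
            s, e = to_genomic(istart, iend)
            junctions.append((s, e, strand, gene_id, idx))
        for r0, r1, family in sense_repeats:
            s, e = to_genomic(r0, r1)
            repeats.append((s, e, family, strand))
        for p in sense_plants:
            hs, he = to_genomic(*p["host"])
            ns, ne = to_genomic(*p["exon"])
            plants.append(
                PlantSpec(
                    gene_id=gene_id,
                    host_intron_index=p["intron_idx"],
                    host_intron=(hs, he),
                    novel_exon=(ns, ne),
                    junction_up=(hs, ns),
                    junction_down=(ne, he),
                    chrom=chrom,
                    strand=strand,
                    psi_star=config.psi_values[p["k"] % len(config.psi_values)],
                    repeat_family=p["family"],
                    ss_class=p["ss_class"],
                )
            )
        cursor += gene_len
    cursor += config.intergenic

    # assemble: [spacer][gene block][spacer]...[spacer]; spacers come from
    # their own deterministic stream so gene blocks stay seed-stable
    rng_sp = np.random.default_rng(config.seed + 777)
    pieces = []
    for block in genome:
        pieces.append("".join(_random_seq(rng_sp, config.intergenic, config.gc_background)))
        pieces.append(block)
    pieces.append("".join(_random_seq(rng_sp, config.intergenic, config.gc_background)))
    genome_seq = "".join(pieces)
    assert len(genome_seq) == cursor

    # ---- write outputs
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i:i + 80] + "\n")

    with open(outdir / "annotation.gtf", "w") as fh:
        for g in genes_out:
            s, e = g["span"]
            attrs = f'gene_id "{g["gene_id"]}"; gene_name "{g["gene_id"]}";'
            fh.write(f'{chrom}\tnovex_sim\tgene\t{s + 1}\t{e}\t.\t{g["strand"]}\t.\t{attrs}\n')
            tid = g["gene_id"] + ".t1"
            tattrs = attrs + f' transcript_id "{tid}";'
            fh.write(f'{chrom}\tnovex_sim\ttranscript\t{s + 1}\t{e}\t.\t{g["strand"]}\t.\t{tattrs}\n')
            for a, b in g["exons"]:
                fh.write(f'{chrom}\tnovex_sim\texon\t{a + 1}\t{b}\t.\t{g["strand"]}\t.\t{tattrs}\n')

    with open(outdir / "repeats.bed", "w") as fh:
        for s, e, family, strand in sorted(repeats):
            fh.write(f"{chrom}\t{s}\t{e}\t{family}\t0\t{strand}\n")

    rng_expr = np.random.default_rng(config.seed + 2000)
    expression = {
        g["gene_id"]: round(float(rng_expr.uniform(5, 50)), 3) for g in genes_out
    }
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gid in sorted(expression):
            fh.write(f"{gid}\t{expression[gid]}\n")

    manifest = dict(
        config=dataclasses.asdict(config),
        chrom=chrom,
        chrom_length=len(genome_seq),
        n_annotated_junctions=len(junctions),
        genes=genes_out,
        annotated_junctions=[list(j) for j in sorted(junctions)],
        plants=[dataclasses.asdict(p) for p in plants],
        repeats=[list(r) for r in sorted(repeats)],
        expression=expression,
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _plant_lookup(manifest: dict) -> dict[tuple[int, int], dict]:
    return {tuple(p["host_intron"]): p for p in manifest["plants"]}


def simulate_junction_counts(
    manifest: dict,
    config: SimConfig,
    condition: str,
    outdir: str | Path,
) -> list[tuple[str, Path, int]]:
    """Write per-sample junction tables; returns (sample_id, path, n_rows).

    Annotated junctions receive ``mean_depth`` reads; host junctions of
    planted exons in perturbed samples receive the exclusion count
    round(depth·(1−ψ*)), and the two flanking novel junctions split the
    inclusion count round(2·depth·ψ*).  Control samples carry no novel
    junction reads at all.
    """
    if condition not in ("control", "perturbed"):
        raise ValueError(f"unknown condition {condition!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = manifest["chrom"]
    depth = config.mean_depth
    plants = _plant_lookup(manifest)
    n_samples = config.n_control if condition == "control" else config.n_perturbed
    out = []
    for s in range(n_samples):
        sample_id = f"{condition}_{s + 1}"
        rng = np.random.default_rng(
            config.seed + (10_000 if condition == "perturbed" else 20_000) + s
        )
        rows: list[tuple[int, int, str, int]] = []
        for start, end, strand, _gene, _idx in manifest["annotated_junctions"]:
            plant = plants.get((start, end)) if condition == "perturbed" else None
            if plant is not None:
                mean = depth * (1 - plant["psi_star"])
            else:
                mean = depth
            count = int(round(mean)) if config.count_mode == "exact" else int(rng.poisson(mean))
            rows.append((start, end, strand, count))
            if plant is not None:
                inc = 2 * depth * plant["psi_star"]
                if config.count_mode == "exact":
                    total = int(round(inc))
                    i_up, i_down = (total + 1) // 2, total // 2
                else:
                    i_up = int(rng.poisson(inc / 2))
                    i_down = int(rng.poisson(inc / 2))
                ju, jd = plant["junction_up"], plant["junction_down"]
                if i_up > 0:
                    rows.append((ju[0], ju[1], strand, i_up))
                if i_down > 0:
                    rows.append((jd[0], jd[1], strand, i_down))
        rows = [r for r in rows if r[3] > 0]
        rows.sort()
        path = outdir / f"junctions.{sample_id}.tsv"
        with open(path, "w") as fh:
            for start, end, strand, count in rows:
                code = "1" if strand == "+" else "2"
                fh.write(f"{chrom}\t{start + 1}\t{end}\t{code}\t{count}\t0\n")
        out.append((sample_id, path, len(rows)))
    return out


def theta_true(speed_class: str, t: float) -> float:
    """Planted splicing efficiency θ*(t) for a kinetic class."""
    theta0, thetamax, tau = CLASS_KINETICS[speed_class]
    return theta0 + thetamax * (1.0 - math.exp(-t / tau))


def simulate_timecourse(
    manifest: dict, config: SimConfig, outdir: str | Path
) -> tuple[Path, dict]:
    """Write pulse-chase split/non-split junction counts at t ∈ {0,15,30,60}.

    Every annotated intron is assigned a kinetic class (plant host
    introns are pinned to "very slow", emulating the association between
    exonization and slow excision); a few introns are emitted at
    low depth to exercise the ≥5-reads-per-junction coverage rule.
    Returns (table path, truth dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1000)
    plants = _plant_lookup(manifest)
    introns = [tuple(j) for j in manifest["annotated_junctions"]]

    classes: dict[str, str] = {}
    depths: dict[str, int] = {}
    non_host_ids = []
    intron_ids = {}
    for start, end, strand, gene, idx in introns:
        iid = f"{gene}_i{idx}"
        intron_ids[(start, end)] = iid
        if (start, end) in plants:
            classes[iid] = "very slow"
        else:
            non_host_ids.append(iid)
    cycle = list(SPEED_CLASSES)
    order = rng.permutation(len(non_host_ids))
    for j, pos in enumerate(order):
        classes[non_host_ids[pos]] = cycle[j % len(cycle)]
    lowdepth = sorted(non_host_ids)[: config.n_lowdepth]
    for start, end, strand, gene, idx in introns:
        iid = intron_ids[(start, end)]
        depths[iid] = config.lowdepth_depth if iid in lowdepth else config.timecourse_depth

    path = outdir / "timecourse.tsv"
    with open(path, "w") as fh:
        fh.write(
            "intron_id\tchrom\tstart\tend\tstrand\ttime\t"
            "sj5_split\tsj5_nonsplit\tsj3_split\tsj3_nonsplit\n"
        )
        for start, end, strand, gene, idx in sorted(introns, key=lambda j: (j[0], j[1])):
            iid = intron_ids[(start, end)]
            depth = depths[iid]
            for t in TIMEPOINTS:
                theta = theta_true(classes[iid], t)
                counts = []
                for _sj in (5, 3):
                    if config.count_mode == "exact":
                        split = int(round(depth * theta))
                    else:
                        split = int(rng.binomial(depth, theta))
                    counts.extend([split, depth - split])
                fh.write(
                    f"{iid}\t{manifest['chrom']}\t{start}\t{end}\t{strand}\t{t}\t"
                    f"{counts[0]}\t{counts[1]}\t{counts[2]}\t{counts[3]}\n"
                )
    truth = dict(classes=classes, lowdepth=lowdepth, depths=depths)
    with open(outdir / "timecourse_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return path, truth


def simulate_multimap_reads(
    manifest: dict, config: SimConfig, outdir: str | Path
) -> dict:
    """Write multimapped reads (SAM) over homologous repeat copies plus a
    host-expression table, recording each read's true source locus.

    Candidate loci are Alu-family repeat copies from planted events;
    true source loci are drawn with probabilities proportional to the
    configured host TPMs, so ground-truth fractions equal the TPM
    shares.  A configurable fraction of reads maps uniquely.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 3000)
    chrom = manifest["chrom"]

    alu_plants = [
        p for p in manifest["plants"]
        if p["repeat_family"] and "Alu" in p["repeat_family"]
    ]
    seen_genes: set[str] = set()
    chosen = []
    for p in alu_plants:
        if p["gene_id"] in seen_genes:
            continue
        seen_genes.add(p["gene_id"])
        chosen.append(p)
        if len(chosen) == min(len(config.em_tpm), config.em_max_loci):
            break
    if len(chosen) < 2:
        raise ValueError("need at least two Alu repeat copies in distinct genes")

    # locus = the repeat copy containing the planted exon
    rep_by_key = {(r[0], r[1]): r for r in manifest["repeats"]}
    loci = []
    for i, p in enumerate(chosen):
        ns, ne = p["novel_exon"]
        rep = next(
            (r for r in manifest["repeats"] if r[0] <= ns and ne <= r[1]),
            None,
        )
        if rep is None:
            raise ValueError(f"no repeat copy spans plant exon of {p['gene_id']}")
        loci.append(
            dict(
                locus_id=f"L{i}",
                chrom=chrom,
                start=rep[0],
                end=rep[1],
                strand=rep[3],
                gene_id=p["gene_id"],
                tpm=float(config.em_tpm[i]),
            )
        )
    tpms = np.array([l["tpm"] for l in loci])
    probs = tpms / tpms.sum()

    from pyfaidx import Fasta

    fa = Fasta(str(Path(outdir) / "genome.fa")) if (Path(outdir) / "genome.fa").exists() else None

    sam_path = outdir / "m6a_reads.sam"
    true_counts = {l["locus_id"]: 0 for l in loci}
    read_truth: dict[str, str] = {}
    rl = config.em_read_length
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{manifest['chrom_length']}\n")
        for j in range(config.em_n_reads):
            rid = f"r{j:05d}"
            src = int(rng.choice(len(loci), p=probs))
            true_counts[loci[src]["locus_id"]] += 1
            read_truth[rid] = loci[src]["locus_id"]
            offset = int(rng.integers(0, REPEAT_LENGTH - rl))
            unique = rng.random() < config.em_unique_fraction
            cands = [src] if unique else list(range(len(loci)))
            nh = len(cands)
            for rank, li in enumerate(cands):
                locus = loci[li]
                pos = locus["start"] + offset
                seq = (
                    str(fa[chrom][pos:pos + rl]) if fa is not None else "N" * rl
                ).upper()
                flag = 0 if rank == 0 else 256
                mapq = 255 if nh == 1 else 0
                fh.write(
                    f"{rid}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{rl}M\t*\t0\t0\t"
                    f"{seq}\t*\tNH:i:{nh}\n"
                )

    host_tpm = {l["locus_id"]: l["tpm"] for l in loci}
    with open(outdir / "em_loci.bed", "w") as fh:
        for l in loci:
            fh.write(
                f"{l['chrom']}\t{l['start']}\t{l['end']}\t{l['gene_id']}\t0\t{l['strand']}\n"
            )
    with open(outdir / "em_expression.tsv", "w") as fh:
        fh.write("gene_id\ttpm\n")
        for l in loci:
            fh.write(f"{l['gene_id']}\t{l['tpm']}\n")

    truth = dict(
        loci=loci,
        true_counts=true_counts,
        true_fractions={
            lid: true_counts[lid] / config.em_n_reads for lid in true_counts
        },
        prior_fractions={l["locus_id"]: float(p) for l, p in zip(loci, probs)},
        read_truth=read_truth,
        sam=str(sam_path),
        n_reads=config.em_n_reads,
        read_length=rl,
        host_tpm=host_tpm,
    )
    with open(outdir / "em_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def generate_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Reference + control/perturbed junction tables in one call.

    Returns the manifest extended with per-sample junction-table paths.
    """
    outdir = Path(outdir)
    manifest = generate_reference(config, outdir)
    samples = {}
    for condition in ("control", "perturbed"):
        for sample_id, path, n_rows in simulate_junction_counts(
            manifest, config, condition, outdir
        ):
            samples[sample_id] = dict(path=str(path), condition=condition, n_rows=n_rows)
    manifest["samples"] = samples
    # the sidecar stores paths relative to the bundle dir so identical
    # seeds give byte-identical bundles wherever they are written
    relative = {
        sid: dict(spec, path=Path(spec["path"]).name) for sid, spec in samples.items()
    }
    with open(outdir / "samples.json", "w") as fh:
        json.dump(relative, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# small statistical simulators for the modelling/stats modules


def simulate_logistic_table(
    n: int, coef_transposon: float = 2.0, seed: int = 0
) -> "pd.DataFrame":
    """Synthetic intron feature table with a planted transposon-overlap
    log-odds effect, for logistic parameter-recovery checks.

    logit P(exonized) = −0.6 + coef·transposon_overlap + 1.0·gc_z
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    trans = rng.random(n) < 0.3
    gc_z = rng.normal(size=n)
    logit = -0.6 + coef_transposon * trans + 1.0 * gc_z
    p = 1.0 / (1.0 + np.exp(-logit))
    label = rng.random(n) < p
    return pd.DataFrame(
        dict(
            intron_id=[f"i{j}" for j in range(n)],
            label=np.where(label, "exonized", "background"),
            transposon_overlap=trans.astype(int),
            gc=gc_z,
        )
    )


def simulate_engagement_tables(
    n_genes: int = 500, shift_slope: float = -0.3, seed: int = 0
) -> tuple["pd.DataFrame", dict[str, float]]:
    """Synthetic total/polysome TPM tables with a planted engagement
    shift of ``shift_slope``·Δψ; returns (table, Δψ per gene)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    genes = [f"G{j:04d}" for j in range(n_genes)]
    dpsi = {g: float(rng.uniform(-0.1, 0.5)) for g in genes}
    rows = []
    for g in genes:
        base = float(rng.uniform(20, 200))
        shift = shift_slope * max(dpsi[g], 0.0)
        noise = float(rng.normal(0, 0.02))
        rows.append(
            dict(
                gene_id=g,
                total_pre=base,
                total_post=base,
                poly_pre=base,
                # Δpoly = (post-pre)/max(...) = target shift (for shift<=0)
                poly_post=base * (1.0 + shift + noise),
            )
        )
    return pd.DataFrame(rows), dpsi


def simulate_cohort_counts(
    n_per_group: int = 20,
    control_mean: float = 40.0,
    suppression: float = 0.5,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Per-sample exonization-event counts for a suppressed case cohort
    vs controls (Poisson counts; ``suppression`` scales the case mean)."""
    rng = np.random.default_rng(seed)
    control = [int(c) for c in rng.poisson(control_mean, size=n_per_group)]
    case = [int(c) for c in rng.poisson(control_mean * suppression, size=n_per_group)]
    return case, control
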