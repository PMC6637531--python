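"""EM assignment of multimapped reads to repeat loci and normalized
coverage/meta-profiles around them.

Repetitive elements make m6a-fragment reads multimap (here up to 10
candidate loci per read).  Reads are assigned fractionally by an EM in
which host-gene expression acts as a Dirichlet prior on the per-locus
read-generating weights:

    E-step:  γ(r,l) ∝ θ_l over the read's candidate loci
    M-step:  θ_l = (α·p_l + Σ_r γ(r,l)) / (α + N)

with p the TPM-normalized host-expression shares and α the prior
strength (in pseudo-reads).  Uniquely mapped reads are pinned at weight
1.  For a single ambiguous read the converged weights equal the
expression shares exactly; with informative (partially unique) data the
data term dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
from scipy import stats

from .types import GenomicInterval

MAX_CANDIDATES = 10


@dataclass
class MultiRead:
    """One read with its candidate alignments (locus_id, interval)."""

    read_id: str
    alignments: list[tuple[str, GenomicInterval]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alignments) <= MAX_CANDIDATES:
            raise ValueError(
                f"read {self.read_id} has {len(self.alignments)} candidate loci "
                f"(must be 1..{MAX_CANDIDATES})"
            )


@dataclass
class EMResult:
    #: read_id -> {locus_id: weight}; weights sum to 1 per read
    assignments: dict[str, dict[str, float]]
    #: locus_id -> total fractional read mass
    locus_mass: dict[str, float]
    #: max |Δθ| per iteration
    delta_history: list[float]
    n_iter: int
    converged: bool
    #: reads whose candidate hosts all had zero TPM (uniform fallback)
    zero_prior_reads: list[str] = field(default_factory=list)


def load_multireads(
    sam_path: str | Path, loci: Sequence[tuple[str, GenomicInterval]]
) -> list[MultiRead]:
    """Group SAM alignments by read name and attach each alignment to
    the locus it overlaps; reads with more than 10 candidates are
    discarded, alignments outside every locus are dropped."""
    by_read: dict[str, list[tuple[str, GenomicInterval]]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end,
                "-" if aln.is_reverse else "+",
            )
            locus_id = next(
                (lid for lid, liv in loci if liv.overlap(iv) > 0), None
            )
            if locus_id is None:
                continue
            by_read.setdefault(aln.query_name, []).append((locus_id, iv))
    out = []
    for rid in sorted(by_read):
        alns = by_read[rid]
        if len(alns) > MAX_CANDIDATES:
            continue
        out.append(MultiRead(rid, alns))
    return out


def em_assign(
    reads: Sequence[MultiRead],
    host_tpm: Mapping[str, float],
    max_iter: int = 100,
    tol: float = 1e-6,
    prior_strength: float = 1.0,
) -> EMResult:
    """Fractionally assign multimapped reads to loci (see module docs)."""
    loci = sorted({lid for r in reads for lid, _ in r.alignments})
    index = {lid: i for i, lid in enumerate(loci)}
    L, N = len(loci), len(reads)
    tpm = np.array([max(0.0, float(host_tpm.get(lid, 0.0))) for lid in loci])
    prior = tpm / tpm.sum() if tpm.sum() > 0 else np.full(L, 1.0 / L)

    cand: list[np.ndarray] = []
    zero_prior = []
    for r in reads:
        idx = np.unique([index[lid] for lid, _ in r.alignments])
        cand.append(idx)
        if tpm[idx].sum() == 0 and len(idx) > 1:
            zero_prior.append(r.read_id)

    theta = prior.copy()
    gamma = np.zeros((N, L))
    deltas: list[float] = []
    converged = False
    for _ in range(max_iter):
        gamma[:] = 0.0
        for i, idx in enumerate(cand):
            if len(idx) == 1:
                gamma[i, idx[0]] = 1.0
                continue
            w = theta[idx]
            total = w.sum()
            gamma[i, idx] = w / total if total > 0 else 1.0 / len(idx)
        new_theta = (prior_strength * prior + gamma.sum(axis=0)) / (prior_strength + N)
        delta = float(np.abs(new_theta - theta).max())
        deltas.append(delta)
        theta = new_theta
        if delta < tol:
            converged = True
            break

    assignments = {
        r.read_id: {loci[j]: float(gamma[i, j]) for j in cand[i]}
        for i, r in enumerate(reads)
    }
    locus_mass = {lid: float(gamma[:, j].sum()) for lid, j in index.items()}
    return EMResult(
        assignments=assignments,
        locus_mass=locus_mass,
        delta_history=deltas,
        n_iter=len(deltas),
        converged=converged,
        zero_prior_reads=zero_prior,
    )


def normalized_coverage(
    reads: Sequence[MultiRead],
    assignments: Mapping[str, Mapping[str, float]],
    loci: Sequence[tuple[str, GenomicInterval]],
    library_size: float,
) -> dict[str, float]:
    """Per-locus fractional coverage x 10^6 / (library size x locus
    length): reads-per-million per nucleotide, strand-aware through the
    locus definitions."""
    out = {}
    for lid, liv in loci:
        if liv.length <= 0:
            continue
        total = 0.0
        for r in reads:
            w = assignments.get(r.read_id, {})
            for cand_lid, aln in r.alignments:
                if cand_lid == lid:
                    total += w.get(lid, 0.0) * aln.overlap(liv)
        out[lid] = total * 1e6 / (library_size * liv.length)
    return out


@dataclass
class CoverageProfile:
    """Mean relative coverage around anchor 5′ ends (flank mean = 1)."""

    positions: np.ndarray  # relative positions, [-W, W)
    values: np.ndarray
    n_anchors: int


def _coverage_arrays(
    reads: Sequence[MultiRead],
    assignments: Mapping[str, Mapping[str, float]],
) -> dict[str, np.ndarray]:
    sizes: dict[str, int] = {}
    for r in reads:
        for _, iv in r.alignments:
            sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end + 1)
    cov = {c: np.zeros(n) for c, n in sizes.items()}
    for r in reads:
        w = assignments.get(r.read_id, {})
        for lid, iv in r.alignments:
            weight = w.get(lid, 0.0)
            if weight > 0:
                cov[iv.chrom][iv.start:iv.end] += weight
    return cov


def metaprofile(
    reads: Sequence[MultiRead],
    assignments: Mapping[str, Mapping[str, float]],
    anchors: Sequence[GenomicInterval],
    window: int = 300,
) -> CoverageProfile:
    """Coverage at positions relative to anchor 5′ ends (strand-flipped
    for − anchors), averaged over anchors and normalized so the mean
    over the outermost 10% of positions (both tails) equals 1."""
    if not anchors:
        raise ValueError("no anchors given")
    if window <= 0:
        raise ValueError("window must be positive")
    cov = _coverage_arrays(reads, assignments)
    width = 2 * window
    acc = np.zeros(width)
    for anchor in anchors:
        arr = cov.get(anchor.chrom)
        vals = np.zeros(width)
        if arr is not None:
            if anchor.strand == "+":
                lo, hi = anchor.start - window, anchor.start + window
                src = arr[max(0, lo):min(len(arr), hi)]
                vals[max(0, -lo):max(0, -lo) + len(src)] = src
            else:
                lo, hi = anchor.end - window, anchor.end + window
                src = arr[max(0, lo):min(len(arr), hi)]
                tmp = np.zeros(width)
                tmp[max(0, -lo):max(0, -lo) + len(src)] = src
                vals = tmp[::-1]
        acc += vals
    mean = acc / len(anchors)
    k = max(1, int(0.1 * width) // 2)
    flank = np.concatenate([mean[:k], mean[-k:]]).mean()
    values = mean / flank if flank > 0 else mean
    return CoverageProfile(np.arange(-window, window), values, len(anchors))


def compare_coverage(
    exonized_values: Sequence[float], background_values: Sequence[float]
) -> dict:
    """Two-sided Wilcoxon rank-sum on per-locus normalized coverage."""
    if len(exonized_values) == 0 or len(background_values) == 0:
        raise ValueError("both groups must be nonempty")
    stat, p = stats.ranksums(exonized_values, background_values)
    return dict(
        statistic=float(stat),
        p_value=float(p),
        median_exonized=float(np.median(exonized_values)),
        median_background=float(np.median(background_values)),
        n_exonized=len(exonized_values),
        n_background=len(background_values),
    )
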