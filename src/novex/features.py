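"""Genomic/splicing features of introns and the logistic model that
discriminates exonization-prone introns from expressed background.

Splice-site strength is scored with position weight matrices trained on
the annotation's own junctions (5′ss window: 3 exonic + 6 intronic nt;
3′ss window: 20 intronic + 3 exonic nt), log2-odds against a uniform
background.  Branchpoint and polypyrimidine-tract statistics come from
a declared heuristic over the 20–500 nt window upstream of the 3′ss
(motif yUnAy with the branch adenosine at the fourth position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .events import ExonizationEvent
from .simulate import revcomp
from .types import AnnotationBundle, GenomicInterval

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
WINDOW_5SS = 9   # 3 exon + 6 intron
WINDOW_3SS = 23  # 20 intron + 3 exon
BP_WINDOW = (20, 500)  # branch search window upstream of the 3'ss


@dataclass
class SpliceSitePWM:
    """Per-position log2-odds matrix for one splice-site kind."""

    kind: str  # "5ss" | "3ss"
    log_odds: np.ndarray  # (window, 4)

    @property
    def window(self) -> int:
        return self.log_odds.shape[0]

    def score(self, sequence: str) -> float:
        """Sum of per-position log-odds; N contributes 0."""
        if len(sequence) != self.window:
            raise ValueError(
                f"{self.kind} PWM expects {self.window} nt, got {len(sequence)}"
            )
        total = 0.0
        for i, base in enumerate(sequence.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                total += self.log_odds[i, idx]
        return float(total)


def train_pwm_from_sequences(kind: str, sequences: Sequence[str]) -> SpliceSitePWM:
    window = WINDOW_5SS if kind == "5ss" else WINDOW_3SS
    counts = np.ones((window, 4))  # +1 pseudocount
    n = 0
    for seq in sequences:
        if len(seq) != window or any(b not in _BASE_INDEX for b in seq.upper()):
            continue
        for i, base in enumerate(seq.upper()):
            counts[i, _BASE_INDEX[base]] += 1
        n += 1
    if n < 50:
        raise ValueError(f"need >= 50 clean {kind} training sites, got {n}")
    probs = counts / counts.sum(axis=1, keepdims=True)
    return SpliceSitePWM(kind, np.log2(probs / 0.25))


def splice_site_windows(
    annotation: AnnotationBundle, genome
) -> tuple[list[str], list[str]]:
    """Extract 5′ss and 3′ss training windows for every annotated
    junction, in transcription orientation; out-of-bounds sites skipped."""
    five, three = [], []
    for _gene_id, intron in annotation.annotated_introns():
        chrom_len = len(genome[intron.chrom])
        if intron.strand == "+":
            w5 = (intron.start - 3, intron.start + 6)
            w3 = (intron.end - 20, intron.end + 3)
        else:
            w5 = (intron.end - 6, intron.end + 3)
            w3 = (intron.start - 3, intron.start + 20)
        for window, sink in ((w5, five), (w3, three)):
            if window[0] < 0 or window[1] > chrom_len:
                continue
            seq = str(genome[intron.chrom][window[0]:window[1]]).upper()
            if intron.strand == "-":
                seq = revcomp(seq)
            sink.append(seq)
    return five, three


def train_pwm(annotation: AnnotationBundle, genome) -> tuple[SpliceSitePWM, SpliceSitePWM]:
    """Train the donor/acceptor PWM pair on the annotated junctions."""
    five, three = splice_site_windows(annotation, genome)
    return train_pwm_from_sequences("5ss", five), train_pwm_from_sequences("3ss", three)


def score_splice_site(pwm: SpliceSitePWM, sequence: str) -> float:
    return pwm.score(sequence)


@dataclass
class BranchFeatures:
    bp_num: int = 0
    bp_scr: float = 0.0
    ppt_len: int = 0
    ppt_scr: float = 0.0
    agez_len: int = 0
    defined: bool = True


def _is_py(base: str) -> bool:
    return base in "CT"


def score_branch_region(seq: str) -> BranchFeatures:
    """Branchpoint/PPT/AGEZ heuristics over an intron's 3′-terminal
    sequence (the string must end at the 3′ss, i.e. with the terminal AG).

    Branch candidates are adenosines whose yUnAy context is scored as
    (consensus-matching positions)/5 × positional weight
    1 − |dist − 25|/475 (clamped); bp_num counts strict yUnAy matches
    with the branch A 20–500 nt upstream of the 3′ss.  The PPT is the
    longest >= 80%-pyrimidine stretch between the best branchpoint and
    the 3′ss; AGEZ is the AG-free gap upstream of the 3′ss AG.
    """
    L = len(seq)
    if L < 23:
        return BranchFeatures(defined=False)
    seq = seq.upper()

    bp_num = 0
    best_score, best_pos = 0.0, None
    best_strict_score, best_strict_pos = 0.0, None
    for i in range(3, L - 1):
        if seq[i] != "A":
            continue
        dist = L - i  # branch A to intron 3' end
        if not BP_WINDOW[0] <= dist <= BP_WINDOW[1]:
            continue
        ctx = seq[i - 3:i + 2]  # y U n A y
        match = (
            _is_py(ctx[0])
            + (ctx[1] == "T")
            + 1  # n matches anything
            + 1  # the branch A itself
            + _is_py(ctx[4])
        )
        strict = match == 5
        bp_num += strict
        posw = max(0.0, 1.0 - abs(dist - 25) / 475.0)
        score = (match / 5.0) * posw
        if score > best_score:
            best_score, best_pos = score, i
        if strict and score > best_strict_score:
            best_strict_score, best_strict_pos = score, i

    bp_scr = best_strict_score if best_strict_pos is not None else best_score
    anchor = best_strict_pos if best_strict_pos is not None else best_pos

    ppt_len, ppt_scr = 0, 0.0
    if anchor is not None:
        region = seq[anchor + 1:L - 2]
        ppt_len, ppt_scr = _longest_py_run(region)

    agez_len = L - 2  # whole region AG-free by default
    for j in range(L - 4, -1, -1):
        if seq[j:j + 2] == "AG":
            agez_len = (L - 2) - (j + 2)
            break
    return BranchFeatures(bp_num, bp_scr, ppt_len, ppt_scr, agez_len)


def _longest_py_run(region: str) -> tuple[int, float]:
    """Longest contiguous stretch with pyrimidine fraction >= 0.8."""
    n = len(region)
    is_py = np.array([_is_py(b) for b in region], dtype=int)
    prefix = np.concatenate([[0], np.cumsum(is_py)])
    best_len, best_frac = 0, 0.0
    for a in range(n):
        for b in range(a + best_len + 1, n + 1):
            count = prefix[b] - prefix[a]
            frac = count / (b - a)
            if frac >= 0.8 and (b - a) > best_len:
                best_len, best_frac = b - a, frac
    return best_len, best_frac * best_len


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _scan_pwm(pwm: SpliceSitePWM, seq: str) -> np.ndarray:
    """PWM score at every window start position (N-positions score 0)."""
    enc = _encode(seq.upper())
    n = len(enc) - pwm.window + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(pwm.window):
        col = enc[i:i + n]
        valid = col >= 0
        scores[valid] += pwm.log_odds[i, col[valid]]
    return scores


def best_internal_sites(
    pwm5: SpliceSitePWM, pwm3: SpliceSitePWM, intron_seq: str, margin: int = 30
) -> tuple[float, float, int] | None:
    """Best internal (cryptic) acceptor/donor pair inside an intron.

    Returns (ss5_score, ss3_score, ss_dist) where ss_dist is the span
    between the chosen acceptor (putative exon start) and donor
    (putative exon end) — for host introns of real events this recovers
    the novel exon.  None when the intron is too short to scan.
    """
    L = len(intron_seq)
    acc_scores = _scan_pwm(pwm3, intron_seq)  # window start = a - 20
    don_scores = _scan_pwm(pwm5, intron_seq)  # window start = b - 3
    best = None
    # acceptor exon-start positions a, donor exon-end positions b
    a_lo, a_hi = max(20, margin), L - margin - 10
    if a_hi <= a_lo or acc_scores.size == 0:
        return None
    a_candidates = np.arange(a_lo, a_hi)
    a_idx = a_candidates - 20
    a_idx = a_idx[a_idx < acc_scores.size]
    if a_idx.size == 0:
        return None
    best_a_rel = int(np.argmax(acc_scores[a_idx]))
    a = int(a_idx[best_a_rel] + 20)
    s3 = float(acc_scores[a - 20])
    b_lo, b_hi = a + 10, L - margin
    b_candidates = np.arange(b_lo, b_hi)
    b_idx = b_candidates - 3
    b_idx = b_idx[(b_idx >= 0) & (b_idx < don_scores.size)]
    if b_idx.size == 0:
        return None
    best_b_rel = int(np.argmax(don_scores[b_idx]))
    b = int(b_idx[best_b_rel] + 3)
    s5 = float(don_scores[b - 3])
    return s5, s3, b - a


# ---------------------------------------------------------------------------
# feature extraction


def _intron_sense_seq(genome, intron: GenomicInterval) -> str:
    seq = str(genome[intron.chrom][intron.start:intron.end]).upper()
    return revcomp(seq) if intron.strand == "-" else seq


def _track_mean(track: dict[str, list[tuple[int, int, float]]], chrom: str, start: int, end: int) -> float:
    total, covered = 0.0, 0
    for s, e, v in track.get(chrom, []):
        ov = min(e, end) - max(s, start)
        if ov > 0:
            total += ov * v
            covered += ov
    return total / (end - start) if end > start else 0.0


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            track.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    return track


def extract_features(
    annotation: AnnotationBundle,
    genome,
    events: Sequence[ExonizationEvent],
    expression: Mapping[str, float],
    repeats: Sequence[tuple[GenomicInterval, str]] = (),
    nucleosome: dict | None = None,
    tad_boundaries: Sequence[GenomicInterval] | None = None,
    min_tpm: float = 1.0,
    expand_families: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """One feature row per intron: host introns of accepted events are
    labeled "exonized"; all other introns of expressed genes
    (TPM > ``min_tpm``) form the background.  Returns the table plus a
    metadata dict naming each feature's provenance/interpretation."""
    pwm5, pwm3 = train_pwm(annotation, genome)
    host_of: dict[tuple, ExonizationEvent] = {
        ev.host_intron.key(): ev for ev in events
    }

    rows = []
    for gene_id, intron in annotation.annotated_introns():
        gene = annotation.genes[gene_id]
        key = intron.key()
        is_exonized = key in host_of
        if not is_exonized and expression.get(gene_id, 0.0) <= min_tpm:
            continue
        sense = _intron_sense_seq(genome, intron)
        gc = (sense.count("G") + sense.count("C")) / len(sense)
        if intron.strand == "+":
            tss_distance = intron.start - gene.span.start
            mid = (intron.start + intron.end) // 2
            rel = (mid - gene.span.start) / gene.span.length
        else:
            tss_distance = gene.span.end - intron.end
            mid = (intron.start + intron.end) // 2
            rel = (gene.span.end - mid) / gene.span.length

        sites = best_internal_sites(pwm5, pwm3, sense)
        ss5, ss3, ss_dist = sites if sites is not None else (0.0, 0.0, 0)

        if is_exonized:
            ev = host_of[key]
            # branch region ends at the novel exon's acceptor (3'ss)
            if intron.strand == "+":
                region_end = ev.novel_exon.start - intron.start
            else:
                region_end = intron.end - ev.novel_exon.end
        else:
            region_end = len(sense)
        branch = score_branch_region(sense[max(0, region_end - 500):region_end])

        row = dict(
            intron_id=f"{gene_id}_{intron.start}_{intron.end}",
            label="exonized" if is_exonized else "background",
            intron_length=intron.length,
            gc=gc,
            tss_distance=tss_distance,
            relative_gene_position=rel,
            ss5_score=ss5,
            ss3_score=ss3,
            ss_dist=ss_dist,
            bp_num=branch.bp_num,
            bp_scr=branch.bp_scr,
            ppt_len=branch.ppt_len,
            ppt_scr=branch.ppt_scr,
            agez_len=branch.agez_len,
        )

        overlapping = [fam for iv, fam in repeats if intron.overlap(iv) > 0]
        row["transposon_overlap"] = int(bool(overlapping))
        if expand_families:
            classes = {
                "Alu" if "Alu" in f else ("L1" if f.startswith("L1") else "Other")
                for f in overlapping
            }
            for cls in ("Alu", "L1", "Other"):
                row[f"transposon_{cls}"] = int(cls in classes)

        if nucleosome is not None:
            if is_exonized:
                ev = host_of[key]
                w = (ev.novel_exon.start - 100, ev.novel_exon.end + 100)
            else:
                center = (intron.start + intron.end) // 2
                w = (center - 160, center + 160)
            row["nucleosome_occ"] = _track_mean(nucleosome, intron.chrom, *w)
        if tad_boundaries is not None:
            mid = (intron.start + intron.end) // 2
            dists = [
                abs(mid - (b.start + b.end) // 2)
                for b in tad_boundaries
                if b.chrom == intron.chrom
            ]
            row["tad_boundary_dist"] = min(dists) if dists else np.nan
        rows.append(row)

    table = pd.DataFrame(rows)
    if (table["label"] == "background").sum() == 0:
        raise ValueError("no expressed background introns (all TPM <= threshold)")
    metadata = {
        "ss5_score": "PWM log2-odds trained on annotated donors (maximum-entropy scorer replaced by PWM)",
        "ss3_score": "PWM log2-odds trained on annotated acceptors (maximum-entropy scorer replaced by PWM)",
        "ss_dist": "interpretation: span of the best internal acceptor/donor pair (novel-exon length analog)",
        "bp_num": "strict yUnAy matches 20-500 nt upstream of the 3'ss (SVM branch scorer replaced by heuristic)",
        "bp_scr": "(consensus matches/5) x positional weight of best branch candidate",
        "ppt_len": "longest >=80%-pyrimidine stretch between branchpoint and 3'ss",
        "ppt_scr": "pyrimidine fraction x length of the PPT",
        "agez_len": "AG-free gap upstream of the 3'ss AG",
        "dropped": [
            name
            for name, present in (
                ("nucleosome_occ", nucleosome is not None),
                ("tad_boundary_dist", tad_boundaries is not None),
            )
            if not present
        ],
    }
    return table, metadata


# ---------------------------------------------------------------------------
# logistic model


@dataclass
class ModelFit:
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    auc: float
    n_train: int
    n_test: int
    split_seed: int
    separation_flag: bool = False
    feature_names: list[str] = field(default_factory=list)


def fit_logistic(
    table: pd.DataFrame, split_seed: int = 0, test_size: float = 0.1
) -> ModelFit:
    """Binomial GLM with intercept on z-scored continuous features,
    evaluated by ROC AUC on a held-out stratified 10% split.

    Binary indicator columns are left unscaled so their coefficients
    stay on the log-odds-per-indicator scale; continuous columns are
    z-scored, making coefficients scale-invariant.  Perfect separation
    falls back to a ridge-stabilized fit with a warning flag.
    """
    feature_cols = [
        c for c in table.columns
        if c not in ("intron_id", "label") and pd.api.types.is_numeric_dtype(table[c])
    ]
    X = table[feature_cols].astype(float).copy()
    X = X.dropna(axis=1, how="any")
    feature_cols = list(X.columns)
    y = (table["label"] == "exonized").astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    for c in feature_cols:
        vals = X[c].to_numpy()
        if len(np.unique(vals)) > 2:
            sd = vals.std()
            X[c] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=split_seed, stratify=y
    )

    exog = sm.add_constant(X_train, has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y_train, exog, family=sm.families.Binomial()).fit(maxiter=100)
        params = res.params
        pvals = res.pvalues
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise PerfectSeparationError("diverged coefficients")
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        separation = True
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X_train, y_train)
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]),
            index=["const"] + feature_cols,
        )
        pvals = pd.Series(np.nan, index=params.index)

    exog_test = sm.add_constant(X_test, has_constant="add")[params.index]
    eta = exog_test.to_numpy() @ params.to_numpy()
    prob = expit(eta)
    auc = float(roc_auc_score(y_test, prob))
    return ModelFit(
        coefficients={k: float(v) for k, v in params.items()},
        pvalues={k: float(v) for k, v in pvals.items()},
        auc=auc,
        n_train=len(y_train),
        n_test=len(y_test),
        split_seed=split_seed,
        separation_flag=separation,
        feature_names=feature_cols,
    )
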