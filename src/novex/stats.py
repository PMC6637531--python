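"""Downstream statistics: gene-set enrichment against an expressed
background, polysome-engagement shifts, and cohort event-count deltas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Δψ bin edges for the engagement-shift analysis
DPSI_BINS = ((-np.inf, 0.0), (0.0, 0.05), (0.05, 0.15), (0.15, 0.3), (0.3, np.inf))
DPSI_LABELS = ("<=0", "(0,0.05]", "(0.05,0.15]", "(0.15,0.3]", ">0.3")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    K: int  # background genes in term
    N: int  # background size
    n: int  # query size
    k: int  # query genes in term
    p: float
    q: float = float("nan")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """GMT: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            sets[f[0]] = (f[1], set(f[2:]))
    return sets


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    query: set[str],
    background: set[str],
    gene_sets: Mapping[str, tuple[str, set[str]]],
    min_size: int = 5,
    max_size: int = 2000,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of query genes per term,
    BH-corrected across the retained terms.

    Gene sets are restricted to the background before the size filter;
    terms smaller than ``min_size`` or larger than ``max_size`` (after
    restriction) are excluded.
    """
    stray = query - background
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)[:10]}")
    N, n = len(background), len(query)
    results = []
    for term_id in sorted(gene_sets):
        name, members = gene_sets[term_id]
        in_bg = members & background
        K = len(in_bg)
        if not min_size <= K <= max_size:
            continue
        k = len(in_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, name, K, N, n, k, p))
    if results:
        qvals = bh_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                term_id=r.term_id, term_name=r.term_name, K=r.K, N=r.N,
                n=r.n, k=r.k, p=r.p, q=r.q,
            )
            for r in results
        ]
    )


def _normalized_change(pre: float, post: float) -> float:
    """(post − pre)/max(post, pre); 0 when both are 0."""
    m = max(pre, post)
    if m == 0:
        return 0.0
    return (post - pre) / m


def engagement_shift(
    expr: pd.DataFrame, dpsi: Mapping[str, float]
) -> pd.DataFrame:
    """Polysome-engagement shift per gene, binned by novel-exon Δψ.

    ``expr`` needs columns gene_id, total_pre, total_post, poly_pre,
    poly_post (TPM).  Per fraction Δ = (post − pre)/max(post, pre);
    shift = Δpoly − Δtotal.  Genes missing a Δψ are dropped.
    """
    rows = []
    for _, r in expr.iterrows():
        g = r["gene_id"]
        if g not in dpsi:
            continue
        d_total = _normalized_change(float(r["total_pre"]), float(r["total_post"]))
        d_poly = _normalized_change(float(r["poly_pre"]), float(r["poly_post"]))
        d = float(dpsi[g])
        label = None
        for (lo, hi), lab in zip(DPSI_BINS, DPSI_LABELS):
            if lo < d <= hi:
                label = lab
                break
        rows.append(
            dict(
                gene_id=g, delta_total=d_total, delta_poly=d_poly,
                shift=d_poly - d_total, dpsi=d, psi_increase_bin=label,
            )
        )
    return pd.DataFrame(rows)


def engagement_shift_summary(shift_table: pd.DataFrame) -> dict:
    """Median shift per Δψ bin plus a rank-sum between the extreme bins."""
    medians = {}
    for lab in DPSI_LABELS:
        vals = shift_table.loc[shift_table["psi_increase_bin"] == lab, "shift"]
        if len(vals):
            medians[lab] = float(vals.median())
    lo = shift_table.loc[shift_table["psi_increase_bin"] == DPSI_LABELS[0], "shift"]
    hi = shift_table.loc[shift_table["psi_increase_bin"] == DPSI_LABELS[-1], "shift"]
    p = float("nan")
    if len(lo) and len(hi):
        p = float(stats.ranksums(hi, lo).pvalue)
    return dict(bin_medians=medians, extreme_bins_p=p)


def cohort_event_delta(
    case_counts: Mapping[str, int] | Sequence[int],
    control_counts: Mapping[str, int] | Sequence[int],
) -> dict:
    """Per-case-sample percentage change in event counts vs the control
    median, with a rank-sum comparison of the two groups."""
    case = (
        dict(case_counts)
        if isinstance(case_counts, Mapping)
        else {f"case_{i + 1}": c for i, c in enumerate(case_counts)}
    )
    control = (
        list(control_counts.values())
        if isinstance(control_counts, Mapping)
        else list(control_counts)
    )
    med = float(np.median(control))
    if med == 0:
        return dict(percent_change={}, p_value=float("nan"), undefined=True)
    pct = {s: 100.0 * (c - med) / med for s, c in sorted(case.items())}
    stat, p = stats.ranksums(list(case.values()), control)
    return dict(
        percent_change=pct,
        median_control=med,
        statistic=float(stat),
        p_value=float(p),
        undefined=False,
    )
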