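"""Hypergeometric enrichment, BH correction, engagement shift and
cohort deltas."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from novex.simulate import simulate_cohort_counts, simulate_engagement_tables
from novex.stats import (
    bh_adjust,
    cohort_event_delta,
    engagement_shift,
    engagement_shift_summary,
    hypergeom_enrichment,
    read_gmt,
)


def _enrich_one(N, K, n, k, min_size=0, max_size=10**6):
    """Run one (N, K, n, k) instance through the enrichment machinery."""
    background = {f"g{i}" for i in range(N)}
    term = {f"g{i}" for i in range(K)}
    query = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
    assert len(query) == n
    results = hypergeom_enrichment(
        query, background, {"T": ("t", term)}, min_size=min_size, max_size=max_size
    )
    return results[0] if results else None


def test_hypergeometric_printed_example():
    r = _enrich_one(N=10, K=5, n=4, k=4)
    assert r.p == pytest.approx(comb(5, 4) * comb(5, 0) / comb(10, 4), abs=1e-12)


def test_hypergeometric_matches_exhaustive_enumeration_small_n():
    """All instances with N <= 12 agree with the tail sum computed by
    direct enumeration of C(K,j)·C(N−K,n−j)/C(N,n)."""
    for N in range(2, 13):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(max(0, n + K - N), min(n, K) + 1):
                    r = _enrich_one(N, K, n, k)
                    expected = sum(
                        comb(K, j) * comb(N - K, n - j)
                        for j in range(k, min(n, K) + 1)
                    ) / comb(N, n)
                    assert r.p == pytest.approx(expected, abs=1e-10), (N, K, n, k)


def test_term_size_filter():
    assert _enrich_one(N=20, K=4, n=5, k=3, min_size=5, max_size=2000) is None
    assert _enrich_one(N=20, K=5, n=5, k=3, min_size=5, max_size=2000) is not None
    background = {f"g{i}" for i in range(3000)}
    huge_term = set(list(background)[:2500])
    assert (
        hypergeom_enrichment(
            {"g0"}, background, {"T": ("t", huge_term)}, min_size=5, max_size=2000
        )
        == []
    )


def test_query_must_be_subset_of_background():
    with pytest.raises(ValueError, match="not in background"):
        hypergeom_enrichment({"x"}, {"a", "b"}, {})


def test_null_queries_never_significant_after_bh():
    """k at its independence expectation across 100 terms stays
    non-significant after BH."""
    rng = np.random.default_rng(0)
    N = 1000
    background = {f"g{i}" for i in range(N)}
    query = set(rng.choice(sorted(background), size=100, replace=False))
    gene_sets = {}
    for t in range(100):
        members = set(rng.choice(sorted(background), size=50, replace=False))
        gene_sets[f"T{t}"] = (f"term{t}", members)
    results = hypergeom_enrichment(query, background, gene_sets)
    assert len(results) == 100
    assert min(r.q for r in results) > 0.05


def test_bh_step_up_hand_computed():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_bh_matches_independent_step_up_oracle():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=37)
    q = bh_adjust(p)
    # independent step-up: q_(i) = min_{j>=i} p_(j)·m/j on sorted p
    order = np.argsort(p)
    m = len(p)
    expected_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    expected = np.empty(m)
    expected[order] = np.clip(expected_sorted, 0, 1)
    assert q == pytest.approx(expected, abs=1e-12)
    # permutation invariance
    perm = rng.permutation(m)
    assert bh_adjust(p[perm]) == pytest.approx(q[perm], abs=1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_read_gmt(tmp_path):
    p = tmp_path / "toy.gmt"
    p.write_text("T1\tfirst term\tg1\tg2\tg3\nT2\tsecond\tg2\tg4\n")
    sets = read_gmt(p)
    assert sets["T1"] == ("first term", {"g1", "g2", "g3"})
    assert sets["T2"][1] == {"g2", "g4"}


# ---------------------------------------------------------------------------
# engagement shift


def _expr_row(gene, tpre, tpost, ppre, ppost):
    return dict(
        gene_id=gene, total_pre=tpre, total_post=tpost, poly_pre=ppre, poly_post=ppost
    )


def test_engagement_shift_formula():
    expr = pd.DataFrame([_expr_row("g1", 100, 100, 100, 50)])
    table = engagement_shift(expr, {"g1": 0.2})
    row = table.iloc[0]
    assert row["delta_total"] == 0.0
    assert row["delta_poly"] == pytest.approx(-0.5)
    assert row["shift"] == pytest.approx(-0.5)
    assert row["psi_increase_bin"] == "(0.15,0.3]"


def test_engagement_shift_all_equal_is_zero_and_zero_tpm_defined():
    expr = pd.DataFrame(
        [_expr_row("g1", 7, 7, 7, 7), _expr_row("g2", 0, 0, 0, 0)]
    )
    table = engagement_shift(expr, {"g1": 0.0, "g2": 0.4})
    assert (table["shift"] == 0.0).all()


def test_engagement_shift_antisymmetric_under_pre_post_swap():
    rng = np.random.default_rng(1)
    rows = [
        _expr_row(f"g{i}", *rng.uniform(1, 100, size=4)) for i in range(50)
    ]
    expr = pd.DataFrame(rows)
    swapped = expr.rename(
        columns=dict(
            total_pre="total_post", total_post="total_pre",
            poly_pre="poly_post", poly_post="poly_pre",
        )
    )
    dpsi = {f"g{i}": 0.1 for i in range(50)}
    a = engagement_shift(expr, dpsi)["shift"].to_numpy()
    b = engagement_shift(swapped, dpsi)["shift"].to_numpy()
    assert np.allclose(a, -b, atol=1e-9)


def test_engagement_shift_genes_missing_dpsi_dropped():
    expr = pd.DataFrame([_expr_row("g1", 1, 2, 3, 4), _expr_row("g2", 1, 2, 3, 4)])
    table = engagement_shift(expr, {"g1": 0.1})
    assert list(table["gene_id"]) == ["g1"]


def test_planted_shift_gives_monotone_bin_medians():
    expr, dpsi = simulate_engagement_tables(n_genes=800, shift_slope=-0.3, seed=2)
    table = engagement_shift(expr, dpsi)
    summary = engagement_shift_summary(table)
    meds = summary["bin_medians"]
    ordered = [meds[k] for k in ("(0,0.05]", "(0.05,0.15]", "(0.15,0.3]", ">0.3")]
    assert all(a > b for a, b in zip(ordered, ordered[1:]))
    assert summary["extreme_bins_p"] < 1e-6


# ---------------------------------------------------------------------------
# cohorts


def test_cohort_delta_identity_and_half():
    out = cohort_event_delta([10, 10, 10], [10, 10, 10])
    assert all(v == 0.0 for v in out["percent_change"].values())
    out = cohort_event_delta([5, 5], [10, 10, 10])
    assert all(v == pytest.approx(-50.0) for v in out["percent_change"].values())


def test_cohort_delta_zero_control_median_flagged():
    out = cohort_event_delta([5], [0, 0, 0])
    assert out["undefined"] is True


def test_cohort_suppression_detected_across_seeds():
    hits = 0
    for seed in range(10):
        case, control = simulate_cohort_counts(
            n_per_group=20, suppression=0.5, seed=seed
        )
        out = cohort_event_delta(case, control)
        if out["p_value"] < 0.01:
            hits += 1
    assert hits >= 9
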