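"""Event calling: PSI, candidate enumeration, the six filters, repeat
overlap classification, and read-depth saturation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crafted import control_leak, crafted_candidates, toy_annotation
from novex.events import CRITERIA, ExonizationEvent
from novex.exonization import (
    apply_filters,
    call_events,
    classify_repeat_overlap,
    compute_psi,
    enumerate_candidates,
    saturation_curve,
)
from novex.simulate import SimConfig, generate_bundle
from novex.types import GenomicInterval, JunctionRecord


# ---------------------------------------------------------------------------
# PSI


@pytest.mark.parametrize(
    "i_up, i_down, e, expected",
    [(6, 4, 5, 0.5), (10, 10, 0, 1.0), (0, 0, 0, None), (0, 0, 7, 0.0)],
)
def test_compute_psi(i_up, i_down, e, expected):
    assert compute_psi(i_up, i_down, e) == expected


def test_compute_psi_rejects_negative_counts():
    with pytest.raises(ValueError):
        compute_psi(-1, 0, 0)


@settings(max_examples=200, deadline=None)
@given(
    i_up=st.integers(0, 500),
    i_down=st.integers(0, 500),
    e=st.integers(0, 500),
)
def test_psi_bounds_and_monotonicity(i_up, i_down, e):
    """PSI stays in [0,1], grows with inclusion and shrinks with
    exclusion reads."""
    psi = compute_psi(i_up, i_down, e)
    if psi is None:
        assert i_up + i_down + e == 0
        return
    assert 0.0 <= psi <= 1.0
    more_inc = compute_psi(i_up + 2, i_down, e)
    assert more_inc >= psi
    more_exc = compute_psi(i_up, i_down, e + 2)
    if psi > 0:
        assert more_exc < psi


# ---------------------------------------------------------------------------
# enumeration


def _records(sample_id, *intervals_counts):
    return [
        JunctionRecord(GenomicInterval("chrT", s, e, "+"), sample_id, c)
        for (s, e, c) in intervals_counts
    ]


def test_enumerate_pairs_junctions_within_host_intron():
    ann = toy_annotation()
    # host intron (200, 500): novel junctions (200, 300) and (400, 500)
    pert = {"s1": _records("s1", (200, 300, 8), (400, 500, 6), (200, 500, 4))}
    (cand,) = enumerate_candidates(pert, ann)
    assert cand.novel_exon == GenomicInterval("chrT", 300, 400, "+")
    assert (cand.i_up, cand.i_down, cand.e) == (8, 6, 4)
    assert cand.psi == pytest.approx(7 / 11)


def test_single_unpaired_junction_yields_no_candidate():
    ann = toy_annotation()
    pert = {"s1": _records("s1", (200, 300, 8))}
    assert enumerate_candidates(pert, ann) == []


def test_fixture_candidates_match_planted_coordinates(tmp_path):
    from novex.annotation_io import parse_gtf, read_junction_table

    config = SimConfig(seed=13, n_genes=6, n_plants=3)
    manifest = generate_bundle(config, tmp_path)
    ann = parse_gtf(tmp_path / "annotation.gtf")
    pert = {
        sid: read_junction_table(spec["path"], sid, ann)
        for sid, spec in manifest["samples"].items()
        if spec["condition"] == "perturbed"
    }
    candidates = enumerate_candidates(pert, ann)
    assert {(c.novel_exon.start, c.novel_exon.end) for c in candidates} == {
        tuple(p["novel_exon"]) for p in manifest["plants"]
    }


# ---------------------------------------------------------------------------
# the six filters


def test_each_crafted_candidate_fails_exactly_its_criterion():
    ann = toy_annotation()
    candidates = crafted_candidates()
    _, verdicts = apply_filters(list(candidates.values()), control_leak(), ann)
    by_exon = {ev.novel_exon.key(): ev for ev in verdicts}
    for criterion, crafted in candidates.items():
        ev = by_exon[crafted.novel_exon.key()]
        assert len(ev.verdicts) == len(CRITERIA)
        failed = [c for c, v in ev.verdicts.items() if not v.passed]
        assert failed == [criterion], f"{criterion}: failed {failed}"
        assert not ev.accepted


def test_planted_truth_recovery_sensitivity_one_fdr_zero(big_bundle):
    accepted, _ = call_events(
        big_bundle["perturbed"],
        big_bundle["control"],
        big_bundle["annotation"],
        big_bundle["repeats"],
    )
    planted = {tuple(p["novel_exon"]) for p in big_bundle["manifest"]["plants"]}
    got = {(ev.novel_exon.start, ev.novel_exon.end) for ev in accepted}
    assert got == planted


def test_accepted_events_recheck_criteria_three_and_four(called, annotation, junctions):
    from novex.exonization import aggregate_counts

    control_counts = aggregate_counts(junctions["control"])
    for ev in called["accepted"]:
        assert ev.upstream_junction not in annotation.catalog
        assert ev.downstream_junction not in annotation.catalog
        assert control_counts.get(ev.upstream_junction.key(), 0) == 0
        assert control_counts.get(ev.downstream_junction.key(), 0) == 0


def test_calling_is_order_independent(annotation, junctions, repeats):
    fwd, _ = call_events(
        junctions["perturbed"], junctions["control"], annotation, repeats
    )
    rev_pert = dict(reversed(list(junctions["perturbed"].items())))
    rev_ctrl = dict(reversed(list(junctions["control"].items())))
    rev, _ = call_events(rev_pert, rev_ctrl, annotation, repeats)
    assert [e.novel_exon.key() for e in fwd] == [e.novel_exon.key() for e in rev]


# ---------------------------------------------------------------------------
# repeat overlap


def _exon_event(start=300, end=400):
    return ExonizationEvent(
        gene_id="gA",
        host_intron=GenomicInterval("chrT", 200, 500, "+"),
        novel_exon=GenomicInterval("chrT", start, end, "+"),
        upstream_junction=GenomicInterval("chrT", 200, start, "+"),
        downstream_junction=GenomicInterval("chrT", end, 500, "+"),
        i_up=10, i_down=10, e=10, psi=0.5,
    )


@pytest.mark.parametrize(
    "repeat_end, expect_family",
    [(320, "AluSx"), (319, None)],  # 20/100 nt passes, 19/100 fails
)
def test_overlap_fraction_boundary(repeat_end, expect_family):
    ev = _exon_event(300, 400)
    repeats = [(GenomicInterval("chrT", 250, repeat_end, "+"), "AluSx")]
    classify_repeat_overlap(ev, repeats)
    if expect_family is None:
        assert ev.repeat_overlap is None
    else:
        assert ev.repeat_overlap.family == expect_family
        assert ev.repeat_overlap.repeat_class == "Alu"
        assert ev.repeat_overlap.overlap_fraction == pytest.approx(0.2)


def test_repeat_tie_break_largest_then_alphabetical():
    ev = _exon_event(300, 400)
    repeats = [
        (GenomicInterval("chrT", 300, 360, "+"), "L1MC4"),
        (GenomicInterval("chrT", 340, 400, "+"), "AluY"),  # same 60-nt overlap
        (GenomicInterval("chrT", 300, 340, "+"), "MIRb"),
    ]
    classify_repeat_overlap(ev, repeats)
    assert ev.repeat_overlap.family == "AluY"  # alphabetical among 60-nt ties
    ev2 = _exon_event(300, 400)
    classify_repeat_overlap(
        ev2, [(GenomicInterval("chrT", 300, 400, "+"), "MIRb")] + repeats
    )
    assert ev2.repeat_overlap.family == "MIRb"  # largest overlap wins
    assert ev2.repeat_overlap.repeat_class == "MIRb"


# ---------------------------------------------------------------------------
# saturation


def test_saturation_identity_fraction_recovers_everything(big_bundle):
    table = saturation_curve(
        big_bundle["perturbed"],
        big_bundle["control"],
        big_bundle["annotation"],
        big_bundle["repeats"],
        fractions=[1.0],
        seed=0,
    )
    assert table["percent_detected"].iloc[0] == 100.0


def test_saturation_rejects_bad_fractions(big_bundle):
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            saturation_curve(
                big_bundle["perturbed"],
                big_bundle["control"],
                big_bundle["annotation"],
                big_bundle["repeats"],
                fractions=[bad],
            )


def test_saturation_half_depth_recovery_at_depth_40(tmp_path):
    """With depth 40 and ψ*=0.5, p=0.5 keeps expected inclusion support
    at ~40 reads, far above threshold: recovery stays near 100%."""
    from novex.annotation_io import parse_gtf, read_junction_table, read_repeats

    config = SimConfig(seed=17, n_genes=6, n_plants=4, mean_depth=40, psi_values=(0.5,))
    manifest = generate_bundle(config, tmp_path)
    ann = parse_gtf(tmp_path / "annotation.gtf")
    pert, ctrl = {}, {}
    for sid, spec in manifest["samples"].items():
        recs = read_junction_table(spec["path"], sid, ann)
        (pert if spec["condition"] == "perturbed" else ctrl)[sid] = recs
    reps = read_repeats(tmp_path / "repeats.bed")
    recov = []
    for seed in range(20):
        table = saturation_curve(
            pert, ctrl, ann, reps, fractions=[0.5], seed=seed, repeat_class=None
        )
        recov.append(table["percent_detected"].iloc[0])
    assert sum(recov) / len(recov) >= 95.0
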