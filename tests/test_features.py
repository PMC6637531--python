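"""Splice-site PWMs, branch-region heuristics, feature extraction and
the logistic model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from novex.features import (
    BranchFeatures,
    fit_logistic,
    extract_features,
    score_branch_region,
    score_splice_site,
    train_pwm,
    train_pwm_from_sequences,
)
from novex.simulate import DONOR_CONSENSUS, simulate_logistic_table

RNG = np.random.default_rng(2024)
BASES = np.array(list("ACGT"))


def _random_seqs(n, length):
    return ["".join(RNG.choice(BASES, size=length)) for _ in range(n)]


# ---------------------------------------------------------------------------
# PWM


def test_consensus_training_set_maximizes_consensus_score():
    pwm = train_pwm_from_sequences("5ss", [DONOR_CONSENSUS] * 60)
    best = score_splice_site(pwm, DONOR_CONSENSUS)
    for seq in _random_seqs(200, 9):
        assert score_splice_site(pwm, seq) <= best + 1e-12


def test_uniform_random_training_gives_near_zero_log_odds():
    pwm = train_pwm_from_sequences("5ss", _random_seqs(10_000, 9))
    assert np.abs(pwm.log_odds).max() < 0.1


def test_annotated_sites_outscore_random_intronic_windows(annotation, genome):
    from novex.features import splice_site_windows

    pwm5, pwm3 = train_pwm(annotation, genome)
    five, three = splice_site_windows(annotation, genome)
    annotated = np.median([pwm5.score(s) for s in five])
    random_windows = _random_seqs(500, 9)
    background = np.median([pwm5.score(s) for s in random_windows])
    assert annotated - background > 2.0  # bits
    # GT at intron positions 4-5 of the donor window dominates
    assert pwm5.log_odds[3].argmax() == 2  # G
    assert pwm5.log_odds[4].argmax() == 3  # T
    assert pwm3.log_odds[18].argmax() == 0  # A of the 3'ss AG
    assert pwm3.log_odds[19].argmax() == 2  # G


def test_score_splice_site_contract():
    pwm = train_pwm_from_sequences("5ss", [DONOR_CONSENSUS] * 60)
    with pytest.raises(ValueError):
        score_splice_site(pwm, "ACGT")
    assert score_splice_site(pwm, "N" * 9) == 0.0


def test_score_equals_brute_force_positional_sum():
    pwm = train_pwm_from_sequences(
        "5ss", _random_seqs(200, 9)
    )
    index = {b: i for i, b in enumerate("ACGT")}
    for seq in _random_seqs(1000, 9):
        expected = sum(pwm.log_odds[i, index[b]] for i, b in enumerate(seq))
        assert score_splice_site(pwm, seq) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# branch region


def test_branch_region_finds_planted_motif_and_ppt():
    seq = "G" * 5 + "TACTAAC" + "C" * 20 + "AG"
    out = score_branch_region(seq)
    assert out.defined
    assert out.bp_num >= 1
    assert out.ppt_len >= 20
    assert out.bp_scr > 0
    assert out.agez_len == len(seq) - 2  # no upstream AG anywhere


def test_agez_measures_gap_to_nearest_upstream_ag():
    # ten C's between the upstream AG and the 3'ss AG (padded to >=23 nt)
    seq = "T" * 10 + "TAGCCCCCCCCCCAG"
    out = score_branch_region(seq)
    assert out.agez_len == 10


def test_poly_a_has_no_branch_matches_and_no_ppt():
    out = score_branch_region("A" * 40)
    assert out.bp_num == 0
    assert out.ppt_len == 0


def test_short_sequence_flagged_undefined():
    assert score_branch_region("TAGCCCCCCCCCCAG") == BranchFeatures(defined=False)


def test_branch_region_brute_force_count_oracle():
    """bp_num equals an independent regex-style scan for yUnAy."""
    import re

    rng = np.random.default_rng(5)
    for _ in range(20):
        seq = "".join(rng.choice(BASES, size=120))
        out = score_branch_region(seq)
        L = len(seq)
        expected = 0
        for m in re.finditer(r"(?=([CT]T.A[CT]))", seq):
            i = m.start() + 3  # branch A index
            if seq[i] == "A" and 20 <= L - i <= 500:
                expected += 1
        assert out.bp_num == expected


# ---------------------------------------------------------------------------
# feature extraction


def test_feature_table_labels_and_ranges(annotation, genome, called, expression, repeats):
    table, metadata = extract_features(
        annotation, genome, called["accepted"], expression, repeats
    )
    assert set(table["label"]) == {"exonized", "background"}
    assert (table["label"] == "exonized").sum() == len(called["accepted"])
    assert table["gc"].between(0, 1).all()
    assert table["relative_gene_position"].between(0, 1).all()
    assert (table["intron_length"] > 0).all()
    assert (table["tss_distance"] >= 0).all()
    assert "nucleosome_occ" in metadata["dropped"]
    # exonized host introns are the long, GC-rich, repeat-bearing ones
    by_label = table.groupby("label")
    assert by_label["intron_length"].mean()["exonized"] > by_label["intron_length"].mean()["background"]
    assert by_label["gc"].mean()["exonized"] > by_label["gc"].mean()["background"]
    assert by_label["transposon_overlap"].mean()["exonized"] == 1.0


def test_ss_dist_recovers_planted_exon_length(annotation, genome, called, expression, repeats, bundle):
    table, _ = extract_features(
        annotation, genome, called["accepted"], expression, repeats
    )
    exonized = table[table["label"] == "exonized"]
    # planted exons are 110 nt; the best internal acceptor/donor pair
    # should recover that span on the exonized host introns
    assert (exonized["ss_dist"] == 110).mean() >= 0.8


def test_tss_distance_strand_aware(annotation):
    for gene in annotation.genes.values():
        introns = sorted(gene.all_introns())
        if gene.strand == "+":
            first = introns[0]
            assert first.start - gene.span.start >= 0
        else:
            first = introns[-1]
            assert gene.span.end - first.end >= 0


# ---------------------------------------------------------------------------
# logistic model


def test_perfectly_separating_feature_gives_auc_one():
    n = 400
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-3, 0.1, n // 2), rng.normal(3, 0.1, n // 2)])
    table = pd.DataFrame(
        dict(
            intron_id=[f"i{j}" for j in range(n)],
            label=["background"] * (n // 2) + ["exonized"] * (n // 2),
            x=x,
        )
    )
    fit = fit_logistic(table, split_seed=0)
    assert fit.auc == 1.0


def test_labels_independent_of_features_gives_chance_auc():
    rng = np.random.default_rng(42)
    n = 2000
    table = pd.DataFrame(
        dict(
            intron_id=[f"i{j}" for j in range(n)],
            label=rng.choice(["exonized", "background"], size=n),
            a=rng.normal(size=n),
            b=rng.normal(size=n),
        )
    )
    fit = fit_logistic(table, split_seed=1)
    assert abs(fit.auc - 0.5) < 0.1


def test_feature_scaling_invariance():
    table = simulate_logistic_table(3000, coef_transposon=1.5, seed=3)
    fit1 = fit_logistic(table, split_seed=0)
    scaled = table.copy()
    scaled["gc"] = scaled["gc"] * 1000.0
    fit2 = fit_logistic(scaled, split_seed=0)
    assert fit1.coefficients["gc"] == pytest.approx(fit2.coefficients["gc"], abs=1e-6)
    assert fit1.pvalues["gc"] == pytest.approx(fit2.pvalues["gc"], abs=1e-6)


def test_planted_coefficient_recovery_across_seeds():
    """Planted transposon log-odds of 2.0 recovered within ±0.3 with
    p < 0.01 in at least 9 of 10 seeds (n = 5000)."""
    hits = 0
    for seed in range(10):
        table = simulate_logistic_table(5000, coef_transposon=2.0, seed=seed)
        fit = fit_logistic(table, split_seed=seed)
        coef = fit.coefficients["transposon_overlap"]
        p = fit.pvalues["transposon_overlap"]
        if abs(coef - 2.0) <= 0.3 and p < 0.01 and fit.auc > 0.7:
            hits += 1
    assert hits >= 9


def test_model_auc_not_below_best_single_feature(annotation, genome, called, expression, repeats):
    table, _ = extract_features(
        annotation, genome, called["accepted"], expression, repeats
    )
    full = fit_logistic(table, split_seed=0)
    for feature in ("intron_length", "gc", "transposon_overlap"):
        single = fit_logistic(
            table[["intron_id", "label", feature]], split_seed=0
        )
        assert full.auc >= single.auc - 0.02
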