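"""Scanner unit tests: regularization, log-odds, exact DP, strand logic."""

import numpy as np
import pytest

from grnrewire.io_formats import PWM
from grnrewire.motif_scanning import (
    ScanConfig,
    log_odds,
    regularize,
    reverse_complement,
    scan_peak,
    score_distribution,
)

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def point_mass(consensus: str) -> PWM:
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return PWM("PM", ("PM",), mat)


def enumerate_int_distribution(int_matrix, background):
    """Oracle: exact distribution of the integer window score by listing
    all 4^w words."""
    w = int_matrix.shape[0]
    radix = 4 ** np.arange(w - 1, -1, -1)
    codes = (np.arange(4**w)[:, None] // radix) % 4
    scores = int_matrix[np.arange(w)[None, :], codes].sum(axis=1)
    probs = np.asarray(background)[codes].prod(axis=1)
    out = {}
    for q, p in zip(scores, probs):
        out[int(q)] = out.get(int(q), 0.0) + float(p)
    return out


# ------------------------------------------------------------- regularize


def test_regularize_identity_at_zero_pseudocount():
    pwm = PWM("m", ("t",), np.full((3, 4), 0.25))
    cfg = ScanConfig(pseudocount=0.0)
    np.testing.assert_array_equal(regularize(pwm, cfg).probabilities,
                                  pwm.probabilities)


def test_regularize_closed_form_on_point_mass_row():
    pwm = point_mass("A")
    cfg = ScanConfig(pseudocount=0.01)
    row = regularize(pwm, cfg).probabilities[0]
    np.testing.assert_allclose(
        row, np.array([1.0025, 0.0025, 0.0025, 0.0025]) / 1.01, rtol=1e-12
    )


def test_regularized_rows_sum_to_one():
    rng = np.random.default_rng(0)
    pwm = PWM("m", ("t",), rng.dirichlet(np.ones(4), size=7))
    reg = regularize(pwm, ScanConfig(pseudocount=0.37))
    np.testing.assert_allclose(reg.probabilities.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------- log_odds


def test_log_odds_zero_when_model_equals_background():
    pwm = PWM("m", ("t",), np.full((4, 4), 0.25))
    np.testing.assert_allclose(log_odds(pwm, ScanConfig()), 0.0, atol=1e-12)


def test_log_odds_two_bits_for_certain_base_uniform_background():
    pwm = point_mass("G")
    s = log_odds(pwm, ScanConfig(pseudocount=0.0))
    assert s[0, 2] == pytest.approx(2.0)


def test_log_odds_satisfies_moment_identity():
    # sum_x b[x] * 2^{s[i][x]} = 1 for every position
    rng = np.random.default_rng(1)
    bg = tuple(rng.dirichlet(np.ones(4)))
    pwm = PWM("m", ("t",), rng.dirichlet(np.ones(4), size=5))
    cfg = ScanConfig(pseudocount=0.05, background=bg)
    s = log_odds(regularize(pwm, cfg), cfg)
    moments = (np.asarray(bg)[None, :] * np.exp2(s)).sum(axis=1)
    np.testing.assert_allclose(moments, 1.0, atol=1e-10)


# ------------------------------------------------------ score_distribution


def test_single_position_point_mass_pvalue_is_quarter():
    cfg = ScanConfig(pseudocount=0.01)
    reg = regularize(point_mass("A"), cfg)
    s = log_odds(reg, cfg)
    dist = score_distribution(s, UNIFORM, cfg.granularity)
    top = dist.max_score
    assert dist.pvalue_int(top) == pytest.approx(0.25, abs=1e-12)
    assert dist.probs[-1] == pytest.approx(0.25, abs=1e-12)


def test_pvalue_at_minimum_achievable_score_is_one():
    rng = np.random.default_rng(5)
    cfg = ScanConfig()
    reg = regularize(PWM("m", ("t",), rng.dirichlet(np.ones(4), size=4)), cfg)
    dist = score_distribution(log_odds(reg, cfg), UNIFORM)
    assert dist.pvalue_int(dist.min_score) == pytest.approx(1.0, abs=1e-9)


def test_dp_matches_enumeration_for_small_widths():
    rng = np.random.default_rng(9)
    cfg = ScanConfig()
    for w in (1, 2, 3, 5):
        bg = tuple(rng.dirichlet(np.full(4, 2.0)))
        cfg_w = ScanConfig(background=bg)
        reg = regularize(PWM("m", ("t",), rng.dirichlet(np.ones(4), size=w)), cfg_w)
        dist = score_distribution(log_odds(reg, cfg_w), bg)
        oracle = enumerate_int_distribution(dist.int_matrix, bg)
        for q, p in oracle.items():
            idx = q - dist.min_score
            assert dist.probs[idx] == pytest.approx(p, abs=1e-9)


def test_probability_mass_sums_to_one():
    rng = np.random.default_rng(12)
    reg = regularize(PWM("m", ("t",), rng.dirichlet(np.ones(4), size=9)), ScanConfig())
    dist = score_distribution(log_odds(reg, ScanConfig()), UNIFORM)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)


def test_oversized_grid_rejected_with_granularity_advice():
    reg = regularize(point_mass("ACGTACGTAC"), ScanConfig())
    with pytest.raises(ValueError, match="granularity"):
        score_distribution(log_odds(reg, ScanConfig()), UNIFORM,
                           granularity=1e-9, max_grid_cells=10**6)


def test_infinite_scores_rejected():
    s = log_odds(point_mass("AC"), ScanConfig(pseudocount=0.0))
    with pytest.raises(ValueError, match="regularize"):
        score_distribution(s, UNIFORM)


# ---------------------------------------------------------------- scanning


def test_consensus_sequence_yields_single_plus_hit_with_analytic_pvalue():
    # non-palindromic consensus, otherwise the '-' strand hit is real too
    pwm = point_mass("AACGTACG")
    cfg = ScanConfig(alpha=1e-4)
    hits = scan_peak("AACGTACG", pwm, cfg, "pk")
    assert len(hits) == 1
    (h,) = hits
    assert (h.offset, h.strand) == (0, "+")
    assert h.pvalue == pytest.approx(4.0**-8, rel=1e-9)


def test_reverse_complemented_sequence_gives_mirror_hits():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    pwm = point_mass("ACGTAACGT")
    seq = seq[:100] + "ACGTAACGT" + seq[100:]
    cfg = ScanConfig(alpha=1e-3)
    fwd = scan_peak(seq, pwm, cfg, "pk")
    rev = scan_peak(reverse_complement(seq), pwm, cfg, "pk")
    w, L = pwm.width, len(seq)
    mirrored = sorted(
        (L - w - h.offset, {"+": "-", "-": "+"}[h.strand], round(h.score, 6),
         h.pvalue)
        for h in rev
    )
    assert mirrored == sorted(
        (h.offset, h.strand, round(h.score, 6), h.pvalue) for h in fwd
    )
    assert len(fwd) >= 2  # planted site seen on both strands


def test_all_n_sequence_yields_no_hits():
    assert scan_peak("N" * 50, point_mass("ACGT"), ScanConfig(), "pk") == []


def test_windows_overlapping_n_are_skipped_but_others_scanned():
    pwm = point_mass("ACGT")
    cfg = ScanConfig(alpha=0.5)
    hits = scan_peak("ACGTNACGT", pwm, cfg, "pk")
    offsets = {h.offset for h in hits if h.strand == "+"}
    assert 0 in offsets and 5 in offsets
    assert not any(1 <= o <= 4 for o in offsets)


def test_lowering_alpha_never_adds_hits():
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    pwm = PWM("m", ("t",), rng.dirichlet(np.full(4, 0.6), size=6))
    loose = {(h.offset, h.strand) for h in scan_peak(seq, pwm, ScanConfig(alpha=1e-2), "pk")}
    tight = {(h.offset, h.strand) for h in scan_peak(seq, pwm, ScanConfig(alpha=1e-3), "pk")}
    assert tight <= loose


def test_sequence_shorter_than_motif_yields_nothing():
    assert scan_peak("ACG", point_mass("ACGTA"), ScanConfig(), "pk") == []
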