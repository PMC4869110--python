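"""PWM scoring, genome scanning against a brute-force oracle, selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucfoot.io import Track
from nucfoot.motif_scan import (MotifInstance, Pwm, annotate_covariates,
                                scan_genome, score_pwm, select_instances)
from nucfoot.simulate import make_informative_pwm

REVCOMP = str.maketrans("ACGT", "TGCA")


def brute_force_scan(genome, pwm, min_score):
    """Independent reference scanner: score every window on both strands,
    then apply the same dedup rule (highest score; ties '+', then leftmost)
    with a quadratic sweep."""
    L = len(pwm)
    cand = []
    for chrom, seq in genome.items():
        for i in range(len(seq) - L + 1):
            win = seq[i:i + L]
            s = score_pwm(win, pwm)
            if s > min_score:
                cand.append((chrom, i, "+", s))
            s = score_pwm(win.translate(REVCOMP)[::-1], pwm)
            if s > min_score:
                cand.append((chrom, i, "-", s))
    cand.sort(key=lambda t: (-round(t[3], 6), t[2] != "+", t[1], t[0]))
    kept = []
    for c in cand:
        if not any(k[0] == c[0] and abs(k[1] - c[1]) < L for k in kept):
            kept.append(c)
    return sorted(kept)


class TestScorePwm:
    def test_uniform_pwm_scores_zero(self, uniform_pwm):
        assert score_pwm("ACGTAC", uniform_pwm) == pytest.approx(0.0)

    def test_consensus_approaches_two_bits_per_position(self, simple_pwm):
        # counts of 100 with pseudocount 0.5: log2((100.5/102)/0.25) per base
        expected = 7 * np.log2((100.5 / 102.0) / 0.25)
        assert score_pwm("ACGTACG", simple_pwm) == pytest.approx(expected)
        assert expected == pytest.approx(14.0, abs=0.25)

    def test_score_is_log2_likelihood_ratio(self, rng):
        """Score equals log2 P(window|PWM) / P(window|uniform) directly."""
        pwm = make_informative_pwm(length=8, seed=3)
        idx = {b: i for i, b in enumerate("ACGT")}
        window = "".join(rng.choice(list("ACGT"), 8))
        lik = np.prod([pwm.probs[i, idx[b]] for i, b in enumerate(window)])
        assert score_pwm(window, pwm) == pytest.approx(np.log2(lik / 0.25 ** 8))

    def test_threshold_thirteen_is_8192x_over_chance(self, simple_pwm):
        """A 13-bit score certifies a 2^13 = 8192-fold likelihood ratio."""
        s = score_pwm("ACGTACG", simple_pwm)
        assert 2.0 ** s > 8192

    def test_ambiguous_base_scores_mean_of_compatible(self, simple_pwm):
        sN = score_pwm("NCGTACG", simple_pwm)
        s_each = [score_pwm(b + "CGTACG", simple_pwm) for b in "ACGT"]
        # per spec, N contributes log2(mean p / 0.25), not mean of logs
        rest = sum(np.log2(simple_pwm.probs[i + 1, j] / 0.25)
                   for i, j in enumerate([1, 2, 3, 0, 1, 2]))
        assert sN == pytest.approx(rest + np.log2(simple_pwm.probs[0].mean() / 0.25))
        assert sN < max(s_each)

    def test_length_mismatch_rejected(self, simple_pwm):
        with pytest.raises(ValueError, match="length"):
            score_pwm("ACGT", simple_pwm)


class TestScanGenome:
    def test_planted_consensus_found_at_exact_coordinate(self, simple_pwm, rng):
        bg = "".join(rng.choice(list("AT"), 500))  # GC-poor: no spurious hits
        genome = {"chr1": bg[:200] + "ACGTACG" + bg[200:]}
        hits = scan_genome(genome, simple_pwm, min_score=13.0)
        assert [(h.start, h.strand) for h in hits] == [(200, "+")]

    def test_scan_equals_brute_force_oracle(self, rng):
        pwm = make_informative_pwm(length=10, dominance=0.7, seed=11)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}
        got = sorted((h.chrom, h.start, h.strand, round(h.pwm_score, 9))
                     for h in scan_genome(genome, pwm, min_score=5.0))
        want = [(c, i, s, round(v, 9))
                for c, i, s, v in brute_force_scan(genome, pwm, 5.0)]
        assert got == want

    def test_strict_inequality_at_threshold(self, uniform_pwm):
        """A window scoring exactly the threshold is excluded."""
        genome = {"chr1": "ACGTACGTACGT"}
        assert scan_genome(genome, uniform_pwm, min_score=0.0) == []

    def test_reverse_complement_symmetry(self, rng):
        pwm = make_informative_pwm(length=9, seed=2)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        rc = seq.translate(REVCOMP)[::-1]
        fwd = scan_genome({"chr1": seq}, pwm, min_score=8.0)
        rev = scan_genome({"chr1": rc}, pwm.reverse_complement(), min_score=8.0)
        n = len(seq)
        # coordinates mirror; strand labels persist (score of the rc-PWM on
        # the rc-window equals the original score in the same orientation)
        mirrored = sorted((n - h.end, h.strand, round(h.pwm_score, 9))
                          for h in rev)
        assert mirrored == sorted((h.start, h.strand, round(h.pwm_score, 9))
                                  for h in fwd)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.floats(6.0, 14.0))
    def test_selection_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(77)
        pwm = make_informative_pwm(length=8, seed=5)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 8000))}
        base = {(h.start, h.strand) for h in scan_genome(genome, pwm, min_score=6.0)}
        higher = {(h.start, h.strand) for h in scan_genome(genome, pwm, min_score=thr)}
        assert higher <= base


def _inst(score, mapp):
    m = MotifInstance("chr1", 1000, 1012, "+", score)
    m.mappability = mapp
    m.gc_flank = 0.5
    m.cons_score = 0.5
    return m


class TestSelectInstances:
    def test_primary_keeps_top_quintile(self):
        insts = [_inst(float(s), 1.0) for s in range(100)]
        kept = select_instances(insts, mode="primary")
        assert sorted(i.pwm_score for i in kept) == [float(s) for s in range(80, 100)]

    def test_primary_mappability_cutoff(self):
        insts = [_inst(20.0, 0.98)] + [_inst(float(s), 1.0) for s in range(10)]
        kept = select_instances(insts, mode="primary")
        assert all(i.mappability >= 0.99 for i in kept)

    def test_quintile_boundary_ties_all_kept(self):
        insts = [_inst(10.0, 1.0) for _ in range(10)]
        assert len(select_instances(insts, mode="primary")) == 10

    def test_extended_mode_score_and_mappability_rules(self):
        a, b = _inst(14.2, 0.93), _inst(13.9, 0.93)
        kept = select_instances([a, b], mode="extended")
        assert kept == [a]

    def test_ctcf_relaxed_keeps_thirteen_and_up(self):
        a, b = _inst(13.0, 1.0), _inst(12.9, 1.0)
        kept = select_instances([a, b], mode="ctcf-relaxed")
        assert kept == [a]

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            assert select_instances([], mode="primary") == []


class TestAnnotateCovariates:
    def test_all_gc_flanks(self):
        unit = "G" * 200 + "ATATATATATAT" + "C" * 200  # 412 bp
        genome = {"chr1": unit * 6}
        inst = MotifInstance("chr1", 3 * 412 + 200, 3 * 412 + 212, "+", 15.0)
        out = annotate_covariates([inst], genome, window=400)
        assert out[0].gc_flank == pytest.approx(1.0)

    def test_constant_conservation(self):
        genome = {"chr1": "ACGT" * 600}
        cons = Track({"chr1": np.full(2400, 0.8)})
        inst = MotifInstance("chr1", 1200, 1212, "+", 15.0)
        out = annotate_covariates([inst], genome, conservation=cons, window=400)
        assert out[0].cons_score == pytest.approx(0.8)

    def test_block_mean_gc_equals_hand_computation(self):
        # 20 bp toy flanks around a 4 bp motif, flank=20, block=5
        left, right = "GGGGGATATACCCCCGGGGG", "AAAAATTTTTGCGCGATATA"
        genome = {"chr1": "A" * 500 + left + "ACGT" + right + "A" * 500}
        inst = MotifInstance("chr1", 520, 524, "+", 10.0)
        out = annotate_covariates([inst], genome, flank=20, window=40, block=5)
        blocks = [left[i:i + 5] for i in range(0, 20, 5)] + \
                 [right[i:i + 5] for i in range(0, 20, 5)]
        hand = np.mean([sum(c in "GC" for c in b) / 5 for b in blocks])
        assert out[0].gc_flank == pytest.approx(hand)

    def test_edge_instances_dropped_with_warning(self):
        genome = {"chr1": "ACGT" * 100}
        inst = MotifInstance("chr1", 2, 10, "+", 10.0)
        with pytest.warns(UserWarning, match="dropped"):
            assert annotate_covariates([inst], genome) == []
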