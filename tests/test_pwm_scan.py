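import itertools
import math

import numpy as np
import pytest

from dualsite.core_io import BASE_INDEX, PWM, ValidationError
from dualsite.pwm_scan import (
    core_positions,
    core_similarity,
    information_vector,
    matrix_similarity,
    reverse_complement,
    scan_sequence,
)


def brute_mss(pwm: PWM, window: str, lo: int | None = None, hi: int | None = None) -> float:
    """Independent straight-from-the-definition similarity score."""
    f = pwm.freqs
    L = len(pwm)
    lo, hi = (0 if lo is None else lo), (L if hi is None else hi)
    info = [
        sum(f[i, b] * math.log(4 * f[i, b]) if f[i, b] > 0 else 0.0 for b in range(4))
        for i in range(L)
    ]
    cur = sum(info[i] * f[i, BASE_INDEX[window[i]]] for i in range(lo, hi))
    mx = sum(info[i] * f[i].max() for i in range(lo, hi))
    mn = sum(info[i] * f[i].min() for i in range(lo, hi))
    return 0.0 if mx == mn else (cur - mn) / (mx - mn)


class TestInformationVector:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # uninformative column
            ((1.0, 0.0, 0.0, 0.0), math.log(4)),  # fully conserved column
            ((0.5, 0.5, 0.0, 0.0), math.log(2)),  # 2*0.5*ln2, hand arithmetic
        ],
    )
    def test_single_column_values(self, row, expected):
        iv = information_vector(PWM("p", np.array([row])))
        assert iv.values[0] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_ln4(self, rng):
        freqs = rng.dirichlet(np.ones(4), size=20)
        vals = information_vector(PWM("p", freqs)).values
        assert ((vals >= -1e-12) & (vals <= math.log(4) + 1e-12)).all()


class TestMatrixSimilarity:
    def test_consensus_scores_one(self, toy_pwm):
        consensus = toy_pwm.consensus
        assert matrix_similarity(toy_pwm, consensus) == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self, toy_pwm):
        anti = "".join("ACGT"[i] for i in toy_pwm.freqs.argmin(axis=1))
        assert matrix_similarity(toy_pwm, anti) == pytest.approx(0.0, abs=1e-12)

    def test_all_256_windows_match_brute_force(self, toy_pwm):
        for w in itertools.product("ACGT", repeat=4):
            w = "".join(w)
            got = matrix_similarity(toy_pwm, w)
            assert got == pytest.approx(brute_mss(toy_pwm, w), abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_degenerate_uniform_matrix_scores_zero(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        assert matrix_similarity(pwm, "ACGT") == 0.0

    def test_length_mismatch_rejected(self, toy_pwm):
        with pytest.raises(ValidationError):
            matrix_similarity(toy_pwm, "ACGTT")


class TestCoreSimilarity:
    def test_short_matrix_core_is_whole_matrix(self, toy_pwm):
        for w in ("ACGT", "TTTT", "CAGT"):
            assert core_similarity(toy_pwm, w) == pytest.approx(
                matrix_similarity(toy_pwm, w)
            )

    def test_tie_broken_leftmost(self):
        # two equal-information 5-mers: positions 0-4 and 3-7 both contain
        # the same conserved columns pattern; verified against trying both
        col_hi = [0.97, 0.01, 0.01, 0.01]
        col_lo = [0.25, 0.25, 0.25, 0.25]
        freqs = np.array([col_hi, col_hi, col_lo, col_hi, col_hi, col_lo, col_hi, col_hi])
        pwm = PWM("tie", freqs)
        info = information_vector(pwm).values
        sums = np.convolve(info, np.ones(5), "valid")
        ties = np.flatnonzero(np.isclose(sums, sums.max()))
        assert len(ties) > 1  # the fixture really is tied
        assert core_positions(pwm) == (int(ties[0]), int(ties[0]) + 5)
        window = "AAAAAAAA"
        scores = [brute_mss(pwm, window, s, s + 5) for s in ties]
        assert core_similarity(pwm, window) == pytest.approx(scores[0])

    def test_consensus_core_scores_one(self, rng):
        freqs = rng.dirichlet(np.ones(4) * 0.4, size=9)
        pwm = PWM("p9", freqs)
        assert core_similarity(pwm, pwm.consensus) == pytest.approx(1.0)


class TestScan:
    def embed(self, rng, site, length=200, at=80):
        seq = "".join(rng.choice(list("ACGT"), length))
        return seq[:at] + site + seq[at + len(site):]

    def test_planted_consensus_recovered_at_its_offset(self, rng):
        freqs = np.full((8, 4), 0.04)
        freqs[np.arange(8), [0, 1, 2, 3, 0, 1, 2, 3]] = 0.88
        pwm = PWM("strong", freqs)
        seq = self.embed(rng, pwm.consensus)
        hits = [h for h in scan_sequence(pwm, seq, 0.75, 0.85) if h.strand == "+"]
        assert any(h.start == 80 and h.matrix_score == pytest.approx(1.0) for h in hits)

    def test_one_mismatch_site_fails_perfect_cutoffs(self, rng):
        freqs = np.full((8, 4), 0.04)
        freqs[np.arange(8), [0, 1, 2, 3, 0, 1, 2, 3]] = 0.88
        pwm = PWM("strong", freqs)
        site = "C" + pwm.consensus[1:]
        seq = self.embed(rng, site)
        assert scan_sequence(pwm, seq, 1.0, 1.0) == []

    def test_hits_match_exhaustive_oracle_both_strands(self, rng):
        freqs = rng.dirichlet(np.ones(4) * 0.5, size=8)
        pwm = PWM("p8", freqs)
        seq = "".join(rng.choice(list("ACGT"), 200))
        expected = set()
        cs, ce = core_positions(pwm)
        for i in range(len(seq) - 7):
            for strand in "+-":
                w = seq[i : i + 8] if strand == "+" else reverse_complement(seq[i : i + 8])
                if brute_mss(pwm, w, cs, ce) >= 0.6 and brute_mss(pwm, w) >= 0.7:
                    expected.add((i, strand, round(brute_mss(pwm, w), 10)))
        got = {
            (h.start, h.strand, round(h.matrix_score, 10))
            for h in scan_sequence(pwm, seq, 0.6, 0.7)
        }
        assert got == expected

    def test_raising_cutoffs_never_adds_hits(self, rng):
        freqs = rng.dirichlet(np.ones(4) * 0.5, size=6)
        pwm = PWM("p6", freqs)
        seq = "".join(rng.choice(list("ACGT"), 300))
        loose = {(h.start, h.strand) for h in scan_sequence(pwm, seq, 0.5, 0.6)}
        tight = {(h.start, h.strand) for h in scan_sequence(pwm, seq, 0.7, 0.8)}
        assert tight <= loose

    def test_reverse_complement_scan_mirrors_hits(self, rng):
        freqs = rng.dirichlet(np.ones(4) * 0.5, size=7)
        pwm = PWM("p7", freqs)
        seq = "".join(rng.choice(list("ACGT"), 150))
        fwd = scan_sequence(pwm, seq, 0.6, 0.7)
        rev = scan_sequence(pwm, reverse_complement(seq), 0.6, 0.7)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - (h.start + 7), flip[h.strand], round(h.matrix_score, 9))
            for h in fwd
        )
        assert mirrored == sorted(
            (h.start, h.strand, round(h.matrix_score, 9)) for h in rev
        )

    def test_windows_with_n_skipped(self, toy_pwm):
        hits = scan_sequence(toy_pwm, "NNNN" + toy_pwm.consensus, 0.0, 0.0)
        assert all(h.start >= 1 for h in hits)
        assert not any("N" in h.sequence for h in hits)

    def test_region_shorter_than_matrix_is_empty(self, toy_pwm):
        assert scan_sequence(toy_pwm, "AC", 0.5, 0.5) == []
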