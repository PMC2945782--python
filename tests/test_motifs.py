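"""PWM parsing, log-odds construction and promoter scanning oracles."""

import numpy as np
import pytest

from adiporeg.motifs import (
    CONSERVATION_MODES,
    PWM,
    best_hit,
    parse_pwm_collection,
    scan_promoters,
    top3_mean,
)
from conftest import make_promoter, random_count_pwm, random_promoter

JASPAR_TEXT = """\
>MA0001.1 TEST1
A [ 4 19 0 0 0 0 0 2 ]
C [16 0 20 0 0 0 0 3 ]
G [ 0 1 0 20 0 20 0 5 ]
T [ 0 0 0 0 20 0 20 10 ]
>MA0002.1 TEST2
A [ 1 2 3 ]
C [ 4 5 6 ]
G [ 7 8 9 ]
T [10 11 12 ]
"""

TRANSFAC_TEXT = """\
AC  M00001
XX
ID  V$TEST_01
XX
DE  test matrix
P0      A      C      G      T
01      1      2      2      0      S
02      2      1      2      0      R
03      3      0      1      1      A
04      0      5      0      0      C
05      5      0      0      0      A
XX
//
"""


class TestParsing:
    def test_jaspar_collection_shapes_and_counts(self):
        pwms = parse_pwm_collection(JASPAR_TEXT, "jaspar")
        assert [p.motif_id for p in pwms] == ["MA0001.1", "MA0002.1"]
        assert pwms[0].width == 8 and pwms[1].width == 3
        assert pwms[0].counts[1, 0] == 16  # C count preserved exactly
        assert pwms[1].counts[3, 2] == 12

    def test_transfac_block_width(self):
        (pwm,) = parse_pwm_collection(TRANSFAC_TEXT, "transfac")
        assert pwm.width == 5
        assert pwm.counts[0, 4] == 5  # A column of row 05

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            parse_pwm_collection(JASPAR_TEXT, "meme")

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            parse_pwm_collection(JASPAR_TEXT.replace("A [ 4", "A [ -4"), "jaspar")

    def test_transfac_frequency_matrix_rescaled(self):
        freq = TRANSFAC_TEXT
        for old, new in [("1      2      2      0", "0.2    0.4    0.4    0.0"),
                         ("2      1      2      0", "0.4    0.2    0.4    0.0"),
                         ("3      0      1      1", "0.6    0.0    0.2    0.2"),
                         ("0      5      0      0", "0.0    1.0    0.0    0.0"),
                         ("5      0      0      0", "1.0    0.0    0.0    0.0")]:
            freq = freq.replace(old, new)
        (pwm,) = parse_pwm_collection(freq, "transfac")
        assert np.allclose(pwm.counts.sum(axis=0), 100.0)


class TestLogOdds:
    def test_single_column_hand_example(self):
        pwm = PWM("x", np.array([[2.0], [0.0], [0.0], [0.0]]), pseudocount=0.25)
        lo = pwm.log_odds()
        assert lo[0, 0] == pytest.approx(np.log2((2.25 / 3) / 0.25))
        assert lo[0, 0] == pytest.approx(np.log2(3), rel=1e-12)

    def test_uninformative_matrix_scores_zero(self):
        pwm = PWM("x", np.full((4, 3), 5.0))
        assert np.allclose(pwm.log_odds(), 0.0)

    def test_column_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        pwm = random_count_pwm(rng, 6)
        assert np.allclose(pwm.frequencies().sum(axis=0), 1.0)

    def test_zero_column_needs_pseudocount(self):
        with pytest.raises(ValueError):
            PWM("x", np.zeros((4, 2)), pseudocount=0.0)


# --- independent naive scanner oracle ------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _score_window(window, lo):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return sum(lo[idx[b], j] for j, b in enumerate(window))


def _naive_all_scores(seq, lo):
    """Every (offset, strand) candidate score by direct enumeration.

    The reverse-strand score of a window is the score of its reverse
    complement; enumerated per position so each base's matrix column is
    looked up explicitly.
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = lo.shape[1]
    out = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        fwd = np.sum(np.array([lo[idx[b], j] for j, b in enumerate(window)]))
        rev = np.sum(
            np.array([lo[idx[_COMP[b]], w - 1 - j] for j, b in enumerate(window)])
        )
        out.append((off, "+", float(fwd)))
        out.append((off, "-", float(rev)))
    return out

def _naive_best(seq, cons, lo, threshold):
    w = lo.shape[1]
    best = None
    for off, strand, s in _naive_all_scores(seq, lo):
        if min(cons[off : off + w]) < threshold:
            continue
        if best is None or s > best[2]:
            best = (off, strand, s)
    return best


class TestScannerOracle:
    def test_best_hit_and_top3_match_naive_enumeration(self):
        """Exact agreement with a direct O(L*w) double-strand enumeration."""
        rng = np.random.default_rng(202)
        for _ in range(200):
            L = int(rng.integers(20, 80))
            w = int(rng.integers(4, min(12, L) + 1))
            prom = random_promoter(rng, L)
            pwm = random_count_pwm(rng, w)
            lo = pwm.log_odds()
            threshold = float(rng.choice([0.0, 0.3, 0.6]))
            naive = _naive_best(prom.sequence, prom.conservation, lo, threshold)
            score, hit = best_hit(prom, pwm, threshold)
            if naive is None:
                assert not score.eligible and hit is None
            else:
                assert hit.score_bits == naive[2]
                assert score.score == pwm.normalize(naive[2])
            # top-3 averaging against full enumeration
            all_scores = sorted(
                (s for _, _, s in _naive_all_scores(prom.sequence, lo)),
                reverse=True,
            )
            expected = float(np.mean(all_scores[:3]))
            assert top3_mean(prom, pwm).score == pwm.normalize(expected)

    def test_agrees_with_biopython_pssm(self):
        """Raw log-odds profile matches Bio.motifs' PSSM calculation."""
        from Bio.Seq import Seq
        from Bio.motifs import Motif
        from Bio.motifs.matrix import FrequencyPositionMatrix

        rng = np.random.default_rng(55)
        prom = random_promoter(rng, 60)
        pwm = random_count_pwm(rng, 8)
        counts = {b: list(pwm.counts[i]) for i, b in enumerate("ACGT")}
        motif = Motif(counts=FrequencyPositionMatrix("ACGT", counts))
        motif.pseudocounts = pwm.pseudocount
        pssm = motif.pssm
        ref = pssm.calculate(Seq(prom.sequence))
        from adiporeg.motifs import _window_scores, encode_sequence

        ours = _window_scores(encode_sequence(prom.sequence), pwm.log_odds())
        np.testing.assert_allclose(ours, np.asarray(ref), rtol=1e-5)


class TestConservationMasking:
    def test_planted_consensus_found_under_full_conservation(self):
        rng = np.random.default_rng(9)
        pwm = random_count_pwm(rng, 8)
        site = pwm.consensus()
        seq = "A" * 30 + site + "A" * 30
        prom = make_promoter("p", seq)
        score, hit = best_hit(prom, pwm, 0.7)
        assert hit.offset == 30
        assert score.score == pytest.approx(1.0)

    def test_single_low_base_blocks_threshold_one(self):
        pwm = PWM("x", np.eye(4)[:, :2] * 10 + 1)
        cons = np.ones(20)
        cons[5] = 0.99
        prom = make_promoter("p", "ACGT" * 5, cons)
        score, hit = best_hit(prom, pwm, 1.0)
        # windows covering base 5 are ineligible; others still pass
        assert hit is not None
        assert not (hit.offset <= 5 <= hit.offset + pwm.width - 1)
        all_block = make_promoter("p", "ACGT" * 5, np.full(20, 0.99))
        score2, hit2 = best_hit(all_block, pwm, 1.0)
        assert not score2.eligible and hit2 is None

    def test_palindromic_matrix_scores_both_strands_equally(self):
        counts = np.array(
            [[10, 0, 0, 10], [0, 10, 10, 0], [0, 10, 10, 0], [10, 0, 0, 10]],
            dtype=float,
        )  # ACGT / revcomp-symmetric
        pwm = PWM("pal", counts)
        lo = pwm.log_odds()
        assert np.allclose(lo, lo[::-1, ::-1])
        rng = np.random.default_rng(1)
        prom = random_promoter(rng, 40)
        from adiporeg.motifs import _window_scores, encode_sequence

        enc = encode_sequence(prom.sequence)
        assert np.allclose(_window_scores(enc, lo), _window_scores(enc, lo[::-1, ::-1]))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            prom = random_promoter(rng, 60)
            pwm = random_count_pwm(rng, 6)
            scores = []
            for thr in (0.7, 0.8, 0.9, 1.0):
                s, _ = best_hit(prom, pwm, thr)
                scores.append(s.score if s.eligible else -np.inf)
            assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_short_promoter_raises(self):
        prom = make_promoter("p", "ACG")
        pwm = random_count_pwm(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            best_hit(prom, pwm, 0.7)


class TestScanTable:
    def test_matches_single_promoter_functions(self):
        rng = np.random.default_rng(31)
        proms = [random_promoter(rng, 50, f"p{i}") for i in range(5)]
        pwms = [random_count_pwm(rng, 6), random_count_pwm(rng, 9)]
        pwms[0].motif_id, pwms[1].motif_id = "m1", "m2"
        table = scan_promoters(proms, pwms, CONSERVATION_MODES)
        assert len(table) == 5 * 2 * 5
        for _, row in table.iterrows():
            prom = next(p for p in proms if p.gene_id == row.promoter_id)
            pwm = next(m for m in pwms if m.motif_id == row.motif_id)
            if row["mode"] == "none":
                assert row.score == top3_mean(prom, pwm).score
            else:
                ref, _ = best_hit(prom, pwm, float(row["mode"]))
                assert row.score == ref.score
                assert row.eligible == ref.eligible

    def test_normalized_scores_in_unit_interval(self):
        rng = np.random.default_rng(8)
        proms = [random_promoter(rng, 40, f"p{i}") for i in range(3)]
        pwm = random_count_pwm(rng, 5)
        table = scan_promoters(proms, [pwm], CONSERVATION_MODES)
        assert table.score.between(0, 1).all()
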