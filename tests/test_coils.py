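"""Heptad-window scoring, probability calibration and profile assembly."""

import csv
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coils_oracle import brute_force_probability, brute_force_scores
from oraitraffic import coils, sequences
from oraitraffic._coils_data import MTIDK
from oraitraffic.coils import (
    CoilsError,
    CoilsParams,
    mutant_delta,
    predict,
    scan_windows,
    score_to_probability,
    window_scores,
)
from oraitraffic.sequences import AMINO_ACIDS, ProteinSequence

FIXTURE = Path(__file__).parent / "fixtures" / "coils_reference_profiles.csv"


def _seq(residues, **kw):
    return ProteinSequence(id=kw.pop("id", "s"), residues=residues, **kw)


class TestWindowScores:
    def test_homopolymer_scores_equal_best_position_propensity(self):
        # every window/frame covers K at all 7 heptad positions equally often
        # only when window % 7 == 0; with window 14 the geometric mean over
        # any frame is the same, so all residues share one score
        seq = _seq("K" * 30)
        scores, registers = window_scores(seq, CoilsParams(window=14, ad_weighting=False))
        expected = np.exp(np.mean(np.log(np.array(MTIDK["K"])[[(0 + j) % 7 for j in range(14)]])))
        assert np.allclose(scores, expected)

    def test_proline_rich_sequence_scores_near_floor(self):
        scores, _ = window_scores(_seq("P" * 20), CoilsParams(window=14))
        assert scores.max() < 0.05

    @pytest.mark.parametrize("window", [14, 21])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_enumerator(self, window, weighted):
        residues = "IEALEGK" * 6  # ideal heptad repeat
        seq = _seq(residues)
        got, _ = window_scores(seq, CoilsParams(window=window, ad_weighting=weighted))
        expected = brute_force_scores(residues, window, weighted)
        assert np.allclose(got, expected, rtol=0, atol=1e-12)

    def test_matches_brute_force_on_natural_sequence(self, horai1):
        frag = sequences.extract_cterm(horai1, 250)
        got, _ = window_scores(frag, CoilsParams(window=14))
        expected = brute_force_scores(frag.residues, 14, True)
        assert np.allclose(got, expected, rtol=0, atol=1e-12)

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(CoilsError, match="shorter than window"):
            window_scores(_seq("MKLV"), CoilsParams(window=14))

    def test_registers_are_heptad_letters(self):
        _, registers = window_scores(_seq("IEALEGK" * 4), CoilsParams(window=14))
        assert set(registers) <= set("abcdefg")


class TestScoreToProbability:
    def test_limits_at_class_means(self):
        p = CoilsParams(window=14)
        m_cc, sd_cc, m_g, _ = p.calibration
        assert score_to_probability(m_g, p) < 0.05
        assert score_to_probability(m_cc, p) > 0.5
        assert score_to_probability(m_cc + 2 * sd_cc, p) > 0.95
        assert score_to_probability(0.0, p) < 1e-3

    def test_monotone_increasing_on_score_range(self):
        # non-decreasing everywhere on the attainable score range; strictly
        # increasing wherever the probability is away from its float
        # saturation at 0 and 1
        for window in (14, 21, 28):
            for weighted in (False, True):
                p = CoilsParams(window=window, ad_weighting=weighted)
                xs = np.linspace(0.2, 4.0, 400)
                ys = score_to_probability(xs, p)
                assert np.all(np.diff(ys) >= 0)
                interior = (ys[:-1] > 1e-6) & (ys[1:] < 1 - 1e-6)
                assert np.all(np.diff(ys)[interior] > 0)
                assert np.all((ys >= 0) & (ys <= 1))

    def test_unsupported_window_has_no_calibration(self):
        with pytest.raises(CoilsError):
            CoilsParams(window=7)

    @settings(max_examples=100, deadline=None)
    @given(score=st.floats(min_value=0.0, max_value=5.0))
    def test_agrees_with_closed_form(self, score):
        p = CoilsParams(window=14)
        assert score_to_probability(score, p) == pytest.approx(
            brute_force_probability(score, 14, True), abs=1e-12
        )


@pytest.fixture(scope="module")
def reference():
    rows = {}
    with open(FIXTURE) as fh:
        for row in csv.DictReader(fh):
            key = (row["name"], int(row["window"]), row["ad_weighting"] == "True")
            rows.setdefault(key, []).append(
                (int(row["index"]), float(row["score"]), float(row["probability"]))
            )
    return rows


@pytest.fixture(scope="module")
def fixture_sequences(horai1, isoform_cterms):
    panel = dict(sequences.construct_panel(horai1))
    return {
        "hOrai1_cterm": sequences.extract_cterm(panel["WT"], 260),
        "F270,279A_cterm": sequences.extract_cterm(panel["F270,279A"], 260),
        "L273S_cterm": sequences.extract_cterm(panel["L273S"], 260),
        "xOrai1_cterm": isoform_cterms["xOrai1"],
        "xOrai2_cterm": isoform_cterms["xOrai2"],
        "ideal_heptad": _seq("IEALEGK" * 6),
    }


class TestReferenceProfiles:
    """Package output vs the frozen brute-force oracle fixture."""

    def test_probabilities_within_1e3_and_scores_exact(self, reference,
                                                       fixture_sequences):
        assert len(fixture_sequences) >= 5
        checked = 0
        for (name, window, weighted), rows in reference.items():
            seq = fixture_sequences[name]
            profile = predict(seq, CoilsParams(window=window, ad_weighting=weighted))
            rows.sort()
            ref_scores = np.array([r[1] for r in rows])
            ref_probs = np.array([r[2] for r in rows])
            assert np.allclose(profile.raw_scores, ref_scores, rtol=0, atol=1e-9)
            assert np.max(np.abs(profile.probabilities - ref_probs)) < 1e-3
            checked += 1
        assert checked == len(reference)


class TestPredict:
    def test_wt_cterm_segment_overlaps_cc_region(self, horai1):
        profile = predict(horai1)
        segs = profile.segments
        assert len(segs) >= 1
        assert any(s.start <= 285 and s.end >= 269 for s in segs)

    def test_l273s_destabilizes_relative_to_wt(self, panel):
        delta, verdict = mutant_delta(predict(panel["WT"]), predict(panel["L273S"]))
        assert delta < 0
        assert verdict == "destabilized"

    def test_truncation_266_loses_the_segment(self, panel):
        assert predict(panel["1-266"]).segments == ()

    def test_probabilities_bounded_and_max_consistent(self, horai1):
        profile = predict(horai1)
        assert len(profile.probabilities) == len(horai1)
        assert np.all((profile.probabilities >= 0) & (profile.probabilities <= 1))
        assert profile.max_probability == profile.probabilities.max()

    def test_segments_reported_in_full_length_numbering(self, horai1):
        frag = sequences.extract_cterm(horai1, 260)
        profile = predict(frag)
        assert profile.segments
        for seg in profile.segments:
            assert 260 <= seg.start <= seg.end <= 301

    def test_palindromic_input_invariant_under_reversal(self):
        # reversing a palindromic sequence is the identity, so the profile
        # must be bit-identical (heptad direction makes general reversal
        # equivariance false, so only this degenerate symmetry holds)
        half = "IEALEGKQKMLVHD"
        pal = half + half[::-1]
        fwd, _ = window_scores(_seq(pal), CoilsParams(window=14))
        rev, _ = window_scores(_seq(pal[::-1]), CoilsParams(window=14))
        assert np.array_equal(fwd, rev)


class TestScanWindows:
    def test_single_window_degenerates_to_predict(self, horai1):
        w, profile = scan_windows(horai1, windows=(14,))
        direct = predict(horai1, CoilsParams(window=14))
        assert w == 14
        assert np.allclose(profile.probabilities, direct.probabilities)

    def test_tie_breaks_toward_smallest_window(self):
        # a hard-zero sequence ties all windows at the probability floor
        seq = _seq("P" * 40)
        w, _ = scan_windows(seq)
        assert w == 14

    def test_sequence_shorter_than_largest_window_rejected(self):
        with pytest.raises(CoilsError):
            scan_windows(_seq("IEALEGK" * 3))  # 21 aa < 28

    def test_isoform_ordering(self, isoform_cterms):
        maxp = {}
        for name, seq in isoform_cterms.items():
            _, profile = scan_windows(seq, windows=(14, 21, 28))
            maxp[name] = profile.max_probability
        assert maxp["xOrai1"] > maxp["hOrai1"] > maxp["xOrai2"]


class TestMutantDelta:
    def test_identity_is_unchanged(self, horai1):
        profile = predict(horai1)
        delta, verdict = mutant_delta(profile, profile)
        assert delta == 0.0
        assert verdict == "unchanged"

    def test_stabilizing_mutants(self, panel):
        wt = predict(panel["WT"])
        for name in ("F270A", "F279A", "F270,279A", "A277,280L"):
            delta, verdict = mutant_delta(wt, predict(panel[name]))
            assert verdict == "stabilized", name
            assert delta > 0

    def test_a277_280l_comparable_to_double_f_mutant(self, panel):
        p_al = predict(panel["A277,280L"]).max_probability
        p_ff = predict(panel["F270,279A"]).max_probability
        assert abs(p_al - p_ff) < 0.05

    def test_params_mismatch_rejected(self, horai1):
        a = predict(horai1, CoilsParams(window=14))
        b = predict(horai1, CoilsParams(window=21))
        with pytest.raises(CoilsError, match="params mismatch"):
            mutant_delta(a, b)


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet=AMINO_ACIDS, min_size=14, max_size=40))
def test_raw_scores_nonnegative_probabilities_bounded(residues):
    profile = predict(_seq(residues))
    assert np.all(profile.raw_scores >= 0)
    assert np.all((profile.probabilities >= 0) & (profile.probabilities <= 1))
    assert profile.max_probability == pytest.approx(profile.probabilities.max())
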