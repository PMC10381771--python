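"""Hit rates, proportion index, confusion matrices, selection, distractors."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emometrics import (
    concealed_joint_space,
    confusion_matrix,
    hit_rate,
    proportion_index,
    select_distractors,
    select_stimuli,
    summarize_ratings,
)
from emometrics.data import RawResponse, ResponseTable, StimulusRecord
from emometrics.labels import default_label_set
from emometrics.validation import SelectionCriteria, StimulusStats, stimulus_pi
from emometrics.simulate import SimulationSpec, simulate_study, simulate_ratings


def _table(rows, stimuli):
    return ResponseTable(
        rows=rows, label_set=default_label_set(), stimulus_index=stimuli
    )


def _nv(sid="s1", target="fear"):
    return StimulusRecord(stimulus_id=sid, modality="nonverbal", target_emotion=target)


class TestProportionIndex:
    def test_chance_maps_to_half_exactly(self):
        # exact rational arithmetic: pi(1/k, k) = 1/2 for every k
        for k in range(2, 40):
            P = Fraction(1, k)
            pi = P * (k - 1) / (1 + P * (k - 2))
            assert pi == Fraction(1, 2)
        assert proportion_index(1 / 18, 18) == pytest.approx(0.5, abs=1e-15)

    def test_endpoints(self):
        assert proportion_index(0.0, 7) == 0.0
        assert proportion_index(1.0, 7) == 1.0

    def test_half_with_eighteen_options(self):
        # exact: 0.5 * 17 / (1 + 0.5 * 16) = 8.5 / 9
        assert proportion_index(0.5, 18) == pytest.approx(8.5 / 9, abs=1e-15)

    def test_identity_at_two_options(self):
        for P in np.linspace(0, 1, 11):
            assert proportion_index(P, 2) == pytest.approx(P)

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999), st.integers(2, 50))
    @settings(max_examples=100, deadline=None)
    def test_strictly_monotone_in_hit_rate(self, p1, p2, k):
        if p1 == p2:
            return
        lo, hi = sorted([p1, p2])
        assert proportion_index(lo, k) < proportion_index(hi, k)

    @given(st.floats(0.01, 0.99), st.integers(2, 49))
    @settings(max_examples=100, deadline=None)
    def test_increasing_in_option_count(self, P, k):
        assert proportion_index(P, k + 1) >= proportion_index(P, k)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            proportion_index(1.2, 18)
        with pytest.raises(ValueError):
            proportion_index(0.5, 1)


class TestJointSpace:
    def test_eighteen_by_eighteen(self):
        assert concealed_joint_space(18, 18) == 324

    def test_two_by_two(self):
        assert concealed_joint_space(2, 2) == 4

    def test_degenerate_option_count_rejected(self):
        with pytest.raises(ValueError):
            concealed_joint_space(5, 1)


class TestHitRate:
    def test_counting(self):
        stim = {"s1": _nv()}
        rows = [
            RawResponse(f"p{i}", {}, "s1", "fear" if i < 9 else "joy")
            for i in range(10)
        ]
        assert hit_rate(_table(rows, stim), "s1") == pytest.approx(0.9)

    def test_concealed_hit_requires_both_judgements(self):
        stim = {
            "c1": StimulusRecord(
                stimulus_id="c1", modality="concealed",
                displayed_emotion="anger", concealed_emotion="content",
            )
        }
        rows = [
            RawResponse("p1", {}, "c1", "anger", "content"),  # both right: hit
            RawResponse("p2", {}, "c1", "anger", "joy"),      # displayed only: miss
        ]
        assert hit_rate(_table(rows, stim), "c1") == pytest.approx(0.5)

    def test_no_judgements_is_an_error(self):
        table = _table([RawResponse("p1", {}, "s1", "fear")], {"s1": _nv(), "s2": _nv("s2")})
        with pytest.raises(ValueError):
            hit_rate(table, "s2")

    def test_known_mixing_proportion_recovered(self):
        # 70/30 mixture has expected hit rate 0.7; binomial error at n=4000
        rng = np.random.default_rng(99)
        stim = {"s1": _nv()}
        rows = [
            RawResponse(f"p{i}", {}, "s1", "fear" if rng.random() < 0.7 else "joy")
            for i in range(4000)
        ]
        hr = hit_rate(_table(rows, stim), "s1")
        assert abs(hr - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 4000)


class TestConfusionMatrix:
    def test_perfect_raters_give_identity_diagonal(self):
        stim = {"s1": _nv("s1", "fear"), "s2": _nv("s2", "joy")}
        rows = [RawResponse(f"p{i}", {}, sid, stim[sid].target_emotion)
                for i in range(5) for sid in stim]
        cm = confusion_matrix(_table(rows, stim), "nonverbal")
        frame = cm.raw_frame()
        assert frame.loc["fear", "fear"] == 1.0
        assert frame.loc["joy", "joy"] == 1.0
        assert frame.loc["fear", "joy"] == 0.0

    def test_two_emotion_toy_counts(self):
        stim = {"sa": _nv("sa", "fear"), "sb": _nv("sb", "joy")}
        rows = []
        for i in range(10):
            rows.append(RawResponse(f"p{i}", {}, "sa", "fear" if i < 8 else "joy"))
            rows.append(RawResponse(f"p{i}", {}, "sb", "joy" if i < 8 else "fear"))
        cm = confusion_matrix(_table(rows, stim), "nonverbal")
        frame = cm.raw_frame()
        assert frame.loc["fear", "fear"] == pytest.approx(0.8)
        assert frame.loc["fear", "joy"] == pytest.approx(0.2)
        assert frame.loc["joy", "joy"] == pytest.approx(0.8)

    def test_rows_are_stochastic_and_pi_bounded(self):
        study = simulate_study(SimulationSpec(n_per_cell=5, seed=2))
        cm = confusion_matrix(study.table, "nonverbal")
        assert np.allclose(cm.raw.sum(axis=1), 1.0)
        assert cm.pi.min() >= 0 and cm.pi.max() <= 1

    def test_uniform_choices_give_chance_pi_on_diagonal(self):
        # uniform over the full 18-label menu: every cell P = 1/18 -> pi = 0.5
        rng = np.random.default_rng(7)
        labels = list(default_label_set())
        stim = {"s1": _nv()}
        rows = [
            RawResponse(f"p{i}", {}, "s1", labels[rng.integers(18)])
            for i in range(9000)
        ]
        cm = confusion_matrix(_table(rows, stim), "nonverbal")
        se = 3 * np.sqrt((1 / 18) * (17 / 18) / 9000)  # binomial SE on P
        assert abs(cm.raw_frame().loc["fear", "fear"] - 1 / 18) < se
        assert abs(cm.pi_frame().loc["fear", "fear"] - 0.5) < 0.1

    def test_empty_modality_is_an_error(self):
        stim = {"s1": _nv()}
        with pytest.raises(ValueError):
            confusion_matrix(_table([RawResponse("p1", {}, "s1", "fear")], stim), "verbal")


class TestRatings:
    def test_simple_mean(self):
        stim = {"s1": _nv()}
        rows = [
            RawResponse(f"p{i}", {}, "s1", "fear", intensity_rating=v, believability_rating=3)
            for i, v in enumerate([2, 3, 4])
        ]
        summ = summarize_ratings(_table(rows, stim))
        assert summ.per_stimulus.loc["s1", "intensity_mean"] == pytest.approx(3.0)

    def test_single_rating_sd_zero_with_flag(self):
        stim = {"s1": _nv()}
        rows = [RawResponse("p1", {}, "s1", "fear", intensity_rating=4, believability_rating=2)]
        summ = summarize_ratings(_table(rows, stim))
        assert summ.per_stimulus.loc["s1", "intensity_sd"] == 0.0
        assert "s1" in summ.degenerate_stimuli

    def test_unrated_stimuli_listed(self):
        stim = {"s1": _nv(), "s2": _nv("s2")}
        rows = [
            RawResponse("p1", {}, "s1", "fear", intensity_rating=3, believability_rating=3),
            RawResponse("p1", {}, "s2", "fear"),
        ]
        summ = summarize_ratings(_table(rows, stim))
        assert summ.unrated_stimuli == ["s2"]

    def test_latent_means_recovered_within_standard_error(self):
        df = simulate_ratings({"s1": (2.7, 3.2)}, n_raters=500, seed=11, sd=0.9)
        # discretization keeps the mean near the latent value at this noise
        assert abs(df["intensity"].mean() - 2.7) < 0.15
        assert set(df["intensity"]) <= set(range(1, 6))


class TestSelectStimuli:
    def test_all_criteria_met(self):
        res = select_stimuli(
            [StimulusStats("s1", "nonverbal", 0.6, 2.8, 3.2)], SelectionCriteria()
        )
        assert res.accepted == ["s1"]

    def test_below_chance_rejected_with_reason(self):
        res = select_stimuli(
            [StimulusStats("s1", "nonverbal", 0.45, 2.8, 3.2)], SelectionCriteria()
        )
        assert res.rejected == ["s1"]
        assert "below-chance recognition" in res.reasons["s1"]

    def test_concealed_skips_believability(self):
        res = select_stimuli(
            [StimulusStats("c1", "concealed", 0.6, 2.7, 1.05)], SelectionCriteria()
        )
        assert res.accepted == ["c1"]

    def test_boundary_pi_is_strictly_above_chance(self):
        res = select_stimuli(
            [StimulusStats("s1", "nonverbal", 0.50, 2.8, 3.2)], SelectionCriteria()
        )
        assert res.rejected == ["s1"]

    def test_idempotent_and_order_independent(self):
        stats = [
            StimulusStats("s2", "nonverbal", 0.7, 2.5, 3.5),
            StimulusStats("s1", "nonverbal", 0.4, 2.5, 3.5),
            StimulusStats("s3", "verbal", 0.9, 2.2, 3.1),
        ]
        a = select_stimuli(stats)
        b = select_stimuli(list(reversed(stats)))
        assert a == b
        again = select_stimuli(
            [s for s in stats if s.stimulus_id in a.accepted]
        )
        assert again.accepted == a.accepted


class TestSelectDistractors:
    def test_highest_confusion_becomes_partial(self):
        row = {"anxiety": 0.4, "surprise": 0.2, "joy": 0.05, "awe": 0.04,
               "pride": 0.03, "boredom": 0.01, "shame": 0.0}
        key = select_distractors(row, "fear", n_options=6, n_partial=1)
        assert key.partial == frozenset({"anxiety"})
        assert key.correct == ("fear",)
        assert len(key.incorrect) == 4

    def test_ties_break_alphabetically(self):
        row = {lab: 0.1 for lab in ["joy", "awe", "pride", "boredom", "shame", "surprise"]}
        key = select_distractors(row, "fear", n_options=6, n_partial=1)
        assert key.partial == frozenset({"awe"})  # alphabetically first at equal pi

    def test_option_budget_one_correct_one_partial_four_incorrect(self):
        row = {lab: v for lab, v in zip(
            ["anxiety", "surprise", "joy", "awe", "pride", "boredom"],
            [0.4, 0.3, 0.2, 0.1, 0.05, 0.0],
        )}
        key = select_distractors(row, "fear", n_options=6, n_partial=1)
        assert (len(key.correct), len(key.partial), len(key.incorrect)) == (1, 1, 4)
        assert key.n_options == 6

    def test_too_few_candidates_is_an_error(self):
        with pytest.raises(ValueError):
            select_distractors({"joy": 0.1}, "fear", n_options=6, n_partial=1)


def test_concealed_pi_uses_joint_space_by_default():
    study = simulate_study(SimulationSpec(n_per_cell=30, seed=4))
    cid = study.bank.by_modality("concealed")[0]
    joint = stimulus_pi(study.table, cid, concealed_k_mode="joint")
    single = stimulus_pi(study.table, cid, concealed_k_mode="single")
    # same hit rate, larger k -> larger pi
    assert joint >= single
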