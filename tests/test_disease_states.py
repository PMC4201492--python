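"""The disease-state machine: worked examples, hand traces, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moodcourse as mc
from moodcourse.disease_states import DiseaseState

from _oracle import day_level_course
from conftest import expand_labels, random_run_spec


def annotate(spec, **kwargs):
    signs = mc.generate_sign_fixture(spec)
    return mc.annotate_course(mc.runs_from_daily_signs(signs), **kwargs)


class TestRunLengthEncoding:
    def test_worked_example_three_runs(self):
        signs = mc.generate_sign_fixture([("neg", 28), ("pos", 5), ("neg", 27)])
        runs = mc.runs_from_daily_signs(signs)
        assert [(r.symptomatic, r.length) for r in runs] == [
            (True, 28), (False, 5), (True, 27)
        ]

    def test_constant_sequence_is_one_run(self):
        runs = mc.runs_from_daily_signs(np.zeros(10, dtype=bool))
        assert len(runs) == 1 and runs[0].length == 10

    def test_alternating_days_one_run_each(self):
        runs = mc.runs_from_daily_signs(np.array([1, 0, 1, 0, 1, 0], dtype=bool))
        assert [r.length for r in runs] == [1] * 6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mc.runs_from_daily_signs(np.array([], dtype=bool))


class TestWorkedExamples:
    def test_interrupted_episode_merges_into_single_sixty_day_episode(self):
        # 28 d symptomatic, 5 d asymptomatic, 27 d symptomatic: one DE of 60 d
        ann = annotate([("neg", 28), ("pos", 5), ("neg", 27)])
        assert mc.count_episodes(ann) == 1
        assert mc.episode_durations(ann) == [60]
        assert [iv.label for iv in ann.intervals] == [
            DiseaseState.DEPRESSIVE_EPISODE,
            DiseaseState.REBOUND_DE,
            DiseaseState.DEPRESSIVE_EPISODE,
        ]

    def test_subthreshold_symptoms_never_leave_null(self):
        ann = annotate([("neg", 13), ("pos", 100)])
        assert mc.count_episodes(ann) == 0
        assert all(iv.label is DiseaseState.NULL for iv in ann.intervals)

    def test_relapse_then_recovery_hand_trace(self):
        # DE 20 d, remission 20 d, relapse 20 d, then 200 d rest -> recovery
        ann = annotate([("neg", 20), ("pos", 20), ("neg", 20), ("pos", 200)])
        assert [iv.label for iv in ann.intervals] == [
            DiseaseState.DEPRESSIVE_EPISODE,
            DiseaseState.REMISSION,
            DiseaseState.RELAPSE,
            DiseaseState.RECOVERY,
        ]
        assert [e.kind for e in ann.episodes] == ["DE", "RELAPSE"]
        assert mc.count_episodes(ann, "all_episodes") == 2
        assert mc.count_episodes(ann, "post_recovery_only") == 1

    def test_recurrence_after_recovery_hand_trace(self):
        # 190 d asymptomatic exceeds six months: next episode is a new DE
        ann = annotate([("neg", 20), ("pos", 190), ("neg", 20)])
        assert [iv.label for iv in ann.intervals] == [
            DiseaseState.DEPRESSIVE_EPISODE,
            DiseaseState.RECOVERY,
            DiseaseState.DEPRESSIVE_EPISODE,
        ]
        assert mc.count_episodes(ann) == 2
        assert mc.count_episodes(ann, "post_recovery_only") == 2
        assert mc.episode_durations(ann) == [20, 20]

    def test_remission_interruptions_count_toward_recovery_span(self):
        # 100 + 10 + 75 = 185 contiguous days of rest -> recovery, including
        # the absorbed 10 d symptomatic interruption
        ann = annotate([("neg", 20), ("pos", 100), ("neg", 10), ("pos", 75)])
        assert [iv.label for iv in ann.intervals] == [
            DiseaseState.DEPRESSIVE_EPISODE,
            DiseaseState.RECOVERY,
            DiseaseState.INTERRUPTED_RECOVERY,
            DiseaseState.RECOVERY,
        ]

    def test_trailing_symptomatic_run_counts_as_episode(self):
        ann = annotate([("pos", 30), ("neg", 14)])
        assert mc.count_episodes(ann) == 1
        assert mc.episode_durations(ann) == [14]

    def test_ongoing_episode_initialization(self):
        # treatment runs start inside an episode with onset at day 0
        ann = annotate([("neg", 5), ("pos", 40)], initial_state="ongoing_episode")
        assert [e.kind for e in ann.episodes] == ["DE"]
        assert ann.episodes[0].onset_day == 0
        assert ann.first_remission_day() == 5

    def test_nine_labels_four_clinically_relevant(self):
        assert len(DiseaseState) == 9
        relevant = [s for s in DiseaseState if s.clinically_relevant]
        assert sorted(s.value for s in relevant) == [
            "DEPRESSIVE_EPISODE", "RECOVERY", "RELAPSE", "REMISSION"
        ]


class TestAbsorptionThreshold:
    def test_extending_an_absorbed_interruption_changes_the_annotation(self):
        base = [("neg", 28), ("pos", 13), ("neg", 27)]
        assert mc.count_episodes(annotate(base)) == 1
        extended = [("neg", 28), ("pos", 14), ("neg", 27)]
        ann = annotate(extended)
        assert mc.count_episodes(ann) == 2  # remission splits the episodes

    def test_shrinking_an_absorbed_interruption_never_changes_it(self):
        for gap in (1, 5, 13):
            ann = annotate([("neg", 28), ("pos", gap), ("neg", 27)])
            assert mc.count_episodes(ann) == 1
            assert mc.episode_durations(ann) == [55 + gap]


class TestInvariantsFuzzed:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_and_duration_invariants(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_run_spec(rng)
        ann = annotate(spec)
        # intervals tile [0, total_days) without gap or overlap
        cursor = 0
        for iv in ann.intervals:
            assert iv.start_day == cursor
            assert iv.end_day > iv.start_day
            cursor = iv.end_day
        assert cursor == ann.total_days == sum(length for _, length in spec)
        for iv in ann.intervals:
            if iv.label.value.startswith(("REBOUND", "INTERRUPTED")):
                assert iv.length < 14
        for e in ann.episodes:
            assert e.duration >= 14
        # each maximal recovery block (recovery plus its absorbed
        # interruptions) spans at least the six-month threshold
        recovery = (DiseaseState.RECOVERY, DiseaseState.INTERRUPTED_RECOVERY)
        block = None
        blocks = []
        for iv in ann.intervals:
            if iv.label in recovery:
                block = [iv.start_day, iv.end_day] if block is None else block
                block[1] = iv.end_day
            elif block is not None:
                blocks.append(block)
                block = None
        if block is not None:
            blocks.append(block)
        for start, end in blocks:
            assert end - start >= 180
        assert mc.count_episodes(ann, "post_recovery_only") <= mc.count_episodes(ann)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_reannotating_reconstructed_signs_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        ann = annotate(random_run_spec(rng))
        rebuilt = np.concatenate(
            [np.full(r.length, r.symptomatic, dtype=bool) for r in ann.runs]
        )
        again = mc.annotate_course(mc.runs_from_daily_signs(rebuilt))
        assert expand_labels(again) == expand_labels(ann)
        assert again.episodes == ann.episodes

    @given(seed=st.integers(0, 20_000))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_day_level_rule_interpreter(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_run_spec(rng)
        signs = mc.generate_sign_fixture(spec)
        ann = mc.annotate_course(mc.runs_from_daily_signs(signs))
        labels, episodes = day_level_course(signs)
        assert expand_labels(ann) == labels
        assert [(e.onset_day, e.duration, e.kind) for e in ann.episodes] == episodes
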