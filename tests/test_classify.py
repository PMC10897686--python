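from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from conftest import event_counts
from reference_impl import reference_classify
from rx_pathways import (
    build_patient_sequences,
    classify_patient,
    classify_transition,
    detect_relapse,
    detect_response,
)
from rx_pathways.sequences import TreatmentSequence
from test_sequences import scripts_frame

EVENT_TYPES = (
    "response",
    "remission",
    "relapse",
    "switch",
    "combination",
    "augmentation",
    "resumption",
    "treatment_failure",
)


def run_patient(rows, cfg, dictionary):
    scripts = scripts_frame(rows)
    seqs = build_patient_sequences(scripts, cfg)
    ad_dates = list(scripts.loc[scripts.drug_role == "antidepressant", "issue_date"])
    return classify_patient(seqs, ad_dates, cfg, dictionary)


def counts_of(events):
    out = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        out[ev.event_type] += 1
    return out


def seq(regimen, start_day, days, base=date(2016, 1, 1), ordinal=1):
    start = base + timedelta(days=start_day)
    return TreatmentSequence(
        patient_id="p1",
        regimen=frozenset(regimen),
        start=start,
        end=start + timedelta(days=days),
        ordinal=ordinal,
    )


class TestResponse:
    @pytest.mark.parametrize("days,expected", [(90, True), (89, False), (120, True)])
    def test_duration_threshold(self, cfg, days, expected):
        assert detect_response(seq({"citalopram"}, 0, days), cfg) is expected

    def test_dose_changes_do_not_disqualify(self, cfg, dictionary):
        rows = [
            ("citalopram", date(2016, 1, 1), 30, 20.0),
            ("citalopram", date(2016, 1, 31), 30, 40.0),
            ("citalopram", date(2016, 3, 1), 60, 20.0),
        ]
        events, _ = run_patient(rows, cfg, dictionary)
        assert counts_of(events)["response"] == 1


class TestArchetypeBoundaries:
    """Every outcome rule flips classification exactly at its stated
    threshold on the hand-built boundary patients."""

    def test_all_archetypes_match_expected_labels(self, archetype_run):
        counts = event_counts(archetype_run.pathway_events)
        classes = archetype_run.classes.set_index("patient_id")
        problems = []
        for row in archetype_run.truth.itertuples(index=False):
            pid = row.patient_id
            for t in EVENT_TYPES:
                expected = getattr(row, f"n_{t}")
                if expected < 0:
                    continue
                got = int(counts.loc[pid, t]) if pid in counts.index and t in counts.columns else 0
                if got != expected:
                    problems.append((pid, t, expected, got))
            if row.true_group and classes.loc[pid, "group"] != row.true_group:
                problems.append((pid, "group", row.true_group, classes.loc[pid, "group"]))
            if row.true_lines >= 0 and classes.loc[pid, "lines_of_therapy"] != row.true_lines:
                problems.append(
                    (pid, "lines", row.true_lines, int(classes.loc[pid, "lines_of_therapy"]))
                )
        assert not problems, f"archetype mismatches: {problems}"


class TestRelapseWindowSweep:
    @pytest.mark.parametrize(
        "gap,fires", [(59, False), (60, True), (61, True), (179, True), (180, True), (181, False)]
    )
    def test_inclusive_endpoints(self, cfg, gap, fires):
        base = date(2016, 1, 1)
        seqs = [
            seq({"citalopram"}, 0, 90, ordinal=1),
            seq({"sertraline"}, 90 + gap, 30, ordinal=2),
        ]
        got = detect_relapse(seqs, cfg)
        assert (len(got) == 1) is fires
        if fires:
            assert got[0].event_date == base + timedelta(days=90 + gap)


class TestTransitions:
    def test_switch_within_window(self, cfg):
        assert (
            classify_transition(seq({"sertraline"}, 0, 60), seq({"citalopram"}, 130, 60), cfg)
            == "switch"
        )

    def test_switch_beyond_window_is_not_switch(self, cfg):
        kind = classify_transition(seq({"sertraline"}, 0, 60), seq({"citalopram"}, 60 + 181, 60), cfg)
        assert kind == "none"

    def test_combination_threshold(self, cfg):
        prev = seq({"citalopram"}, 0, 60)
        assert classify_transition(prev, seq({"citalopram", "mirtazapine"}, 60, 50), cfg) == "combination"
        assert classify_transition(prev, seq({"citalopram", "mirtazapine"}, 60, 44), cfg) == "continuation_boundary"

    def test_resumption_outside_relapse_window(self, cfg):
        prev = seq({"fluoxetine"}, 0, 60)
        nxt = seq({"fluoxetine"}, 260, 30)  # 200-day gap, no prior response
        assert classify_transition(prev, nxt, cfg) == "resumption"

    def test_restart_in_relapse_window_after_response_is_not_resumption(self, cfg):
        prev = seq({"fluoxetine"}, 0, 90)
        nxt = seq({"fluoxetine"}, 90 + 100, 30)
        assert classify_transition(prev, nxt, cfg) == "none"

    def test_overlapping_sequences_is_hard_error(self, cfg):
        with pytest.raises(ValueError, match="overlapping"):
            classify_transition(seq({"a"}, 0, 60), seq({"b"}, 30, 60), cfg)

    def test_precedence_combination_over_switch_over_resumption(self, cfg):
        # a regimen that is both a superset and re-introduces an old drug
        first = seq({"citalopram"}, 0, 60)
        second = seq({"sertraline"}, 70, 60)
        third = seq({"sertraline", "citalopram"}, 130, 50)
        assert (
            classify_transition(second, third, cfg, earlier_regimens={first.regimen})
            == "combination"
        )


class TestPatientClassification:
    def test_two_adequate_failures_then_combination_is_trd_three_lines(self, cfg, dictionary):
        rows = [
            ("sertraline", date(2016, 1, 1), 60, 50.0),
            ("citalopram", date(2016, 3, 11), 50, 20.0),  # switch, gap 10
            ("citalopram", date(2016, 4, 30), 50, 20.0),  # combination from 2016-04-30
            ("mirtazapine", date(2016, 4, 30), 50, 15.0),
        ]
        events, classification = run_patient(rows, cfg, dictionary)
        assert classification.group == "TRD"
        assert classification.lines_of_therapy == 3
        got = counts_of(events)
        assert got["switch"] == 1 and got["combination"] == 1

    def test_single_responding_remitting_sequence_is_mdd(self, cfg, dictionary):
        events, classification = run_patient(
            [("sertraline", date(2016, 1, 1), 200, 50.0)], cfg, dictionary
        )
        assert classification.group == "MDD"
        assert counts_of(events)["remission"] == 1

    def test_failures_in_different_episodes_do_not_make_trd(self, cfg, dictionary):
        rows = [
            ("sertraline", date(2016, 1, 1), 60, 50.0),
            ("citalopram", date(2016, 1, 1) + timedelta(days=260), 60, 20.0),
        ]
        _, classification = run_patient(rows, cfg, dictionary)
        assert classification.group == "MDD"

    def test_subminimum_dose_line_is_not_an_adequate_trial(self, cfg, dictionary):
        rows = [
            ("sertraline", date(2016, 1, 1), 60, 10.0),  # below 50 mg minimum
            ("citalopram", date(2016, 3, 11), 60, 20.0),
        ]
        _, classification = run_patient(rows, cfg, dictionary)
        assert classification.group == "MDD"
        # same shape at adequate dose is TRD
        rows[0] = ("sertraline", date(2016, 1, 1), 60, 50.0)
        _, classification = run_patient(rows, cfg, dictionary)
        assert classification.group == "TRD"

    def test_empty_sequences_rejected(self, cfg, dictionary):
        with pytest.raises(ValueError):
            classify_patient([], [], cfg, dictionary)


class TestReferenceOracle:
    """The incremental classifier agrees exactly with an exhaustive
    re-statement of the rules on random small patients."""

    def test_random_patients_match_reference(self, cfg, dictionary):
        rng = np.random.default_rng(99)
        drugs = ["citalopram", "sertraline", "mirtazapine", "fluoxetine"]
        min_doses = {d: dictionary.min_daily_dose(d) for d in drugs}
        base = date(2015, 6, 1)
        checked = 0
        for _ in range(400):
            n = int(rng.integers(1, 7))
            rows = [
                (
                    drugs[int(rng.integers(0, len(drugs)))],
                    base + timedelta(days=int(rng.integers(0, 500))),
                    int(rng.integers(7, 90)),
                    float(rng.choice([10.0, 20.0, 50.0])),
                )
                for _ in range(n)
            ]
            scripts = scripts_frame(rows)
            seqs = build_patient_sequences(scripts, cfg)
            ad_dates = list(scripts["issue_date"])
            events, classification = classify_patient(seqs, ad_dates, cfg, dictionary)
            seq_tuples = [
                (
                    s.regimen,
                    s.start,
                    s.end,
                    {i: tuple(v for v in s.doses.get(i, ()) if v is not None) for i in s.regimen},
                    bool(s.augmentations),
                )
                for s in seqs
            ]
            ref_counts, ref_group, ref_lines = reference_classify(
                seq_tuples, ad_dates, cfg, min_doses
            )
            got = counts_of(events)
            for key, want in ref_counts.items():
                assert got[key] == want, (rows, key, got, ref_counts)
            assert classification.group == ref_group, rows
            assert classification.lines_of_therapy == ref_lines, rows
            checked += 1
        assert checked == 400


class TestCohortInvariants:
    def test_trd_subset_chain_and_line_floor(self, cohort_run):
        cl = cohort_run.classes
        trd = cl[cl.group == "TRD"]
        assert (trd.lines_of_therapy >= 2).all()
        assert cl.loc[cl.trd_4plus_lines, "trd_3plus_lines"].all()
        assert (cl.loc[cl.trd_3plus_lines, "group"] == "TRD").all()
        assert set(cl.group) <= {"MDD", "TRD"}

    def test_relapse_and_remission_presuppose_a_response(self, cohort_run):
        """Every relapse points back at a responding sequence, and every
        remission is anchored on a sequence that itself responded."""
        ev = cohort_run.pathway_events
        responses = {
            (r.patient_id, r.sequence_ordinal)
            for r in ev[ev.event_type == "response"].itertuples(index=False)
        }
        relapses = ev[ev.event_type == "relapse"]
        assert len(relapses) > 0
        for row in relapses.itertuples(index=False):
            assert (row.patient_id, row.related_ordinal) in responses
        for row in ev[ev.event_type == "remission"].itertuples(index=False):
            assert (row.patient_id, row.sequence_ordinal) in responses

    def test_relapse_implies_remission_for_the_same_patient(self, cohort_run):
        """A relapse gap (>= 60 antidepressant-free days after a response)
        itself satisfies the remission discontinuation clause, so every
        relapsing patient also carries a remission event."""
        ev = cohort_run.pathway_events
        relapse_ids = set(ev.loc[ev.event_type == "relapse", "patient_id"])
        remit_ids = set(ev.loc[ev.event_type == "remission", "patient_id"])
        assert relapse_ids <= remit_ids
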