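from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from reference_impl import brute_force_sequences
from rx_pathways import (
    attach_augmentations,
    build_patient_sequences,
    derive_sequences,
    expand_and_merge_coverage,
)


def scripts_frame(rows):
    """rows: (ingredient, issue_date, supply_days[, dose, role, agent_class])"""
    recs = []
    for row in rows:
        ingredient, issue, supply = row[:3]
        dose = row[3] if len(row) > 3 else 20.0
        role = row[4] if len(row) > 4 else "antidepressant"
        agent = row[5] if len(row) > 5 else None
        recs.append(
            {
                "patient_id": "p1",
                "drug_code": "X",
                "ingredient": ingredient,
                "drug_role": role,
                "agent_class": agent,
                "issue_date": issue,
                "daily_dose": dose,
                "supply_days": supply,
            }
        )
    return pd.DataFrame(recs)


class TestCoverageMerging:
    def test_within_tolerance_gap_merges(self, cfg):
        scripts = scripts_frame(
            [("citalopram", date(2016, 1, 1), 30), ("citalopram", date(2016, 2, 5), 30)]
        )
        (iv,) = expand_and_merge_coverage(scripts, cfg)
        assert (iv.start, iv.end) == (date(2016, 1, 1), date(2016, 3, 6))

    def test_gap_beyond_tolerance_splits(self, cfg):
        scripts = scripts_frame(
            [("citalopram", date(2016, 1, 1), 30), ("citalopram", date(2016, 4, 1), 30)]
        )
        out = expand_and_merge_coverage(scripts, cfg)  # 61-day gap after supply
        assert len(out) == 2

    def test_gap_exactly_at_tolerance_merges(self, cfg):
        scripts = scripts_frame(
            [("citalopram", date(2016, 1, 1), 30), ("citalopram", date(2016, 3, 31), 30)]
        )
        assert len(expand_and_merge_coverage(scripts, cfg)) == 1  # gap 60 == tolerance

    def test_overlapping_scripts_do_not_stack(self, cfg):
        scripts = scripts_frame(
            [("citalopram", date(2016, 1, 1), 30), ("citalopram", date(2016, 1, 10), 30)]
        )
        (iv,) = expand_and_merge_coverage(scripts, cfg)
        assert iv.end == date(2016, 2, 9)  # max end, not sum of supplies

    def test_single_script(self, cfg):
        (iv,) = expand_and_merge_coverage(
            scripts_frame([("citalopram", date(2016, 1, 1), 30)]), cfg
        )
        assert iv.days == 30


class TestDeriveSequences:
    def test_dose_change_does_not_split(self, cfg):
        scripts = scripts_frame(
            [
                ("citalopram", date(2016, 1, 1), 30, 20.0),
                ("citalopram", date(2016, 1, 31), 30, 40.0),
                ("citalopram", date(2016, 3, 1), 60, 40.0),
            ]
        )
        seqs = derive_sequences(expand_and_merge_coverage(scripts, cfg), cfg)
        assert len(seqs) == 1
        assert seqs[0].dose_changes == 1

    def test_partition_at_regimen_change_points(self, cfg):
        scripts = scripts_frame(
            [
                ("citalopram", date(2016, 1, 1), 90),
                ("mirtazapine", date(2016, 2, 20), 90),
            ]
        )
        seqs = derive_sequences(expand_and_merge_coverage(scripts, cfg), cfg)
        regimens = [set(s.regimen) for s in seqs]
        assert regimens == [
            {"citalopram"},
            {"citalopram", "mirtazapine"},
            {"mirtazapine"},
        ]
        # half-open convention: the new regimen owns each change date
        assert seqs[0].end == seqs[1].start and seqs[1].end == seqs[2].start

    def test_empty_coverage(self, cfg):
        assert derive_sequences([], cfg) == []

    def test_conservation_of_covered_days(self, cfg):
        scripts = scripts_frame(
            [
                ("citalopram", date(2016, 1, 1), 30),
                ("sertraline", date(2016, 1, 15), 30),
                ("citalopram", date(2016, 4, 1), 30),
            ]
        )
        coverage = expand_and_merge_coverage(scripts, cfg)
        seqs = derive_sequences(coverage, cfg)
        union_days = set()
        for iv in coverage:
            union_days.update(range(iv.start.toordinal(), iv.end.toordinal()))
        assert sum(s.days for s in seqs) == len(union_days)

    def test_idempotent_under_rederivation(self, cfg):
        scripts = scripts_frame(
            [
                ("citalopram", date(2016, 1, 1), 30),
                ("sertraline", date(2016, 1, 20), 45),
            ]
        )
        coverage = expand_and_merge_coverage(scripts, cfg)
        first = derive_sequences(coverage, cfg)
        second = derive_sequences(coverage, cfg)
        assert [(s.regimen, s.start, s.end) for s in first] == [
            (s.regimen, s.start, s.end) for s in second
        ]


class TestAugmentations:
    @pytest.mark.parametrize("overlap,attached", [(45, 1), (44, 0)])
    def test_overlap_threshold(self, cfg, overlap, attached):
        ad = scripts_frame([("sertraline", date(2016, 1, 1), 200)])
        seqs = derive_sequences(expand_and_merge_coverage(ad, cfg), cfg)
        agent = scripts_frame(
            [("lithium", date(2016, 2, 1), overlap, 400.0, "augmentation_agent", "lithium")]
        )
        agent_cov = expand_and_merge_coverage(agent, cfg)
        attach_augmentations(seqs, agent_cov, cfg)
        assert len(seqs[0].augmentations) == attached

    def test_agent_spanning_two_sequences_attaches_to_both(self, cfg):
        ad = scripts_frame(
            [
                ("sertraline", date(2016, 1, 1), 90),
                ("citalopram", date(2016, 3, 31), 90),
            ]
        )
        seqs = derive_sequences(expand_and_merge_coverage(ad, cfg), cfg)
        assert len(seqs) == 2
        agent = scripts_frame(
            [("quetiapine", date(2016, 1, 31), 120, 150.0, "augmentation_agent", "antipsychotic")]
        )
        attach_augmentations(seqs, expand_and_merge_coverage(agent, cfg), cfg)
        assert len(seqs[0].augmentations) == 1 and len(seqs[1].augmentations) == 1


class TestBruteForceOracle:
    """Random small script sets must match a day-by-day regimen scan."""

    def test_random_script_sets_match_daily_scan(self, cfg):
        rng = np.random.default_rng(2024)
        drugs = ["citalopram", "sertraline", "mirtazapine"]
        base = date(2016, 1, 1)
        for _ in range(300):
            n = int(rng.integers(1, 7))
            rows = [
                (
                    drugs[int(rng.integers(0, 3))],
                    base + timedelta(days=int(rng.integers(0, 400))),
                    int(rng.integers(7, 60)),
                )
                for _ in range(n)
            ]
            seqs = derive_sequences(
                expand_and_merge_coverage(scripts_frame(rows), cfg), cfg
            )
            expected = brute_force_sequences(
                rows, tolerance=cfg.same_regimen_gap_tolerance_days
            )
            got = [(s.start, s.end, s.regimen) for s in seqs]
            want = [(s, e, r) for s, e, r in expected]
            assert got == want, f"mismatch for scripts {rows}"


def test_build_patient_sequences_uses_only_antidepressants(cfg):
    scripts = scripts_frame(
        [
            ("sertraline", date(2016, 1, 1), 120),
            ("lithium", date(2016, 1, 10), 50, 400.0, "augmentation_agent", "lithium"),
            ("paracetamol", date(2016, 1, 10), 30, None, "other", None),
        ]
    )
    seqs = build_patient_sequences(scripts, cfg)
    assert len(seqs) == 1 and seqs[0].regimen == frozenset({"sertraline"})
    assert len(seqs[0].augmentations) == 1
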