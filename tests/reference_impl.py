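"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's interval arithmetic: coverage is
materialised day by day, gap-bridging is done on daily boolean vectors,
and the event rules are re-stated with explicit loops over every
(sequence, window) pair. Slow, simple, and only suitable for small
inputs.
"""

from __future__ import annotations

from datetime import date, timedelta


def brute_force_sequences(scripts, tolerance: int = 60):
    """Day-by-day regimen scan: (start, end, regimen) triples.

    ``scripts`` is an iterable of (ingredient, issue_date, supply_days).
    Per ingredient, every covered day is marked, then gaps of at most
    ``tolerance`` days between covered runs are filled; the daily
    ingredient sets are then run-length-encoded, dropping empty days.
    """
    per_ing: dict[str, set[int]] = {}
    for ingredient, issue, supply in scripts:
        days = per_ing.setdefault(ingredient, set())
        start = issue.toordinal()
        for d in range(start, start + int(supply)):
            days.add(d)
    # bridge within-tolerance gaps per ingredient
    for ingredient, days in per_ing.items():
        ordered = sorted(days)
        filled = set(days)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if 1 < b - a <= tolerance + 1:
                filled.update(range(a + 1, b))
        per_ing[ingredient] = filled
    if not per_ing:
        return []
    all_days = set().union(*per_ing.values())
    lo, hi = min(all_days), max(all_days)
    runs = []
    current = None  # (start_day, regimen)
    for day in range(lo, hi + 2):
        regimen = frozenset(i for i, ds in per_ing.items() if day in ds) if day <= hi else frozenset()
        if current is not None and regimen != current[1]:
            if current[1]:
                runs.append(
                    (
                        date.fromordinal(current[0]),
                        date.fromordinal(day),
                        current[1],
                    )
                )
            current = (day, regimen)
        elif current is None:
            current = (day, regimen)
    return runs


def reference_classify(seqs, ad_issue_dates, cfg, min_doses):
    """Exhaustive restatement of the outcome rules over sequence tuples.

    ``seqs``: list of (regimen frozenset, start date, end date,
    doses dict ingredient -> tuple of recorded numeric doses, augmented
    bool). Returns (event_counts dict, group, lines).
    """
    n = len(seqs)
    durations = [(s[2] - s[1]).days for s in seqs]
    responded = [d >= cfg.response_min_days for d in durations]
    low, high = cfg.relapse_window_days

    remitted = [False] * n
    for i in range(n):
        if not responded[i]:
            continue
        if durations[i] >= cfg.remission_response_days:
            remitted[i] = True
            continue
        window_end = seqs[i][2] + timedelta(days=cfg.remission_gap_days)
        if window_end > cfg.study_end + timedelta(days=1):
            continue
        if not any(seqs[i][2] <= d < window_end for d in ad_issue_dates):
            remitted[i] = True

    relapses = 0
    for i in range(n - 1):
        gap = (seqs[i + 1][1] - seqs[i][2]).days
        if responded[i] and low <= gap <= high:
            relapses += 1

    transitions = []
    for i in range(1, n):
        prev_reg, nxt_reg = seqs[i - 1][0], seqs[i][0]
        gap = (seqs[i][1] - seqs[i - 1][2]).days
        seen = {seqs[j][0] for j in range(i)}
        if nxt_reg > prev_reg and durations[i] >= cfg.combination_min_days:
            transitions.append("combination")
        elif (
            (prev_reg - nxt_reg)
            and (nxt_reg - prev_reg)
            and cfg.switch_gap_min_days <= gap <= cfg.switch_gap_max_days
        ):
            transitions.append("switch")
        elif (
            nxt_reg in seen
            and gap > cfg.same_regimen_gap_tolerance_days
            and not (responded[i - 1] and low <= gap <= high)
        ):
            transitions.append("resumption")
        else:
            transitions.append("none")

    failed = []
    for i in range(n):
        fail = not responded[i]
        if i < n - 1 and transitions[i] in ("switch", "combination"):
            fail = True
        if seqs[i][4]:
            fail = True
        failed.append(fail)

    # episodes and TRD
    episodes = []
    start = 0
    for i in range(n):
        gap_next = (seqs[i + 1][1] - seqs[i][2]).days if i + 1 < n else None
        if remitted[i] or (gap_next is not None and gap_next > cfg.episode_gap_days) or i == n - 1:
            episodes.append((start, i + 1))
            start = i + 1
    group = "MDD"
    lines = 0
    for lo_i, hi_i in episodes:
        initiated = {seqs[lo_i][0]}
        for i in range(lo_i + 1, hi_i):
            if transitions[i - 1] in ("switch", "combination"):
                initiated.add(seqs[i][0])
        lines = max(lines, len(initiated))
        distinct_failed = set()
        for i in range(lo_i, hi_i):
            if not failed[i] or durations[i] < cfg.adequate_line_min_days:
                continue
            adequate_dose = True
            for ingredient in seqs[i][0]:
                minimum = min_doses.get(ingredient)
                recorded = seqs[i][3].get(ingredient, ())
                if minimum is not None and recorded and max(recorded) < minimum:
                    adequate_dose = False
            if adequate_dose:
                distinct_failed.add(seqs[i][0])
        if len(distinct_failed) >= 2:
            group = "TRD"

    counts = {
        "response": sum(responded),
        "remission": sum(remitted),
        "relapse": relapses,
        "switch": transitions.count("switch"),
        "combination": transitions.count("combination"),
        "resumption": transitions.count("resumption"),
        "treatment_failure": sum(failed),
    }
    return counts, group, max(lines, 1)
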