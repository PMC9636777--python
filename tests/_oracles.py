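"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive expected results from first principles (manual
arithmetic, brute force, explicit decision tables) without touching the
implementation paths they check.
"""

from __future__ import annotations

import math

FIRST_LINE_DURATIONS = {"fosfomycin": 1, "nitrofurantoin": 5, "sxt": 3}


def decision_table(
    initial_drug: str,
    duration: int,
    allergy_mode: str,  # none | all_first_line | initial_drug
    initial_result: str,  # S | I | R on the initial agent
    switch_day: int | None,  # day of an oral SXT switch order, or None
    iv: bool,  # IV ceftriaxone on day 2
) -> dict:
    """Hand-written decision table for the adjudication clauses.

    Episode semantics mirror the pipeline: orders later than 28 days fall
    outside the episode entirely.
    """
    first_line = set(FIRST_LINE_DURATIONS)
    is_first = initial_drug in first_line

    received = {initial_drug}
    switch_in_episode = switch_day is not None and switch_day <= 28
    if switch_in_episode:
        received.add("sxt")
    if iv:
        received.add("ceftriaxone")

    if allergy_mode == "none":
        allergy = set()
    elif allergy_mode == "all_first_line":
        allergy = set(first_line)
    else:
        allergy = {initial_drug}

    panel = {initial_drug: initial_result}

    inappropriate = False
    if not is_first:
        # escalation justified only by allergy to every first-line agent or
        # documented resistance to every first-line agent (untested counts
        # against the escape)
        escape = first_line <= allergy or all(
            panel.get(d) in ("I", "R") for d in first_line
        )
        if not escape:
            inappropriate = True
    if any(panel.get(d) in ("I", "R") for d in received):
        inappropriate = True
    if received & allergy:
        inappropriate = True

    suboptimal = False
    if switch_in_episode and switch_day > 0 and "sxt" != initial_drug:
        suboptimal = True
    if iv:
        suboptimal = True
    if panel.get(initial_drug) in ("I", "R"):
        suboptimal = True

    strict_appropriate = False
    if is_first and duration == FIRST_LINE_DURATIONS[initial_drug]:
        strict_appropriate = True
    if not is_first and first_line <= allergy:
        strict_appropriate = True  # alternate line justified by allergy

    return {
        "inappropriate": inappropriate,
        "suboptimal": suboptimal,
        "appropriate": strict_appropriate,
        "final_appropriate": not inappropriate and not suboptimal,
    }


def percentile_lower(sorted_values, q: float) -> float:
    """Order-statistic percentile (floor of the interpolation rank)."""
    n = len(sorted_values)
    rank = math.floor((n - 1) * q / 100.0)
    return float(sorted_values[rank])


def winsorize_brute(values, q: float = 98.0) -> list[float]:
    threshold = percentile_lower(sorted(values), q)
    return [min(v, threshold) for v in values]


def smd_manual(a, b) -> float:
    """Continuous SMD by explicit arithmetic (sample variance, ddof=1)."""
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    return abs(ma - mb) / math.sqrt((va + vb) / 2.0)
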