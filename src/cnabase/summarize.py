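"""Arm-level call summarization and original-vs-adjusted discrepancy counts.

A whole chromosome arm is attributed the CNA state whose segments cover
at least half of the arm; uncovered territory counts toward the arm
length, so sparse profiles yield NONE rather than an over-confident
state.  Samples with at least one arm whose state changes after
baseline adjustment are classified as having baseline issues.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io_model import STATES, ArmTable, SegmentProfile, ValidationError

NONE_STATE = "NONE"


def arm_level_calls(profile: SegmentProfile, states: Sequence[str],
                    arms: ArmTable) -> dict[tuple[str, str], str]:
    """Arm state per (chrom, arm): the state covering >= 50% of the arm.

    ``states`` is the call vector to summarize (original or adjusted);
    it must align with ``profile.segments``.
    """
    if len(states) != len(profile.segments):
        raise ValidationError("state vector length does not match segment count")
    cover: dict[tuple[str, str], dict[str, float]] = {
        (chrom, arm): {st: 0.0 for st in STATES} for chrom, arm, _s, _e in arms
    }
    spans = {(chrom, arm): (start, end) for chrom, arm, start, end in arms}
    for seg, st in zip(profile.segments, states):
        for (chrom, arm), (a_start, a_end) in spans.items():
            if chrom != seg.chrom:
                continue
            overlap = min(a_end, seg.end) - max(a_start, seg.start)
            if overlap > 0:
                cover[(chrom, arm)][st] += overlap
    out = {}
    for key, per_state in cover.items():
        a_start, a_end = spans[key]
        arm_len = a_end - a_start
        best = max(STATES, key=lambda st: per_state[st])
        out[key] = best if per_state[best] >= 0.5 * arm_len else NONE_STATE
    return out


def count_discrepancies(original: Mapping[tuple[str, str], str],
                        adjusted: Mapping[tuple[str, str], str]) -> int:
    """Number of arms whose state differs between the two call sets."""
    if set(original) != set(adjusted):
        raise ValidationError("arm sets differ between original and adjusted calls")
    return sum(1 for key in original if original[key] != adjusted[key])


def arm_call_table(profiles, results, arms: ArmTable) -> pd.DataFrame:
    """Long-format per-sample arm call table with a discrepancy flag."""
    rows = []
    by_sample = {r.sample_id: r for r in results}
    for profile in profiles:
        res = by_sample.get(profile.sample_id)
        orig = arm_level_calls(profile, profile.states, arms)
        adj_states = res.adjusted_states if res is not None else profile.states
        adj = arm_level_calls(profile, adj_states, arms)
        for (chrom, arm) in sorted(orig):
            rows.append({
                "sample_id": profile.sample_id,
                "chrom": chrom,
                "arm": arm,
                "original_state": orig[(chrom, arm)],
                "adjusted_state": adj[(chrom, arm)],
                "discrepant": int(orig[(chrom, arm)] != adj[(chrom, arm)]),
            })
    return pd.DataFrame(rows)
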