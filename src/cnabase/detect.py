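"""Baseline-anomaly detection on relative CNA segment profiles.

A mis-anchored copy-neutral baseline shows up as pervasive CNA calls
across the genome and/or an extreme imbalance between duplication and
deletion calls.  This module extracts the screening features — overall
CNA fraction, marker-weighted logR standard deviation, and the
duplication/deletion fraction ratio — and flags suspect profiles along
with the direction the baseline should be tested in.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import DEL, DUP, SegmentProfile, ValidationError

UP = "UP"
DOWN = "DOWN"
BOTH = "BOTH"
NONE = "NONE"


@dataclass(frozen=True)
class DetectionThresholds:
    """User-adjustable flagging thresholds.

    A profile is flagged when its CNA fraction alone is pervasive
    (``t_cna``), when high logR dispersion coincides with substantial
    CNA load (``t_sd`` with ``t_cna_sd``), or when the dup/del fraction
    ratio is extreme in either direction (``r_hi``/``r_lo``) together
    with a minimum CNA load (``t_skew``).  ``delta`` smooths the ratio
    so empty classes stay finite; keeping ``r_lo == 1/r_hi`` makes the
    skew test symmetric under swapping duplications and deletions.
    """

    t_cna: float = 0.7
    t_sd: float = 0.4
    t_cna_sd: float = 0.5
    r_hi: float = 5.0
    r_lo: float = 0.2
    t_skew: float = 0.3
    delta: float = 0.01

    def __post_init__(self) -> None:
        if not (self.r_hi > 1.0 > self.r_lo > 0.0):
            raise ValidationError("ratio bounds must satisfy r_hi > 1 > r_lo > 0")
        for name in ("t_cna", "t_sd", "t_cna_sd", "t_skew", "delta"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class BaselineFeatures:
    cna_fraction: float
    weighted_sd: float
    dup_frac: float
    del_frac: float
    dup_del_ratio: float


@dataclass(frozen=True)
class FlagResult:
    flagged: bool
    bias: str  # UP | DOWN | BOTH | NONE
    features: BaselineFeatures


def profile_features(profile: SegmentProfile, delta: float = 0.01) -> BaselineFeatures:
    """Length-weighted CNA fractions and the marker-weighted logR SD.

    Fractions are weighted by genomic segment length; the dispersion of
    the logR values is weighted by marker counts, which track how well
    each segment mean is supported.
    """
    lengths = profile.lengths
    total = lengths.sum()
    if total <= 0:
        raise ValidationError("profile has zero total segment length")
    states = np.array(profile.states)
    dup_frac = float(lengths[states == DUP].sum() / total)
    del_frac = float(lengths[states == DEL].sum() / total)

    w = profile.n_markers
    x = profile.logr
    mean = float(np.average(x, weights=w))
    weighted_sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))

    return BaselineFeatures(
        cna_fraction=dup_frac + del_frac,
        weighted_sd=weighted_sd,
        dup_frac=dup_frac,
        del_frac=del_frac,
        dup_del_ratio=(dup_frac + delta) / (del_frac + delta),
    )


def flag_profile(features: BaselineFeatures,
                 thresholds: DetectionThresholds = DetectionThresholds()) -> FlagResult:
    """Flag a profile whose features indicate a suspect baseline.

    The bias names the direction in which candidate baselines should be
    explored: an excess of duplication calls suggests the true neutral
    level sits above the current one (UP), an excess of deletions the
    opposite (DOWN), and pervasive CNA without directional skew leaves
    both directions open (BOTH).
    """
    t = thresholds
    f = features
    pervasive = f.cna_fraction > t.t_cna
    dispersed = f.weighted_sd > t.t_sd and f.cna_fraction > t.t_cna_sd
    skew_up = f.dup_del_ratio > t.r_hi and f.cna_fraction > t.t_skew
    skew_down = f.dup_del_ratio < t.r_lo and f.cna_fraction > t.t_skew
    flagged = pervasive or dispersed or skew_up or skew_down
    if not flagged:
        bias = NONE
    elif f.dup_del_ratio > t.r_hi:
        bias = UP
    elif f.dup_del_ratio < t.r_lo:
        bias = DOWN
    else:
        bias = BOTH
    return FlagResult(flagged=flagged, bias=bias, features=f)
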