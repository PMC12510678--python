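"""Synthetic cohorts of CNA segment profiles with known ground truth.

The generator emulates masked array-based segment profiles: each sample
carries per-arm integer copy states on a diploid background, a tumor
purity that scales logR amplitudes, marker-count-dependent segment-mean
noise, and — for a configurable subset — an injected normalization
anchor error that shifts every logR value, reproducing the failure mode
of density-based baseline anchoring in highly altered genomes.  The
emitted call column is a cutoff call on the (possibly shifted) values,
so it is deliberately wrong for shifted samples.  The emitted cohort
prior equals the empirical per-arm event rates of the generated truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import (PRIOR_FLOOR, ArmTable, CohortPrior, ProfileSet,
                       SampleMetadata, Segment, SegmentProfile,
                       ValidationError, call_state, default_arm_table,
                       floor_simplex)

MEDIAN_TO_MODE = "MEDIAN_TO_MODE"
CONSTANT = "CONSTANT"

#: copy number -> call state on a diploid background
CN_STATE = {1: "DEL", 2: "NEUT", 3: "DUP"}

# cohort-characteristic arm event pattern: some arms frequently gained,
# some frequently lost, some quiet (cycled over arms in genomic order)
_DEFAULT_EVENT_CYCLE = (
    (0.60, 0.02), (0.02, 0.50), (0.25, 0.05), (0.05, 0.25),
    (0.40, 0.10), (0.05, 0.05), (0.10, 0.40), (0.02, 0.02),
)


def default_arm_event_probs(arms: ArmTable) -> dict[tuple[str, str], tuple[float, float]]:
    """Deterministic per-arm (p_gain, p_loss) with a mixed CNA landscape."""
    out = {}
    for i, (chrom, arm, _s, _e) in enumerate(arms):
        out[(chrom, arm)] = _DEFAULT_EVENT_CYCLE[i % len(_DEFAULT_EVENT_CYCLE)]
    return out


@dataclass
class SimulationConfig:
    n_samples: int = 200
    arms: ArmTable | None = None
    arm_event_probs: dict[tuple[str, str], tuple[float, float]] | None = None
    purity_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.08          # segment-mean logR SD at 100 markers
    markers_per_mb: float = 10.0
    shift_fraction: float = 0.2
    shift_mode: str = MEDIAN_TO_MODE
    constant_shift: float = 0.4
    call_cutoff: float = 0.1
    seed: int = 0
    study_id: str = "SIM_STUDY"
    cohort_id: str = "SIM_COHORT"

    def __post_init__(self) -> None:
        if self.arms is None:
            self.arms = default_arm_table()
        if self.arm_event_probs is None:
            self.arm_event_probs = default_arm_event_probs(self.arms)
        for key, (pg, pl) in self.arm_event_probs.items():
            if not (0 <= pg <= 1 and 0 <= pl <= 1 and pg + pl <= 1):
                raise ValidationError(f"invalid event probabilities for arm {key}")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("purity_range must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.shift_fraction <= 1:
            raise ValidationError("shift_fraction must lie in [0, 1]")
        if self.shift_mode not in (MEDIAN_TO_MODE, CONSTANT):
            raise ValidationError(f"unknown shift_mode {self.shift_mode!r}")


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort."""

    arm_cn: dict[str, dict[tuple[str, str], int]]     # sample -> arm -> copy number
    purity: dict[str, float]
    shift: dict[str, float]                           # applied baseline shift b (0 = none)
    freqs: dict[tuple[str, str], tuple[float, float]]  # arm -> empirical (gain, loss) rate

    def arm_states(self, sample_id: str) -> dict[tuple[str, str], str]:
        return {key: CN_STATE[cn] for key, cn in self.arm_cn[sample_id].items()}

    def shifted_samples(self) -> list[str]:
        return [s for s, b in self.shift.items() if b != 0.0]


def ideal_logr(cn: int, purity: float) -> float:
    """Expected logR of an integer copy state at a given tumor purity."""
    return float(np.log2((purity * cn + 2.0 * (1.0 - purity)) / 2.0))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[ProfileSet, dict[str, SampleMetadata], CohortPrior, TruthSet]:
    """Generate a cohort with known truth; fully deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    arms = list(config.arms)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    n_shift = int(round(config.shift_fraction * config.n_samples))
    shifted = set(np.array(sample_ids)[rng.permutation(config.n_samples)[:n_shift]])

    profiles: dict[str, SegmentProfile] = {}
    metadata: dict[str, SampleMetadata] = {}
    arm_cn: dict[str, dict[tuple[str, str], int]] = {}
    purity_by: dict[str, float] = {}
    shift_by: dict[str, float] = {}

    lo, hi = config.purity_range
    for sid in sample_ids:
        purity = float(rng.uniform(lo, hi)) if hi > lo else lo
        cns: dict[tuple[str, str], int] = {}
        segs: list[Segment] = []
        for chrom, arm, a_start, a_end in arms:
            p_gain, p_loss = config.arm_event_probs[(chrom, arm)]
            u = rng.random()
            cn = 3 if u < p_gain else (1 if u < p_gain + p_loss else 2)
            cns[(chrom, arm)] = cn
            ideal = ideal_logr(cn, purity)
            n_seg = int(rng.integers(1, 4))
            parts = rng.dirichlet(np.full(n_seg, 5.0)) * (a_end - a_start)
            bounds = a_start + np.concatenate([[0.0], np.cumsum(parts)])
            bounds = np.round(bounds).astype(int)
            bounds[-1] = a_end
            for j in range(n_seg):
                s, e = int(bounds[j]), int(bounds[j + 1])
                if e <= s:
                    continue
                n_markers = max(5, int(round((e - s) / 1e6 * config.markers_per_mb)))
                sd = config.noise_sd * np.sqrt(100.0 / n_markers)
                logr = ideal + float(rng.normal(0.0, sd))
                # state filled in after the shift decision below
                segs.append(Segment(chrom, s, e, n_markers, logr, "NEUT"))

        b = 0.0
        if sid in shifted:
            if config.shift_mode == CONSTANT:
                b = config.constant_shift
            else:
                # anchor error: normalization centred the modal non-neutral state
                by_cn: dict[int, float] = {}
                for (chrom, arm, a_start, a_end) in arms:
                    cn = cns[(chrom, arm)]
                    if cn != 2:
                        by_cn[cn] = by_cn.get(cn, 0.0) + (a_end - a_start)
                if by_cn:
                    modal_cn = max(sorted(by_cn), key=lambda c: by_cn[c])
                    b = ideal_logr(modal_cn, purity)
        final = []
        for seg in segs:
            logr = seg.logr - b
            final.append(Segment(seg.chrom, seg.start, seg.end, seg.n_markers,
                                 logr, call_state(logr, config.call_cutoff)))
        profiles[sid] = SegmentProfile(sid, final)
        metadata[sid] = SampleMetadata(sid, config.study_id, config.cohort_id)
        arm_cn[sid] = cns
        purity_by[sid] = purity
        shift_by[sid] = b

    freqs = {}
    bins = []
    n = float(config.n_samples)
    for chrom, arm, a_start, a_end in arms:
        gain = sum(1 for sid in sample_ids if arm_cn[sid][(chrom, arm)] == 3) / n
        loss = sum(1 for sid in sample_ids if arm_cn[sid][(chrom, arm)] == 1) / n
        freqs[(chrom, arm)] = (gain, loss)
        p_dup, p_del, p_neut = floor_simplex((gain, loss, 1.0 - gain - loss),
                                             PRIOR_FLOOR)
        bins.append((chrom, a_start, a_end, p_dup, p_del, p_neut))

    prior = CohortPrior(config.cohort_id, bins)
    truth = TruthSet(arm_cn=arm_cn, purity=purity_by, shift=shift_by, freqs=freqs)
    return ProfileSet(profiles), metadata, prior, truth


# ---------------------------------------------------------------------------
# documentation archetypes
# ---------------------------------------------------------------------------

def _uniform_probs(arms: ArmTable, p_gain: float,
                   p_loss: float) -> dict[tuple[str, str], tuple[float, float]]:
    return {(c, a): (p_gain, p_loss) for c, a, _s, _e in arms}


def archetype_profiles(kind: int, seed: int = 0) -> SegmentProfile:
    """One deterministic profile per canonical baseline situation.

    1: correct baseline, moderate CNA load (passes detection);
    2: shifted baseline with a moderately altered genome;
    3: correct baseline but the copy-neutral state holds only a minority
       of markers (pervasive CNA);
    4: shifted baseline with a multi-modal logR distribution.
    """
    if kind not in (1, 2, 3, 4):
        raise ValidationError("archetype kind must be 1..4")
    arms = default_arm_table()
    base = dict(n_samples=1, arms=arms, purity_range=(0.9, 0.9), noise_sd=0.05,
                seed=seed * 10 + kind, study_id=f"ARCHETYPE{kind}",
                cohort_id=f"ARCHETYPE{kind}")
    if kind == 1:
        cfg = SimulationConfig(arm_event_probs=_uniform_probs(arms, 0.10, 0.08),
                               shift_fraction=0.0, **base)
    elif kind == 2:
        cfg = SimulationConfig(arm_event_probs=_uniform_probs(arms, 0.15, 0.10),
                               shift_fraction=1.0, shift_mode=CONSTANT,
                               constant_shift=0.4, **base)
    elif kind == 3:
        cfg = SimulationConfig(arm_event_probs=_uniform_probs(arms, 0.75, 0.05),
                               shift_fraction=0.0, **base)
    else:
        cfg = SimulationConfig(arm_event_probs=_uniform_probs(arms, 0.50, 0.30),
                               shift_fraction=1.0, shift_mode=MEDIAN_TO_MODE, **base)
    profiles, _meta, _prior, _truth = simulate_cohort(cfg)
    return next(iter(profiles))
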