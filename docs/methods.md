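# Methods

This note documents the model, the procedure, the parameter choices and
their rationale, and the known limitations of `cnabase`. It is written
against the implementation in `src/cnabase/`; all symbols named here exist
in the code.

## 1. Data model and conventions

The unit of analysis is a **segment**: a genomic interval with a marker
count, a segment-mean log2 ratio (logR), and a 3-state call in
{DEL, NEUT, DUP}. Calls derive from logR by a symmetric cutoff:
logR ≥ 0.1 → DUP, logR ≤ −0.1 → DEL, otherwise NEUT (ties at the cutoff
are CNA calls). A **profile** is one sample's segments, sorted and
non-overlapping per chromosome; a **cohort prior** is a set of genomic bins
with per-state probabilities on the simplex.

Coordinates are 1-based inclusive in SEG files (the field convention) and
0-based half-open internally. Chromosome names are normalized by stripping
a `chr` prefix; only 1–22, X, Y are accepted. All per-segment statistics
weight segments by length (for genome-coverage quantities) or by marker
count (for logR dispersion and distribution fitting), never by raw segment
count, so results are invariant to how a segmentation algorithm happened to
split a constant region (tested: `test_invariant_to_splitting_segments`,
`TestInvarianceSuite`).

## 2. Detection of baseline mis-anchoring

A rigid baseline error leaves per-segment quality intact but produces a
genome-level signature. `profile_features` computes, per profile:

- `cna_fraction` — length fraction of the covered genome called non-neutral;
- `weighted_sd` — marker-weighted standard deviation of segment logR;
- `dup_frac`, `del_frac` — length fractions called DUP / DEL;
- `dup_del_ratio` — `(dup_frac + δ) / (del_frac + δ)` with δ = 0.01
  smoothing so profiles with no events of one kind still yield a finite,
  informative ratio.

`flag_profile` flags a profile when any of these hold
(defaults in `DetectionThresholds`):

| condition | default | reads as |
|---|---|---|
| pervasive: `cna_fraction > t_cna` | 0.7 | almost nothing left to be neutral |
| dispersed: `weighted_sd > t_sd` **and** `cna_fraction > t_cna_sd` | 0.4 / 0.5 | wide, mostly-altered profile |
| skew up: `dup_del_ratio > r_hi` **and** `dup_frac > t_skew` | 5 / 0.3 | gains vastly dominate |
| skew down: `dup_del_ratio < r_lo` **and** `del_frac > t_skew` | 0.2 / 0.3 | losses vastly dominate |

The bias direction is UP if `dup_del_ratio > r_hi` (apparent gains
everywhere ⇒ the baseline likely needs to move up), DOWN if `< r_lo`,
otherwise BOTH (candidates are enumerated in both directions). The
thresholds are deliberately conservative: a typical tumor genome has CNA
fractions well below 0.7, and a genuinely >70%-altered genome is exactly
the situation where density anchoring is unreliable anyway. Raising any
threshold can only unflag profiles (tested as a monotonicity property).

## 3. Candidate baselines via weighted 1-D mixture clustering

Segment logR values are clustered with a hand-written 1-D Gaussian mixture
EM, weighted by marker count. A hand-written EM is used because the
standard library implementations do not support per-sample weights in 1-D
fitting, and the weighting is essential: a 500-marker whole-arm segment
must count for more than a 5-marker focal blip.

- Initialization: weighted quantiles of the data (deterministic — no random
  restarts, so the whole pipeline is reproducible without a clustering
  seed).
- Model selection: k = 1…`k_max` (default 6; profiles effectively carry at
  most ~5 distinguishable copy levels after purity compression), chosen by
  BIC with 3k−1 free parameters.
- Hard assignment after fitting; adjacent clusters whose means differ by
  less than `min_sep` = 0.1 (one call-width — closer clusters cannot imply
  different calls) are merged. Variances are floored at 1e-4 to survive
  point-mass clusters.

The **baseline cluster** is the cluster holding the majority of
NEUT-called genome length (fallback: the cluster whose mean is nearest 0).
Candidate call sets then re-anchor the baseline on each cluster up to
`max_steps` = 2 clusters away in the bias direction(s): candidate offset =
that cluster's mean − baseline cluster's mean, and every segment is
re-called from its cluster's offset-adjusted mean through the same 0.1
cutoff. Two steps suffice because a mis-anchoring lands the baseline on an
adjacent copy level in all realistic failure modes; the zero-shift
candidate (the original calls) is always included.

## 4. Bayesian MAP selection

Each candidate is scored by

```
J(θ) = Σ_i [ log S(d'_i | θ_i, s) + log p(θ_i | r_i, c) ]
```

summing over the profile's segments, assumed independent.

**Plausibility** `S(d'|θ,s) = max(plaus_floor, 2·min(Φ(z), 1−Φ(z)))` with
`z = (d' − μ_{θ,s}) / σ_{θ,s}` — the two-sided Gaussian tail probability,
equal to 1 at the state mean and symmetric around it. The floor
(`plaus_floor` = 1e-10) keeps log-scores finite for extreme outliers so a
single aberrant segment cannot veto an otherwise overwhelming candidate.

**State distributions** are fitted per study (marker-weighted mean and SD
per state, `sigma_floor` = 0.01), because logR amplitudes depend on
platform and purity mix, both of which are study properties. The fit is
only trustworthy when most of the study is correctly anchored, so the rule
depends on the flagged fraction f: f > 0.5 → use the fixed **reference
distribution** (DEL ~ N(−0.35, 0.15), NEUT ~ N(0, 0.06),
DUP ~ N(0.30, 0.12) — magnitudes typical of impure tumor cohorts);
0.25 < f ≤ 0.5 → fit on non-flagged samples only; otherwise fit on all.
Any state with fewer than `min_n` = 10 segments borrows the reference
values, and a fit whose means violate DEL < NEUT < DUP falls back entirely.

**Priors** come from cohort gain/loss frequency tracks; a segment's prior
is the overlap-length-weighted mean over intersecting bins, renormalized.
All probabilities are floored at `prior_floor` = 1e-4: published zero
frequencies reflect finite cohorts, not impossibility, and a hard zero
would make `J` = −∞ regardless of the evidence.

`select_map` keeps the original calls unless a shifted candidate exceeds
the zero-shift score by `margin` (default 0 — strict improvement); ties
among shifted candidates prefer the smaller |shift|. Unflagged samples are
never re-anchored. Samples whose profile yields a single cluster or a
single candidate are reported with status `UNADJUSTABLE` and passed
through unchanged.

The counter-evidential **least-likely prior** (per bin: 0.98 on the
argmin-probability state, 0.01 elsewhere, ties broken DEL < NEUT < DUP) is
a built-in control: replacing the real prior with it must measurably
degrade adjustment quality, demonstrating that the cohort information is
load-bearing rather than decorative.

## 5. Arm-level summary

Original and adjusted calls are reduced to chromosome-arm calls: the state
whose segments cover at least 50% of the arm length (uncovered bases count
in the denominator; no majority → NONE). A sample with ≥1 discrepant arm
between original and adjusted tables is marked `baseline_issue`. Arm
resolution is the right granularity here because baseline errors re-label
whole copy-level plateaus, not focal events.

## 6. Synthetic cohort generator

`simulate_cohort` emulates relative CNA profiles with known truth:

- Per sample, each chromosome arm draws an integer copy number in {1, 2, 3}
  from arm-specific (p_gain, p_loss); the default landscape cycles eight
  (gain, loss) patterns over arms in genomic order so the cohort has
  recurrently gained, recurrently lost, and quiet arms.
- Arms are split into 1–3 segments (Dirichlet lengths); segment logR =
  `log2((purity·CN + 2(1−purity))/2)` plus Gaussian noise with
  SD = `noise_sd · sqrt(100 / n_markers)` — segment means of many markers
  are tighter, matching how segment-mean noise scales in real data.
  Marker counts use 10 markers/Mb.
- A configured fraction of samples receives an **anchor error**: in
  `MEDIAN_TO_MODE` mode the baseline is moved onto the ideal logR of the
  sample's modal non-neutral copy state (reproducing density-mode
  mis-anchoring; samples with no events get no shift), or a `CONSTANT`
  shift. Emitted calls are cutoff calls on the shifted values — i.e.
  deliberately wrong for shifted samples, as in real pipeline output.
- The emitted cohort prior equals the empirical per-arm event rates of the
  generated truth (floored onto the simplex), and a `TruthSet` records
  per-arm copy numbers, purity, and applied shifts.

What it does **not** emulate: focal events smaller than an arm segment,
subclonal (non-integer) copy states, whole-genome duplication ploidy
states beyond CN 3, sex-chromosome baseline differences, wavy logR
artifacts, or segmentation errors. These are orthogonal to the baseline
question the package addresses.

`archetype_profiles` exposes four canonical single-sample situations for
tests and demos: (1) correct baseline with moderate CNA load, (2) shifted
baseline on a moderately altered genome, (3) correct baseline with
pervasive CNA, (4) shifted baseline with a multi-modal logR distribution.

## 7. Numerical choices

- EM: weights rescaled to sum to n so BIC magnitudes match unweighted
  conventions; convergence at |ΔlogL| < 1e-8 or 300 iterations; variance
  floor 1e-4.
- All simplex projections floor at 1e-4 (priors) or 1e-9 (internal) and
  renormalize; a prior file with gain+loss > 1 is rescaled proportionally
  with a warning rather than rejected.
- Candidate scores are compared on the key `(J, −|shift|)` so exact ties
  deterministically prefer conservatism.
- Every stochastic entry point takes a single integer seed; derived seeds
  stay below 2^31. Reruns are byte-identical (tested).

## 8. Open design decisions and limitations

- **Thresholds are heuristics.** The detection thresholds encode broad
  knowledge of tumor CNA landscapes, not a fitted classifier; cohorts with
  genuinely extreme biology (e.g. near-haploid leukemias) may be flagged
  while correctly anchored. The MAP stage is the safeguard: such samples
  keep their original calls unless a shift strictly wins.
- **Segment independence** in `J` ignores spatial correlation; adjacent
  segments of one event are counted as independent evidence. This inflates
  |J| but affects all candidates of a profile similarly, so rankings are
  mostly unaffected.
- **Single rigid offset.** Only translation errors are modeled; per-
  chromosome or wavy normalization artifacts are out of scope.
- **Three states.** High-level amplifications and homozygous deletions are
  folded into DUP/DEL; the plausibility Gaussians absorb them in the tails.
- **Study distribution contamination.** With flagged fraction ≤ 0.25 the
  per-state fits include mis-called segments from shifted samples; this is
  tolerated because at that contamination level the marker-weighted fits
  move little, and the FITTED_CLEAN / REFERENCE rules take over when
  contamination grows.
- Problem sizes used in tests and the acceptance script (cohorts of 200
  samples, ~40 arms, 1–3 segments per arm) are this package's own choice:
  large enough for stable rates, small enough to run in seconds.
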