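import math

import numpy as np
import pytest
from scipy.stats import norm

from cnabase import (DEL, DUP, NEUT, CandidateCallSet, CohortPrior, Segment,
                     SegmentProfile, StateDistributions, ValidationError,
                     fit_state_distributions, least_likely_prior, objective,
                     plausibility, reference_distributions, segment_prior,
                     select_map)
from cnabase.bayes import FITTED, FITTED_CLEAN, REFERENCE

MB = 1_000_000


def dists(mu=(-0.5, 0.0, 0.5), sigma=(0.1, 0.05, 0.1), source=FITTED):
    return StateDistributions(
        study_id="T", mu={DEL: mu[0], NEUT: mu[1], DUP: mu[2]},
        sigma={DEL: sigma[0], NEUT: sigma[1], DUP: sigma[2]}, source=source)


def seg(chrom="1", start_mb=0, end_mb=10, logr=0.0, state=NEUT, markers=100):
    return Segment(chrom, int(start_mb * MB), int(end_mb * MB), markers, logr, state)


class TestSegmentPrior:
    def test_single_bin_identity(self):
        prior = CohortPrior("C", [("1", 0, 100 * MB, 0.2, 0.3, 0.5)])
        assert segment_prior(prior, seg(start_mb=10, end_mb=20)) == \
            pytest.approx((0.2, 0.3, 0.5))

    def test_equal_overlap_mean(self):
        prior = CohortPrior("C", [("1", 0, 10 * MB, 0.2, 0.2, 0.6),
                                  ("1", 10 * MB, 20 * MB, 0.4, 0.2, 0.4)])
        p_dup, _p_del, _p_neut = segment_prior(prior, seg(start_mb=5, end_mb=15))
        assert p_dup == pytest.approx(0.3)

    def test_overlap_length_weighting(self):
        # 3 Mb overlap with p_dup 0.1, 1 Mb with p_dup 0.5 -> 0.75*0.1 + 0.25*0.5
        prior = CohortPrior("C", [("1", 0, 10 * MB, 0.1, 0.3, 0.6),
                                  ("1", 10 * MB, 20 * MB, 0.5, 0.1, 0.4)])
        p_dup, _, _ = segment_prior(prior, seg(start_mb=7, end_mb=11))
        assert p_dup == pytest.approx(0.2)

    def test_uncovered_segment_gets_uniform_prior(self):
        prior = CohortPrior("C", [("1", 0, 10 * MB, 0.2, 0.3, 0.5)])
        with pytest.warns(UserWarning, match="no prior bin"):
            probs = segment_prior(prior, seg(chrom="7"))
        assert probs == pytest.approx((1 / 3, 1 / 3, 1 / 3))


class TestPlausibility:
    def test_peak_at_state_mean(self):
        d = dists()
        for st in (DEL, NEUT, DUP):
            assert plausibility(d.mu[st], st, d) == pytest.approx(1.0)

    def test_one_sigma_tail(self):
        d = dists()
        expected = 2 * (1 - norm.cdf(1.0))
        assert plausibility(d.mu[NEUT] + d.sigma[NEUT], NEUT, d) == \
            pytest.approx(expected, abs=1e-6)

    def test_floor_and_symmetry(self):
        d = dists()
        lo = plausibility(d.mu[DUP] - 10 * d.sigma[DUP], DUP, d, floor_eps=1e-10)
        hi = plausibility(d.mu[DUP] + 10 * d.sigma[DUP], DUP, d, floor_eps=1e-10)
        assert lo == hi == 1e-10


class TestObjective:
    def test_single_segment_uniform_prior(self, uniform_prior):
        d = dists()
        profile = SegmentProfile("S", [seg(logr=0.0, state=NEUT)])
        cand = CandidateCallSet(baseline_cluster=0, offset=0.0, states=(NEUT,),
                                shift_steps=0)
        j = objective(cand, profile, uniform_prior, d)
        assert j == pytest.approx(math.log(1 / 3), abs=1e-9)

    def test_additivity_under_segment_duplication(self, uniform_prior):
        d = dists()
        p1 = SegmentProfile("S", [seg(start_mb=0, end_mb=10, logr=0.3, state=DUP)])
        c1 = CandidateCallSet(0, 0.0, (DUP,), 0)
        p2 = SegmentProfile("S", [seg(start_mb=0, end_mb=5, logr=0.3, state=DUP),
                                  seg(start_mb=5, end_mb=10, logr=0.3, state=DUP)])
        c2 = CandidateCallSet(0, 0.0, (DUP, DUP), 0)
        assert objective(c2, p2, uniform_prior, d) == \
            pytest.approx(2 * objective(c1, p1, uniform_prior, d), abs=1e-9)

    def test_plausibility_uses_offset_adjusted_values(self, uniform_prior):
        d = dists()
        profile = SegmentProfile("S", [seg(logr=0.58, state=NEUT)])
        on_baseline = CandidateCallSet(1, 0.58, (NEUT,), 1)
        off_baseline = CandidateCallSet(0, 0.0, (NEUT,), 0)
        assert objective(on_baseline, profile, uniform_prior, d) > \
            objective(off_baseline, profile, uniform_prior, d)

    def test_mismatched_candidate_rejected(self, uniform_prior):
        profile = SegmentProfile("S", [seg()])
        bad = CandidateCallSet(0, 0.0, (NEUT, NEUT), 0)
        with pytest.raises(ValidationError):
            objective(bad, profile, uniform_prior, dists())


class TestSelectMap:
    def test_single_candidate_keeps_original(self, uniform_prior):
        profile = SegmentProfile("S", [seg(logr=0.0, state=NEUT)])
        res = select_map([CandidateCallSet(0, 0.0, (NEUT,), 0)], profile,
                         uniform_prior, dists())
        assert res.chosen == 0
        assert res.adjusted_states == [NEUT]

    def test_better_shift_is_chosen(self, uniform_prior):
        # data sits at 0.58; the shifted candidate explains it as neutral
        profile = SegmentProfile("S", [seg(logr=0.58, state=DUP),
                                       seg(start_mb=10, end_mb=20, logr=0.58,
                                           state=DUP)])
        cands = [CandidateCallSet(0, 0.0, (DUP, DUP), 0),
                 CandidateCallSet(1, 0.58, (NEUT, NEUT), 1)]
        res = select_map(cands, profile, uniform_prior, dists())
        assert res.chosen == 1
        assert res.adjusted_states == [NEUT, NEUT]
        assert res.chosen_offset == pytest.approx(0.58)

    def test_no_improvement_retains_original_states(self, uniform_prior):
        profile = SegmentProfile("S", [seg(logr=0.0, state=NEUT)])
        cands = [CandidateCallSet(0, 0.0, (NEUT,), 0),
                 CandidateCallSet(1, 0.5, (DEL,), 1)]
        res = select_map(cands, profile, uniform_prior, dists())
        assert res.chosen == 0
        assert res.adjusted_states == list(profile.states)
        assert res.chosen_offset == 0.0

    def test_margin_blocks_marginal_improvements(self, uniform_prior):
        profile = SegmentProfile("S", [seg(logr=0.29, state=NEUT)])
        d = dists(mu=(-0.5, 0.0, 0.58), sigma=(0.1, 0.3, 0.3))
        cands = [CandidateCallSet(0, 0.0, (NEUT,), 0),
                 CandidateCallSet(1, 0.58, (NEUT,), 1)]
        free = select_map(cands, profile, uniform_prior, d, margin=0.0)
        gated = select_map(cands, profile, uniform_prior, d, margin=100.0)
        assert gated.chosen == 0
        assert free.candidates == gated.candidates

    def test_missing_zero_shift_rejected(self, uniform_prior):
        profile = SegmentProfile("S", [seg()])
        with pytest.raises(ValidationError):
            select_map([CandidateCallSet(1, 0.5, (NEUT,), 1)], profile,
                       uniform_prior, dists())


def flat_profiles(n, logr_by_state, markers=100, n_segs=4):
    """n single-study profiles whose segments sit exactly at given state means."""
    out = []
    for i in range(n):
        segs = []
        pos = 0
        for j in range(n_segs):
            st = [DEL, NEUT, DUP][j % 3]
            segs.append(Segment("1", pos * MB, (pos + 10) * MB, markers,
                                logr_by_state[st], st))
            pos += 10
        out.append(SegmentProfile(f"P{i}", segs))
    return out


class TestFitStateDistributions:
    LOGR = {DEL: -0.4, NEUT: 0.0, DUP: 0.45}

    def test_majority_flagged_uses_reference(self):
        profiles = flat_profiles(10, self.LOGR)
        flags = {f"P{i}": i < 6 for i in range(10)}
        d = fit_state_distributions(profiles, flags, min_n=1)
        assert d.source == REFERENCE
        ref = reference_distributions()
        assert d.mu == ref.mu

    def test_quarter_flagged_fits_on_clean_samples(self):
        clean = flat_profiles(7, self.LOGR)
        biased = flat_profiles(3, {DEL: -1.0, NEUT: -0.5, DUP: 0.1})
        for i, p in enumerate(biased):
            p.sample_id = f"B{i}"
        flags = {p.sample_id: p.sample_id.startswith("B") for p in clean + biased}
        d = fit_state_distributions(clean + biased, flags, min_n=1)
        assert d.source == FITTED_CLEAN
        assert d.mu[DUP] == pytest.approx(0.45, abs=1e-9)  # biased samples excluded

    def test_low_flag_fraction_fits_on_all(self):
        profiles = flat_profiles(10, self.LOGR)
        flags = {f"P{i}": i < 2 for i in range(10)}
        d = fit_state_distributions(profiles, flags, min_n=1)
        assert d.source == FITTED
        assert d.mu[NEUT] == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_on_simulated_segments(self):
        rng = np.random.default_rng(9)
        segs = [Segment("1", i * MB, (i + 1) * MB, 100,
                        float(rng.normal(0.0, 0.05)), NEUT)
                for i in range(500)]
        segs += [Segment("2", 0, 10 * MB, 100, -0.4, DEL),
                 Segment("2", 10 * MB, 20 * MB, 100, 0.45, DUP)]
        profile = SegmentProfile("P0", segs)
        d = fit_state_distributions([profile], {"P0": False}, min_n=1)
        assert d.mu[NEUT] == pytest.approx(0.0, abs=0.01)
        assert d.sigma[NEUT] == pytest.approx(0.05, abs=0.01)

    def test_sparse_state_borrows_reference(self):
        profiles = flat_profiles(2, self.LOGR, n_segs=3)
        d = fit_state_distributions(profiles, {p.sample_id: False for p in profiles},
                                    min_n=10)
        ref = reference_distributions()
        assert d.mu == ref.mu  # 2 segments per state < min_n everywhere

    def test_disordered_means_fall_back_to_reference(self):
        profiles = flat_profiles(4, {DEL: 0.5, NEUT: 0.0, DUP: -0.5})
        with pytest.warns(UserWarning, match="not ordered"):
            d = fit_state_distributions(profiles,
                                        {p.sample_id: False for p in profiles},
                                        min_n=1)
        assert d.source == REFERENCE


class TestLeastLikelyPrior:
    def test_lowest_probability_state_promoted(self):
        prior = CohortPrior("C", [("1", 0, MB, 0.5, 0.3, 0.2)])
        flipped = least_likely_prior(prior)
        _c, _s, _e, p_dup, p_del, p_neut = flipped.bins[0]
        assert (p_dup, p_del, p_neut) == (0.01, 0.01, 0.98)

    def test_uniform_tie_breaks_to_del(self):
        third = 1 / 3
        prior = CohortPrior("C", [("1", 0, MB, third, third, third)])
        _c, _s, _e, p_dup, p_del, p_neut = least_likely_prior(prior).bins[0]
        assert p_del == 0.98 and p_dup == p_neut == 0.01

    def test_simplex_preserved_and_not_idempotent(self):
        prior = CohortPrior("C", [("1", 0, MB, 0.7, 0.2, 0.1)])
        once = least_likely_prior(prior)
        twice = least_likely_prior(once)
        for p in (once, twice):
            for _c, _s, _e, *probs in p.bins:
                assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert once.bins != twice.bins
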