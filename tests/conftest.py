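import pytest

from cnabase import ArmTable, CohortPrior, ProfileSet, Segment, SegmentProfile

MB = 1_000_000


def make_profile(spec, sample_id="S1"):
    """Build a profile from (chrom, start_mb, end_mb, n_markers, logr, state) rows."""
    segs = [
        Segment(chrom, int(s * MB), int(e * MB), n_markers, logr, state)
        for chrom, s, e, n_markers, logr, state in spec
    ]
    return SegmentProfile(sample_id, segs)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def small_arms():
    """Two chromosomes, p/q arms of 50/50 and 40/40 Mb."""
    return ArmTable([
        ("1", "p", 0, 50 * MB),
        ("1", "q", 50 * MB, 100 * MB),
        ("2", "p", 0, 40 * MB),
        ("2", "q", 40 * MB, 80 * MB),
    ])


@pytest.fixture
def uniform_prior():
    """Single-cohort prior that is uniform over both test chromosomes."""
    third = 1.0 / 3.0
    return CohortPrior("C1", [
        ("1", 0, 100 * MB, third, third, third),
        ("2", 0, 80 * MB, third, third, third),
    ])


@pytest.fixture
def profile_set_factory():
    def build(profiles):
        return ProfileSet({p.sample_id: p for p in profiles})
    return build
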