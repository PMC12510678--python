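"""Domain types and I/O for segment tables, cohort priors, sample metadata and arm tables.

Copy-number segment profiles are exchanged as SEG-style tab-delimited
tables (one segment per row with a marker count and a mean log2 ratio).
Input coordinates follow the SEG convention (1-based, inclusive); all
in-memory coordinates are 0-based half-open and are converted back on
write.  Cohort priors are per-genomic-bin gain/loss frequencies, the
shape of 1 Mb frequency exports from cohort databases such as
Progenetix.
"""
from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cnabase")

# The three relative copy-number call states.
DEL = "DEL"
NEUT = "NEUT"
DUP = "DUP"
STATES = (DEL, NEUT, DUP)

#: default probability floor applied to prior bins
PRIOR_FLOOR = 1e-4

_CANONICAL_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One genomic interval with marker support, mean logR and a 3-state call."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    n_markers: int
    logr: float
    state: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: end must exceed start")
        if self.start < 0:
            raise ValidationError(f"segment start {self.start} < 0")
        if self.n_markers < 1:
            raise ValidationError(f"n_markers must be >= 1, got {self.n_markers}")
        if not np.isfinite(self.logr):
            raise ValidationError(f"non-finite logr for {self.chrom}:{self.start}")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """All segments of one sample, sorted by (chrom, start), non-overlapping."""

    sample_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"profile {self.sample_id} has no segments")
        self.segments = sorted(
            self.segments, key=lambda s: (_chrom_sort_key(s.chrom), s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on chromosome "
                    f"{seg.chrom} ({prev.start}-{prev.end} and {seg.start}-{seg.end})")
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def logr(self) -> np.ndarray:
        return np.array([s.logr for s in self.segments], dtype=float)

    @property
    def n_markers(self) -> np.ndarray:
        return np.array([s.n_markers for s in self.segments], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments], dtype=float)

    @property
    def states(self) -> list[str]:
        return [s.state for s in self.segments]

    def with_states(self, states: Sequence[str]) -> "SegmentProfile":
        """Return a copy of this profile with the call column replaced."""
        if len(states) != len(self.segments):
            raise ValidationError("state vector length does not match segment count")
        segs = [
            Segment(s.chrom, s.start, s.end, s.n_markers, s.logr, st)
            for s, st in zip(self.segments, states)
        ]
        return SegmentProfile(self.sample_id, segs)


@dataclass
class ProfileSet:
    """An ordered collection of per-sample profiles (one analysis run)."""

    profiles: dict[str, SegmentProfile]

    def __iter__(self):
        return iter(self.profiles.values())

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, sample_id: str) -> SegmentProfile:
        return self.profiles[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.profiles)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    study_id: str
    cohort_id: str


@dataclass
class CohortPrior:
    """Per-bin (p_dup, p_del, p_neut) probabilities for one cohort.

    Bins are stored 0-based half-open, non-overlapping and sorted per
    chromosome; every bin lies on the probability simplex with each
    component at least the configured floor.
    """

    cohort_id: str
    bins: list[tuple[str, int, int, float, float, float]]  # chrom, start, end, p_dup, p_del, p_neut
    _index: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        per_chrom: dict[str, list] = {}
        for chrom, start, end, pd_, pl, pn in self.bins:
            total = pd_ + pl + pn
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"prior bin {chrom}:{start}-{end} probabilities sum to {total}")
            if min(pd_, pl, pn) < 0:
                raise ValidationError(f"negative probability in bin {chrom}:{start}")
            per_chrom.setdefault(chrom, []).append((start, end, pd_, pl, pn))
        self._index.clear()
        for chrom, rows in per_chrom.items():
            rows.sort()
            prev_end = -1
            for start, end, *_ in rows:
                if start < prev_end:
                    raise ValidationError(f"overlapping prior bins on chromosome {chrom}")
                prev_end = end
            self._index[chrom] = np.array(rows, dtype=float)

    def bins_for(self, chrom: str) -> np.ndarray | None:
        """(start, end, p_dup, p_del, p_neut) rows for one chromosome, or None."""
        return self._index.get(chrom)


@dataclass
class ArmTable:
    """Chromosome-arm boundaries (0-based half-open internally)."""

    arms: list[tuple[str, str, int, int]]  # chrom, arm, start, end

    def __post_init__(self) -> None:
        by_chrom: dict[str, dict[str, tuple[int, int]]] = {}
        for chrom, arm, start, end in self.arms:
            if end <= start:
                raise ValidationError(f"arm {chrom}{arm}: end <= start")
            by_chrom.setdefault(chrom, {})[arm] = (start, end)
        for chrom, d in by_chrom.items():
            if "p" in d and "q" in d and d["p"][1] > d["q"][0]:
                raise ValidationError(f"chromosome {chrom}: p arm extends past q start")
        self.arms = sorted(self.arms, key=lambda a: (_chrom_sort_key(a[0]), a[2]))

    def __iter__(self):
        return iter(self.arms)

    def __len__(self) -> int:
        return len(self.arms)


def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def normalize_chrom(raw: str) -> str | None:
    """Canonical chromosome name: strip 'chr', keep 1-22/X/Y, else None."""
    name = str(raw).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper() if name.upper() in ("X", "Y") else name
    if name in _CANONICAL_CHROMS:
        return name
    return None


def call_state(logr: float, cutoff: float) -> str:
    """3-state cutoff call: DUP if logr >= cutoff, DEL if logr <= -cutoff."""
    if logr >= cutoff:
        return DUP
    if logr <= -cutoff:
        return DEL
    return NEUT


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SEG_ALIASES = {
    "sample": {"sample", "sample_id", "id"},
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"start", "loc.start", "loc_start"},
    "end": {"end", "loc.end", "loc_end"},
    "n_markers": {"n_markers", "num_mark", "num.mark", "markers", "num_probes"},
    "logr": {"logr", "seg.mean", "seg_mean", "segment_mean", "log2"},
    "state": {"state", "call", "status"},
}


def _resolve_columns(columns: Iterable[str], required: Sequence[str],
                     optional: Sequence[str] = ()) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    out: dict[str, str] = {}
    for key in list(required) + list(optional):
        found = None
        for alias in _SEG_ALIASES[key]:
            if alias in lower:
                found = lower[alias]
                break
        if found is None and key in required:
            raise FormatError(f"required column {key!r} not found in header")
        if found is not None:
            out[key] = found
    return out


def read_segments(path: str | Path, cutoff: float | None = None) -> ProfileSet:
    """Read a SEG-style tab-delimited table into one profile per sample.

    Input coordinates are 1-based inclusive; they are converted to
    0-based half-open.  If the table carries no call column, ``cutoff``
    must be given and states are derived by symmetric thresholding of
    the segment mean.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns, ["sample", "chrom", "start", "end",
                                         "n_markers", "logr"], ["state"])
    has_state = "state" in cols
    if not has_state and cutoff is None:
        raise FormatError(
            "segment table has no call column and no calling cutoff was given")

    logr = pd.to_numeric(df[cols["logr"]], errors="coerce")
    bad = logr.isna() & df[cols["logr"]].notna() | df[cols["logr"]].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header occupies line 1
        raise FormatError(f"non-numeric logr value at line {line}")
    try:
        start = pd.to_numeric(df[cols["start"]]).astype(int)
        end = pd.to_numeric(df[cols["end"]]).astype(int)
        n_markers = pd.to_numeric(df[cols["n_markers"]]).astype(int)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric coordinate or marker count: {exc}") from exc

    profiles: dict[str, list[Segment]] = {}
    n_dropped = 0
    for i in range(len(df)):
        chrom = normalize_chrom(df[cols["chrom"]].iloc[i])
        if chrom is None:
            n_dropped += 1
            continue
        if has_state:
            state = str(df[cols["state"]].iloc[i]).strip().upper()
            if state not in STATES:
                raise FormatError(
                    f"line {i + 2}: state must be one of {STATES}, got {state!r}")
        else:
            state = call_state(float(logr.iloc[i]), cutoff)
        seg = Segment(chrom=chrom, start=int(start.iloc[i]) - 1, end=int(end.iloc[i]),
                      n_markers=int(n_markers.iloc[i]), logr=float(logr.iloc[i]),
                      state=state)
        profiles.setdefault(str(df[cols["sample"]].iloc[i]), []).append(seg)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} segments on non-canonical contigs")
    if not profiles:
        raise FormatError(f"no usable segments in {path}")
    return ProfileSet({sid: SegmentProfile(sid, segs) for sid, segs in profiles.items()})


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "study_id", "cohort_id"):
        if col not in df.columns:
            raise FormatError(f"metadata is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id in metadata: {dupes}")
    return {
        r.sample_id: SampleMetadata(r.sample_id, r.study_id, r.cohort_id)
        for r in df.itertuples()
    }


def floor_simplex(probs: Sequence[float], floor_eps: float = PRIOR_FLOOR) -> tuple[float, ...]:
    """Floor each probability at ``floor_eps`` then renormalize to sum 1."""
    p = np.maximum(np.asarray(probs, dtype=float), floor_eps)
    return tuple(p / p.sum())


def _prior_rows_to_bins(rows: pd.DataFrame, floor_eps: float,
                        scale: str) -> list[tuple[str, int, int, float, float, float]]:
    gain = rows["gain_freq"].to_numpy(dtype=float)
    loss = rows["loss_freq"].to_numpy(dtype=float)
    if (gain < 0).any() or (loss < 0).any():
        raise ValidationError("negative frequency in prior table")
    if scale == "percent" or (scale == "auto" and max(gain.max(initial=0),
                                                      loss.max(initial=0)) > 1.0):
        gain, loss = gain / 100.0, loss / 100.0
    bins = []
    for chrom_raw, start, end, g, l in zip(rows["chrom"], rows["start"],
                                           rows["end"], gain, loss):
        chrom = normalize_chrom(chrom_raw)
        if chrom is None:
            continue
        if g + l > 1.0:
            # keep the gain:loss ratio, squeeze onto the simplex
            factor = (1.0 - floor_eps) / (g + l)
            warnings.warn(
                f"prior bin {chrom}:{start}: gain+loss={g + l:.3f} > 1, rescaled")
            g, l = g * factor, l * factor
        p_dup, p_del, p_neut = floor_simplex((g, l, 1.0 - g - l), floor_eps)
        bins.append((chrom, int(start) - 1, int(end), p_dup, p_del, p_neut))
    return bins


def read_priors(path: str | Path, floor_eps: float = PRIOR_FLOOR,
                scale: str = "auto") -> dict[str, CohortPrior]:
    """Read a prior table (TSV or JSON) into one CohortPrior per cohort.

    Frequencies may be percentages [0, 100] or fractions [0, 1]; with
    ``scale='auto'`` any value above 1 switches the whole file to
    percent interpretation.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("cohort_id", "chrom", "start", "end", "gain_freq", "loss_freq"):
        if col not in df.columns:
            raise FormatError(f"prior table is missing column {col!r}")
    out = {}
    for cohort_id, rows in df.groupby("cohort_id", sort=False):
        out[str(cohort_id)] = CohortPrior(
            str(cohort_id), _prior_rows_to_bins(rows, floor_eps, scale))
    return out


def read_prior(path: str | Path, floor_eps: float = PRIOR_FLOOR,
               scale: str = "auto", cohort_id: str | None = None) -> CohortPrior:
    """Read a single cohort's prior; errors if the file holds several cohorts."""
    priors = read_priors(path, floor_eps=floor_eps, scale=scale)
    if cohort_id is not None:
        if cohort_id not in priors:
            raise ValidationError(f"cohort {cohort_id!r} not present in {path}")
        return priors[cohort_id]
    if len(priors) != 1:
        raise ValidationError(
            f"{path} holds {len(priors)} cohorts; pass cohort_id to select one")
    return next(iter(priors.values()))


def read_arms(path: str | Path) -> ArmTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "arm", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"arm table is missing column {col!r}")
    arms = []
    for r in df.itertuples():
        chrom = normalize_chrom(r.chrom)
        if chrom is None:
            continue
        arms.append((chrom, str(r.arm), int(r.start) - 1, int(r.end)))
    return ArmTable(arms)


def default_arm_table() -> ArmTable:
    """The packaged hg38 p/q arm boundary table."""
    ref = importlib.resources.files("cnabase").joinpath("data/arms_hg38.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_arms(p)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def segments_to_frame(profiles: ProfileSet,
                      adjusted: Mapping[str, Sequence[str]] | None = None,
                      offsets: Mapping[str, float] | None = None) -> pd.DataFrame:
    """SEG-style frame with coordinates restored to 1-based inclusive.

    ``adjusted``/``offsets``, when given, add the corrected call column
    (written as ``state``, with the input call preserved as
    ``state_original``) and the applied logR offset.
    """
    rows = []
    for profile in profiles:
        adj = adjusted.get(profile.sample_id) if adjusted else None
        off = offsets.get(profile.sample_id, 0.0) if offsets else 0.0
        for i, s in enumerate(profile.segments):
            row = {
                "sample": profile.sample_id, "chrom": s.chrom,
                "start": s.start + 1, "end": s.end,
                "n_markers": s.n_markers, "logr": s.logr,
            }
            if adj is not None:
                row["state"] = adj[i]
                row["state_original"] = s.state
                row["offset"] = off
            else:
                row["state"] = s.state
            rows.append(row)
    return pd.DataFrame(rows)


def write_segments(path: str | Path, profiles: ProfileSet) -> None:
    """Write profiles as a plain SEG table (1-based inclusive coordinates)."""
    segments_to_frame(profiles).to_csv(path, sep="\t", index=False,
                                       float_format="%.6g")


def write_results(outdir: str | Path, results: Sequence, profiles: ProfileSet,
                  manifest: dict | None = None) -> None:
    """Write the adjusted SEG table, the per-sample report and the run manifest.

    ``results`` are AdjustmentResult objects (see :mod:`cnabase.bayes`);
    every result must reference a sample present in ``profiles``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    adjusted = {}
    offsets = {}
    report_rows = []
    for res in results:
        if res.sample_id not in profiles.profiles:
            raise ValidationError(f"result references unknown sample {res.sample_id}")
        adjusted[res.sample_id] = res.adjusted_states
        offsets[res.sample_id] = res.chosen_offset
        report_rows.append({
            "sample_id": res.sample_id,
            "flagged": int(res.flagged),
            "bias": res.bias,
            "n_candidates": len(res.candidates),
            "candidate_J": ";".join(
                f"{s:+d}:{j:.6g}" for s, _o, j in res.candidates),
            "chosen_shift": res.chosen,
            "chosen_offset": f"{res.chosen_offset:.6g}",
            "arm_discrepancies": res.arm_discrepancies,
            "baseline_issue": int(res.arm_discrepancies >= 1),
            "status": res.status,
        })
    frame = segments_to_frame(profiles, adjusted=adjusted, offsets=offsets)
    frame.to_csv(outdir / "adjusted.seg", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(report_rows).to_csv(outdir / "report.tsv", sep="\t", index=False)
    if manifest is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
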