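"""Unsupervised 1-D clustering of segment logR values and candidate baselines.

Segments of one sample are grouped by their mean logR with a
marker-count-weighted Gaussian mixture (model size chosen by BIC,
deterministic weighted-quantile initialization).  The cluster carrying
the copy-neutral calls anchors the current baseline; adjacent clusters
become candidate baselines, each implying a logR offset and a fresh set
of cluster-level 3-state calls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import BOTH, DOWN, NONE, UP
from .io_model import NEUT, SegmentProfile, ValidationError, call_state

logger = logging.getLogger("cnabase")


@dataclass(frozen=True)
class ClusterConfig:
    k_max: int = 6
    min_sep: float = 0.1     # clusters closer than one call-width merge
    cutoff: float = 0.1      # logR threshold for DUP/DEL recall
    max_steps: int = 2       # adjacent clusters tested per direction
    var_floor: float = 1e-4
    max_iter: int = 300
    tol: float = 1e-8


@dataclass
class ClusterModel:
    """Fitted 1-D cluster structure of one profile's logR values."""

    means: np.ndarray       # ascending cluster centers (logR units)
    weights: np.ndarray     # total marker weight per cluster
    assignment: np.ndarray  # per-segment cluster index

    @property
    def k(self) -> int:
        return len(self.means)


@dataclass(frozen=True)
class CandidateCallSet:
    """One candidate baseline and the 3-state calls it implies."""

    baseline_cluster: int
    offset: float           # weighted mean logR of the baseline cluster
    states: tuple[str, ...]
    shift_steps: int        # 0 = the original baseline


# ---------------------------------------------------------------------------
# weighted 1-D Gaussian mixture
# ---------------------------------------------------------------------------

def _weighted_quantiles(x: np.ndarray, w: np.ndarray, qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    cw /= ws.sum()
    return np.interp(qs, cw, xs)


def _em_1d(x: np.ndarray, w: np.ndarray, k: int, var_floor: float,
           max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted EM for a k-component 1-D Gaussian mixture.

    Weights act as per-observation multiplicities, rescaled to sum to
    the number of segments so that log-likelihoods (and hence BIC) stay
    comparable across samples with different marker totals.
    """
    n = x.size
    wn = w * (n / w.sum())
    qs = (np.arange(k) + 0.5) / k
    mu = _weighted_quantiles(x, wn, qs)
    var0 = max(float(np.average((x - np.average(x, weights=wn)) ** 2, weights=wn)),
               var_floor)
    var = np.full(k, var0)
    pi = np.full(k, 1.0 / k)

    loglik = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        logp = (-0.5 * (x[:, None] - mu) ** 2 / var
                - 0.5 * np.log(2.0 * np.pi * var) + np.log(pi))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        new_loglik = float(np.dot(wn, lse))
        resp = np.exp(logp - lse[:, None])
        # M-step
        rw = resp * wn[:, None]
        nj = rw.sum(axis=0) + 1e-300
        pi = nj / nj.sum()
        mu = (rw * x[:, None]).sum(axis=0) / nj
        var = np.maximum((rw * (x[:, None] - mu) ** 2).sum(axis=0) / nj, var_floor)
        if new_loglik - loglik < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return mu, var, pi, loglik


def _hard_model(x: np.ndarray, w: np.ndarray, mu: np.ndarray, var: np.ndarray,
                pi: np.ndarray) -> ClusterModel:
    logp = (-0.5 * (x[:, None] - mu) ** 2 / var
            - 0.5 * np.log(2.0 * np.pi * var) + np.log(pi))
    raw = logp.argmax(axis=1)
    # keep only populated clusters, sorted by their member-weighted mean
    labels = np.unique(raw)
    means = np.array([np.average(x[raw == c], weights=w[raw == c]) for c in labels])
    order = np.argsort(means)
    remap = {int(labels[j]): int(rank) for rank, j in enumerate(order)}
    assignment = np.array([remap[int(c)] for c in raw])
    means = means[order]
    weights = np.array([w[assignment == j].sum() for j in range(len(means))])
    return ClusterModel(means=means, weights=weights, assignment=assignment)


def _merge_close(model: ClusterModel, x: np.ndarray, w: np.ndarray,
                 min_sep: float) -> ClusterModel:
    means, weights, assignment = model.means, model.weights, model.assignment
    while len(means) > 1:
        gaps = np.diff(means)
        j = int(np.argmin(gaps))
        if gaps[j] >= min_sep:
            break
        assignment = np.where(assignment > j, assignment - 1, assignment)
        k = len(means) - 1
        means = np.array([np.average(x[assignment == c], weights=w[assignment == c])
                          for c in range(k)])
        weights = np.array([w[assignment == c].sum() for c in range(k)])
    return ClusterModel(means=means, weights=weights, assignment=assignment)


def cluster_segments(profile: SegmentProfile, k_max: int = 6, min_sep: float = 0.1,
                     var_floor: float = 1e-4, max_iter: int = 300,
                     tol: float = 1e-8) -> ClusterModel:
    """Cluster a profile's segment logR values.

    Fits marker-weighted 1-D Gaussian mixtures for k = 1..k_max, picks k
    by BIC, hard-assigns segments, then greedily merges adjacent
    clusters separated by less than ``min_sep`` (clusters closer than
    one call-width cannot change calls).
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    x = profile.logr
    w = profile.n_markers
    distinct = np.unique(x)
    if len(distinct) < 2 or len(x) < 2:
        mean = float(np.average(x, weights=w))
        return ClusterModel(means=np.array([mean]), weights=np.array([w.sum()]),
                            assignment=np.zeros(len(x), dtype=int))
    best = None
    best_bic = np.inf
    n = len(x)
    for k in range(1, min(k_max, len(distinct)) + 1):
        mu, var, pi, loglik = _em_1d(x, w, k, var_floor, max_iter, tol)
        bic = -2.0 * loglik + (3 * k - 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic = bic
            best = (mu, var, pi)
    model = _hard_model(x, w, *best)
    return _merge_close(model, x, w, min_sep)


# ---------------------------------------------------------------------------
# baseline identification and candidate generation
# ---------------------------------------------------------------------------

def identify_baseline_cluster(model: ClusterModel, profile: SegmentProfile) -> int:
    """Cluster anchoring the current baseline.

    The baseline cluster carries the largest total genomic length of
    segments currently called copy-neutral; profiles without any
    neutral call fall back to the cluster whose mean is closest to 0.
    Ties also resolve toward the mean closest to 0.
    """
    lengths = profile.lengths
    states = np.array(profile.states)
    neut_len = np.zeros(model.k)
    for j in range(model.k):
        sel = (model.assignment == j) & (states == NEUT)
        neut_len[j] = lengths[sel].sum()
    if neut_len.max() > 0:
        best_len = neut_len.max()
        tied = np.flatnonzero(neut_len == best_len)
    else:
        tied = np.arange(model.k)
    return int(tied[np.argmin(np.abs(model.means[tied]))])


def _candidate_for(model: ClusterModel, new_baseline: int, shift_steps: int,
                   cutoff: float) -> CandidateCallSet:
    offset = float(model.means[new_baseline])
    adj_means = model.means - offset
    cluster_states = [call_state(m, cutoff) for m in adj_means]
    states = tuple(cluster_states[int(c)] for c in model.assignment)
    return CandidateCallSet(baseline_cluster=new_baseline, offset=offset,
                            states=states, shift_steps=shift_steps)


def generate_candidates(model: ClusterModel, baseline: int, bias: str,
                        max_steps: int = 2, cutoff: float = 0.1) -> list[CandidateCallSet]:
    """Enumerate candidate baselines around the current one.

    The zero-shift candidate (the original baseline re-expressed through
    the cluster structure) is always first.  Bias UP explores clusters
    with higher means, DOWN lower means, BOTH both directions, each up
    to ``max_steps`` clusters away.  States are assigned per cluster:
    every member of a cluster shares the call implied by the cluster's
    offset-adjusted mean.
    """
    if max_steps < 1:
        raise ValidationError("max_steps must be >= 1")
    if not 0 <= baseline < model.k:
        raise ValidationError(f"baseline index {baseline} out of range")
    steps = [0]
    if bias in (UP, BOTH):
        steps += [s for s in range(1, max_steps + 1) if baseline + s < model.k]
    if bias in (DOWN, BOTH):
        steps += [-s for s in range(1, max_steps + 1) if baseline - s >= 0]
    if len(steps) == 1 and bias != NONE:
        logger.info("baseline cluster is already at the %s edge; no shifted "
                    "candidates available", "upper" if bias == UP else "lower")
    return [_candidate_for(model, baseline + s, s, cutoff) for s in steps]
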