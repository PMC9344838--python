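"""Segmentation, mixture-model posteriors, SIQ and junction calling.

Given the M x K alignment matrix A, runs of identical columns segment the
junction squiggle; each segment is summarized by its median y_n (robust to
outliers), and every candidate assigns one (mu, sigma) to each segment.
A latent variable z in {1..M} indicates which candidate the squiggle came
from; conditional independence of the summaries gives the per-candidate
likelihood

    P(y | z=m) = prod_n N*(y_n; mu_{a_mn}, sigma_{a_mn}),

with N* the flat-tailed normal, and Bayes' rule with the candidate prior
(uniform unless supplied) gives the *assignment probability* P(z=m | y).

The *squiggle information quality* (SIQ) is the maximum over candidates of
the alignment log-likelihood per core state; squiggles that align well to
no candidate — off-target signal regions, pore artifacts — have uniformly
low SIQ and are filtered out before a call is attempted.  Default
thresholds: SIQ > -0.8 and strongest assignment probability > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSet
from .dtw import AlignmentResult, align_all, flat_normal_logpdf
from .pore_model import CandidateSquiggle, PoreModel
from .squiggle import JunctionSquiggle

__all__ = [
    "SegmentedSummary",
    "JunctionCall",
    "segment",
    "candidate_loglik",
    "assignment_probabilities",
    "compute_siq",
    "auto_siq_threshold",
    "apply_thresholds",
    "call_junction",
]

DEFAULT_SIQ_THRESHOLD = -0.8
DEFAULT_PROB_THRESHOLD = 0.8


@dataclass(frozen=True)
class SegmentedSummary:
    """Median summaries of maximal constant-column runs of A.

    ``y[n]`` is the median of x over kept segment n, ``bounds[n]`` its
    half-open index range in x, and ``state_indices[m, n]`` the single
    state of candidate m aligned to that segment (the summarized alignment
    matrix).  Segments shorter than ``min_len`` or longer than ``max_len``
    measurements are dropped as untrustworthy dwells.
    """

    y: np.ndarray
    bounds: tuple[tuple[int, int], ...]
    state_indices: np.ndarray  # M x N
    n_dropped: int = 0

    @property
    def N(self) -> int:
        return int(self.y.size)


def segment(
    x: JunctionSquiggle | np.ndarray,
    A: np.ndarray,
    min_len: int = 1,
    max_len: int | None = None,
) -> SegmentedSummary:
    """Partition x into runs of identical columns of A and summarize each.

    ``max_len=None`` sets the upper length filter to the 99.5th percentile
    (method "higher") of this squiggle's segment lengths, so only extreme
    dwell outliers are dropped.  Raises when every segment is filtered out.
    """
    xs = x.measurements if isinstance(x, JunctionSquiggle) else np.asarray(x, float)
    A = np.atleast_2d(np.asarray(A))
    if A.shape[1] != xs.size:
        raise ValueError("A must have one column per measurement")
    K = xs.size
    change = np.any(A[:, 1:] != A[:, :-1], axis=0)
    starts = np.concatenate(([0], np.flatnonzero(change) + 1))
    ends = np.concatenate((starts[1:], [K]))
    lengths = ends - starts
    if max_len is None:
        max_len = int(np.percentile(lengths, 99.5, method="higher"))
    keep = (lengths >= min_len) & (lengths <= max_len)
    if not keep.any():
        raise ValueError("no usable segments after length filtering")
    y = np.array([np.median(xs[s:e]) for s, e, k in zip(starts, ends, keep) if k])
    bounds = tuple((int(s), int(e)) for s, e, k in zip(starts, ends, keep) if k)
    state_indices = A[:, starts[keep]]
    return SegmentedSummary(
        y=y,
        bounds=bounds,
        state_indices=state_indices,
        n_dropped=int((~keep).sum()),
    )


def candidate_loglik(
    summary: SegmentedSummary,
    cand: CandidateSquiggle,
    m: int,
    tail_sd: float = 3.0,
) -> float:
    """Flat-tailed normal log-likelihood of the summaries under candidate m."""
    idx = summary.state_indices[m]
    mu = cand.means[idx]
    sigma = cand.sds[idx]
    return float(np.sum(flat_normal_logpdf(summary.y, mu, sigma, tail_sd)))


def assignment_probabilities(logliks, priors=None) -> np.ndarray:
    """Posterior P(z=m | y) by Bayes' rule: softmax of loglik + log prior.

    Computed with max-subtraction for stability; invariant to any common
    additive shift of the log-likelihoods.  Raises when no candidate has
    finite likelihood.
    """
    ll = np.asarray(logliks, dtype=float)
    if ll.size < 1:
        raise ValueError("need at least one candidate")
    if priors is None:
        priors = np.full(ll.size, 1.0 / ll.size)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != ll.shape or np.any(priors < 0):
        raise ValueError("priors must be non-negative, one per candidate")
    if abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    with np.errstate(divide="ignore"):
        logp = ll + np.log(priors)
    top = np.max(logp)
    if not np.isfinite(top):
        raise ValueError("no candidate explains the squiggle")
    p = np.exp(logp - top)
    return p / p.sum()


def compute_siq(results: list[AlignmentResult], squiggles: list[CandidateSquiggle]) -> float:
    """Max over candidates of alignment log-likelihood per core state.

    Uses the unsegmented DTW path log-likelihoods — SIQ measures alignment
    quality, which precedes summarization — and the non-buffer state count
    as denominator so buffer size does not distort the score.  Returns
    -inf when no candidate aligned.
    """
    best = float("-inf")
    for res, cand in zip(results, squiggles):
        if res.ok:
            best = max(best, res.path_loglik / cand.n_core_states)
    return best


def auto_siq_threshold(
    siqs,
    floor: float = DEFAULT_SIQ_THRESHOLD,
) -> float:
    """Empirical SIQ threshold: Q1 - 3*IQR of the pooled SIQs, floored.

    Flags squiggles whose SIQ is far below the bulk of the distribution,
    under the assumption that most JWRs align to the correct signal region.
    """
    finite = np.asarray([s for s in siqs if np.isfinite(s)], dtype=float)
    if finite.size == 0:
        return floor
    q1, q3 = np.percentile(finite, [25, 75])
    return max(float(q1 - 3.0 * (q3 - q1)), floor)


@dataclass(frozen=True)
class JunctionCall:
    """Per-JWR outcome: posteriors, SIQ, best candidate and filter status."""

    cands: CandidateSet
    probs: np.ndarray
    siq: float
    logliks: np.ndarray
    path_logliks: np.ndarray
    n_segments: int
    best: int | None
    passed_filters: bool
    reason: str | None = None  # failed_siq | failed_prob | unalignable | no_segments

    @property
    def best_junction(self):
        return None if self.best is None else self.cands.junctions[self.best]


def apply_thresholds(
    call: JunctionCall,
    siq_threshold: float = DEFAULT_SIQ_THRESHOLD,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> JunctionCall:
    """Re-apply pass/fail filters to an existing call (e.g. after pooling SIQs)."""
    import dataclasses

    if call.reason in ("unalignable", "no_segments"):
        return call
    best = int(np.argmax(call.probs))
    passed = call.siq > siq_threshold and call.probs[best] > prob_threshold
    reason = None
    if not passed:
        reason = "failed_siq" if call.siq <= siq_threshold else "failed_prob"
    return dataclasses.replace(
        call,
        best=best if passed else None,
        passed_filters=passed,
        reason=reason,
    )


def call_junction(
    cands: CandidateSet,
    x: JunctionSquiggle,
    model: PoreModel,
    tail_sd: float = 3.0,
    siq_threshold: float = DEFAULT_SIQ_THRESHOLD,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    min_seg_len: int = 1,
    max_seg_len: int | None = None,
) -> JunctionCall:
    """Full per-JWR pipeline: align, segment, score, filter, call.

    ``best`` is the argmax-probability candidate when both the SIQ and the
    strongest-probability thresholds are met, else None with the failure
    reason recorded.
    """
    squiggles = cands.squiggles(model)
    A, results = align_all(x, squiggles, tail_sd=tail_sd)
    path_logliks = np.array([r.path_loglik for r in results])
    ok = np.array([r.ok for r in results])
    M = cands.M
    if not ok.any():
        return JunctionCall(
            cands=cands,
            probs=np.zeros(M),
            siq=float("-inf"),
            logliks=np.full(M, -np.inf),
            path_logliks=path_logliks,
            n_segments=0,
            best=None,
            passed_filters=False,
            reason="unalignable",
        )
    siq = compute_siq(results, squiggles)

    try:
        summary = segment(x, A[ok], min_len=min_seg_len, max_len=max_seg_len)
    except ValueError:
        return JunctionCall(
            cands=cands,
            probs=np.zeros(M),
            siq=siq,
            logliks=np.full(M, -np.inf),
            path_logliks=path_logliks,
            n_segments=0,
            best=None,
            passed_filters=False,
            reason="no_segments",
        )

    logliks = np.full(M, -np.inf)
    ok_idx = np.flatnonzero(ok)
    for row, m in enumerate(ok_idx):
        logliks[m] = candidate_loglik(summary, squiggles[m], row, tail_sd=tail_sd)

    priors = cands.prior_weights[ok]
    probs_ok = assignment_probabilities(logliks[ok], priors / priors.sum())
    probs = np.zeros(M)
    probs[ok_idx] = probs_ok

    best = int(np.argmax(probs))
    passed = siq > siq_threshold and probs[best] > prob_threshold
    reason = None
    if not passed:
        reason = "failed_siq" if siq <= siq_threshold else "failed_prob"
    return JunctionCall(
        cands=cands,
        probs=probs,
        siq=siq,
        logliks=logliks,
        path_logliks=path_logliks,
        n_segments=summary.N,
        best=best if passed else None,
        passed_filters=passed,
        reason=reason,
    )
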