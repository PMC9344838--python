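"""Modified dynamic time warping of a junction squiggle to candidate squiggles.

The aligner treats the junction squiggle x = (x1..xK) as observations from
a model whose parameters are the candidate squiggle's per-state (mu, sigma),
and maximizes the summed flat-tailed normal log-density of the measurements
over monotone state assignments.  Modifications relative to textbook DTW:

* similarity is the model log-likelihood itself, so alignment scores feed
  the downstream mixture model directly;
* each measurement is assigned to exactly one state (steps advance the
  state by 0 or 1, never the measurement axis);
* open start/end restricted to the buffer states, absorbing imperfect
  trimming of the junction squiggle;
* every non-buffer (core) state must receive at least one measurement,
  preventing the squiggle from collapsing onto a small part of the
  candidate.  With {stay, advance-by-1} steps this holds exactly whenever
  the path starts within the head buffer and ends within the tail buffer.

Ties are broken toward the leftmost path (prefer the state advance to have
happened earlier); among equal-score admissible end states the largest is
taken.  Both rules make the traceback deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pore_model import CandidateSquiggle
from .squiggle import JunctionSquiggle

__all__ = [
    "AlignmentResult",
    "SquiggleTooShortError",
    "flat_normal_logpdf",
    "dtw_align",
    "align_all",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class SquiggleTooShortError(ValueError):
    """Fewer measurements than core states: coverage constraint unsatisfiable."""


@dataclass(frozen=True)
class AlignmentResult:
    """Best monotone assignment of measurements to one candidate's states."""

    path: np.ndarray  # state index per measurement, non-decreasing
    path_loglik: float
    start_state: int
    end_state: int
    ok: bool = True

    @classmethod
    def unalignable(cls) -> "AlignmentResult":
        return cls(
            path=np.empty(0, dtype=int),
            path_loglik=float("-inf"),
            start_state=-1,
            end_state=-1,
            ok=False,
        )


def flat_normal_logpdf(x, mu, sigma, tail_sd: float = 3.0):
    """Normal log-density floored at its value ``tail_sd`` sigmas from the mean.

    The flat tails bound the penalty of measurements that match none of the
    candidates (spikes, variants absent from the motifs).  The floored
    density is used unnormalized: posterior assignment probabilities only
    ever compare candidates at the same measurement values, so the common
    normalization constant cancels.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z2 = ((x - mu) / sigma) ** 2
    z2 = np.minimum(z2, tail_sd**2)
    return -np.log(sigma) - _LOG_SQRT_2PI - 0.5 * z2


def dtw_align(
    x: JunctionSquiggle | np.ndarray,
    cand: CandidateSquiggle,
    tail_sd: float = 3.0,
) -> AlignmentResult:
    """Optimal open-ended monotone alignment of x to one candidate squiggle.

    Returns the per-measurement state path and its total log-likelihood.
    Raises :class:`SquiggleTooShortError` when K is smaller than the number
    of core states, in which case no admissible path exists.
    """
    xs = x.measurements if isinstance(x, JunctionSquiggle) else np.asarray(x, float)
    K = xs.size
    S = cand.n_states
    bh, bt = cand.buffer_head, cand.buffer_tail
    if K < 1:
        raise ValueError("empty junction squiggle")
    if K < cand.n_core_states:
        raise SquiggleTooShortError(
            f"squiggle too short for candidate: K={K} < {cand.n_core_states} core states"
        )

    # K x S matrix of per-measurement log-densities
    dens = flat_normal_logpdf(xs[:, None], cand.means[None, :], cand.sds[None, :], tail_sd)

    dp = np.full(S, -np.inf)
    dp[: bh + 1] = dens[0, : bh + 1]
    advanced = np.zeros((K, S), dtype=bool)
    for k in range(1, K):
        shifted = np.concatenate(([-np.inf], dp[:-1]))
        adv = shifted > dp  # strict: on ties prefer stay (advance happened earlier)
        advanced[k] = adv
        dp = np.where(adv, shifted, dp) + dens[k]

    end_lo = S - 1 - bt
    tail_scores = dp[end_lo:]
    if not np.any(np.isfinite(tail_scores)):
        raise SquiggleTooShortError(
            "no admissible path reaches the tail buffer"
        )
    # prefer the largest end state on ties
    rev_arg = int(np.argmax(tail_scores[::-1]))
    end_state = S - 1 - rev_arg
    score = float(dp[end_state])

    path = np.empty(K, dtype=int)
    s = end_state
    for k in range(K - 1, 0, -1):
        path[k] = s
        if advanced[k, s]:
            s -= 1
    path[0] = s
    return AlignmentResult(
        path=path,
        path_loglik=score,
        start_state=int(path[0]),
        end_state=end_state,
    )


def align_all(
    x: JunctionSquiggle | np.ndarray,
    squiggles: list[CandidateSquiggle],
    tail_sd: float = 3.0,
) -> tuple[np.ndarray, list[AlignmentResult]]:
    """Align x to every candidate squiggle; stack the paths into A (M x K).

    Candidates failing the coverage constraint are flagged unalignable
    (never silently dropped); their rows in A are -1.
    """
    if not squiggles:
        raise ValueError("need at least one candidate squiggle")
    xs = x.measurements if isinstance(x, JunctionSquiggle) else np.asarray(x, float)
    K = xs.size
    results: list[AlignmentResult] = []
    A = np.full((len(squiggles), K), -1, dtype=int)
    for m, cand in enumerate(squiggles):
        try:
            res = dtw_align(xs, cand, tail_sd=tail_sd)
        except SquiggleTooShortError:
            res = AlignmentResult.unalignable()
        results.append(res)
        if res.ok:
            A[m] = res.path
    return A, results
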