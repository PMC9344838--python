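"""Diagnostic plot of a junction squiggle against one candidate squiggle.

Renders the candidate mean +/- 1 sd band over the state axis, the aligned
junction-squiggle measurements placed at their assigned states, and the
motif letters along the axis — the visual used to inspect why a candidate
was (or was not) preferred.
"""

from __future__ import annotations

import numpy as np

from .dtw import AlignmentResult
from .pore_model import CandidateSquiggle
from .squiggle import JunctionSquiggle

__all__ = ["plot_alignment", "band_containment"]


def band_containment(
    x: JunctionSquiggle | np.ndarray,
    cand: CandidateSquiggle,
    result: AlignmentResult,
    n_sd: float = 1.0,
) -> float:
    """Fraction of measurements within n_sd of their aligned state mean."""
    xs = x.measurements if isinstance(x, JunctionSquiggle) else np.asarray(x, float)
    if not result.ok:
        raise ValueError("cannot assess an unalignable candidate")
    mu = cand.means[result.path]
    sd = cand.sds[result.path]
    return float(np.mean(np.abs(xs - mu) <= n_sd * sd))


def plot_alignment(
    x: JunctionSquiggle | np.ndarray,
    cand: CandidateSquiggle,
    result: AlignmentResult,
    out_path,
    title: str | None = None,
) -> None:
    """Write a figure of the alignment to ``out_path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = x.measurements if isinstance(x, JunctionSquiggle) else np.asarray(x, float)
    if not result.ok:
        raise ValueError("cannot plot an unalignable candidate")

    states = np.arange(cand.n_states)
    fig, ax = plt.subplots(figsize=(max(6, cand.n_states / 6), 4))
    ax.plot(states, cand.means, color="tab:orange", lw=1.5, label="candidate mean")
    ax.fill_between(
        states,
        cand.means - cand.sds,
        cand.means + cand.sds,
        color="tab:orange",
        alpha=0.25,
        label="±1 sd",
    )
    # spread same-state measurements horizontally within the state's slot
    jitter = np.zeros(xs.size)
    for s in np.unique(result.path):
        idx = np.flatnonzero(result.path == s)
        if idx.size > 1:
            jitter[idx] = np.linspace(-0.35, 0.35, idx.size)
    ax.plot(
        result.path + jitter,
        xs,
        ".-",
        color="tab:blue",
        ms=3,
        lw=0.6,
        alpha=0.8,
        label="junction squiggle",
    )
    for i, base in enumerate(cand.motif[: cand.n_states]):
        ax.annotate(
            base,
            (i, 0),
            xycoords=("data", "axes fraction"),
            xytext=(0, -18),
            textcoords="offset points",
            ha="center",
            fontsize=6,
        )
    ax.set_xlabel("candidate state (k-mer position)")
    ax.set_ylabel("normalized current")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
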