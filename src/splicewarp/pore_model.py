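"""k-mer pore current-level models and candidate squiggle prediction.

A pore model maps every k-mer over {A,C,G,T} to the expected (normalized)
current mean and standard deviation while that k-mer occupies the pore.
Sliding the model over a junction motif yields the *candidate squiggle*:
the per-position (mu, sigma) sequence that an error-free translocation of
that motif would produce.  Model currents are assumed to be on the same
median/MAD-normalized scale as normalized junction squiggles; no rescaling
is applied at load time.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoreModel",
    "CandidateSquiggle",
    "load_pore_model",
    "write_pore_model",
    "synthetic_pore_model",
    "predict_candidate_squiggle",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PoreModel:
    """Complete k-mer current-level model.

    Attributes
    ----------
    k : int
        k-mer length; every one of the 4**k k-mers must be present.
    table : dict
        Maps k-mer string to ``(level_mean, level_sd)`` in normalized
        current units; every sd is strictly positive.
    """

    k: int
    table: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        expected = 4 ** self.k
        if len(self.table) != expected:
            missing = next(
                (
                    "".join(c)
                    for c in itertools.product(_BASES, repeat=self.k)
                    if "".join(c) not in self.table
                ),
                None,
            )
            raise ValueError(
                f"incomplete pore model: {len(self.table)}/{expected} k-mers"
                + (f", missing k-mer {missing}" if missing else "")
            )
        for kmer, (_, sd) in self.table.items():
            if len(kmer) != self.k:
                raise ValueError(f"mixed k-mer lengths: {kmer!r} vs k={self.k}")
            if not sd > 0:
                raise ValueError(f"non-positive sd for k-mer {kmer}")

    def __getitem__(self, kmer: str) -> tuple[float, float]:
        return self.table[kmer]


@dataclass(frozen=True)
class CandidateSquiggle:
    """Predicted squiggle for one candidate junction motif.

    ``means[i]``/``sds[i]`` give the expected current for the k-mer starting
    at motif position i (left-anchored convention).  ``buffer_head`` and
    ``buffer_tail`` count the states contributed by flanking buffer bases;
    these states may be skipped by the open-ended DTW, while every state in
    between (the *core*) must receive at least one measurement.
    """

    motif: str
    means: np.ndarray
    sds: np.ndarray
    buffer_head: int = 0
    buffer_tail: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ValueError("means and sds must be 1-D arrays of equal length")
        if np.any(self.sds <= 0):
            raise ValueError("all sigma must be strictly positive")
        if self.buffer_head < 0 or self.buffer_tail < 0:
            raise ValueError("buffer counts must be non-negative")
        if self.buffer_head + self.buffer_tail >= self.n_states:
            raise ValueError("buffers consume the entire candidate squiggle")

    @property
    def n_states(self) -> int:
        return int(self.means.size)

    @property
    def n_core_states(self) -> int:
        """States belonging to the junction motif proper (non-buffer)."""
        return self.n_states - self.buffer_head - self.buffer_tail


def load_pore_model(path) -> PoreModel:
    """Read a pore model from TSV with columns kmer, level_mean, level_sd."""
    frame = pd.read_csv(path, sep="\t")
    required = {"kmer", "level_mean", "level_sd"}
    if not required.issubset(frame.columns):
        raise ValueError(f"pore model TSV must have columns {sorted(required)}")
    table = {
        str(row.kmer): (float(row.level_mean), float(row.level_sd))
        for row in frame.itertuples()
    }
    if not table:
        raise ValueError("empty pore model table")
    k = len(next(iter(table)))
    return PoreModel(k=k, table=table)


def write_pore_model(model: PoreModel, path) -> None:
    """Write a pore model as the TSV dialect read by :func:`load_pore_model`."""
    kmers = sorted(model.table)
    frame = pd.DataFrame(
        {
            "kmer": kmers,
            "level_mean": [model.table[m][0] for m in kmers],
            "level_sd": [model.table[m][1] for m in kmers],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def _hash_unit(seed: int, kmer: str, salt: str) -> float:
    # stable across runs and platforms, unlike hash()
    digest = hashlib.sha256(f"{seed}:{salt}:{kmer}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


def synthetic_pore_model(k: int = 6, seed: int = 17) -> PoreModel:
    """Deterministic synthetic pore model for tests and simulations.

    Levels are a seeded hash of each k-mer mapped to means spanning about
    [-2, 2] with sds around 0.15-0.35 normalized-current units, then
    calibrated so that the k-mer mixture of normal current distributions
    has median 0 and MAD 1.  Model levels are thereby expressed on the same
    scale that per-read median/MAD normalization produces, the convention
    the candidate/junction squiggle comparison relies on.  The same
    (k, seed) always yields a bit-identical model.
    """
    from scipy.special import ndtr

    kmers = ["".join(c) for c in itertools.product(_BASES, repeat=k)]
    mus = np.array([4.0 * _hash_unit(seed, m, "mean") - 2.0 for m in kmers])
    sds = np.array([0.15 + 0.20 * _hash_unit(seed, m, "sd") for m in kmers])

    def cdf(x: float) -> float:
        return float(ndtr((x - mus) / sds).mean())

    def bisect(f, lo, hi, n=80):
        for _ in range(n):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    med = bisect(lambda x: cdf(x) - 0.5, -6.0, 6.0)
    mad = bisect(lambda d: (cdf(med + d) - cdf(med - d)) - 0.5, 0.0, 6.0)
    table = {
        kmer: ((mu - med) / mad, sd / mad)
        for kmer, mu, sd in zip(kmers, mus, sds)
    }
    return PoreModel(k=k, table=table)


def predict_candidate_squiggle(
    motif: str,
    model: PoreModel,
    buffer_head: int = 0,
    buffer_tail: int = 0,
) -> CandidateSquiggle:
    """Slide the pore model over ``motif`` to predict its squiggle.

    State i takes the model entry of the k-mer starting at motif position i,
    so a motif of length L yields L - k + 1 states.  Buffer counts are
    recorded unchanged for the aligner's open ends.
    """
    motif = motif.upper()
    if len(motif) < model.k:
        raise ValueError(
            f"motif of length {len(motif)} shorter than k={model.k}"
        )
    bad = set(motif) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT character(s) in motif: {sorted(bad)}")
    n = len(motif) - model.k + 1
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        means[i], sds[i] = model.table[motif[i : i + model.k]]
    return CandidateSquiggle(
        motif=motif,
        means=means,
        sds=sds,
        buffer_head=buffer_head,
        buffer_tail=buffer_tail,
    )
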