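"""Uniform access to reference genome sequence (FASTA file or in-memory dict)."""

from __future__ import annotations

__all__ = ["ReferenceSource", "revcomp"]

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ReferenceSource:
    """Fetches upper-case genomic sequence by 0-based half-open interval."""

    def __init__(self, getter, lengths: dict[str, int]):
        self._getter = getter
        self.lengths = lengths

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSource":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        lengths = {name: len(fa[name]) for name in fa.keys()}

        def getter(chrom: str, start: int, end: int) -> str:
            return str(fa[chrom][start:end])

        return cls(getter, lengths)

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "ReferenceSource":
        upper = {k: v.upper() for k, v in seqs.items()}

        def getter(chrom: str, start: int, end: int) -> str:
            return upper[chrom][start:end]

        return cls(getter, {k: len(v) for k, v in upper.items()})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.lengths:
            raise KeyError(f"unknown reference sequence {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or end < start:
            raise ValueError(
                f"reference slice {chrom}:{start}-{end} unavailable "
                f"(length {self.lengths[chrom]})"
            )
        return self._getter(chrom, start, end)
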