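"""Locate junctions-within-reads (JWRs) in spliced alignments and score JAQ.

A *JWR* is the subsequence of a read that is split-mapped across one intron
(one CIGAR N operation).  The *junction alignment quality* (JAQ) of a JWR is
the fraction of matched bases in its alignment over a window of 25 read
bases upstream and downstream of the mapped splice point; mismatches,
inserted read bases and deleted reference bases each count once against the
denominator, so a JAQ of 0.96 means 4% of window bases are inserted,
deleted or mismatched.  Reads whose junction alignments are already near
perfect (high JAQ) rarely benefit from squiggle-based correction, so JAQ
doubles as a cheap prefilter.

Coordinates are 0-based half-open throughout: an intron is the interval
[donor_end, acceptor_end) on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable

__all__ = ["SpliceJunction", "JWR", "extract_jwrs", "compute_jaq", "jaq_for_record"]

# CIGAR op codes as emitted by pysam
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)
_REF_OPS = {_M, _D, _N, _EQ, _X}
_QUERY_OPS = {_M, _I, _S, _EQ, _X}


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """One intron: [donor_end, acceptor_end) on ``chrom``, with transcript strand."""

    chrom: str
    donor_end: int
    acceptor_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.acceptor_end <= self.donor_end:
            raise ValueError("acceptor_end must exceed donor_end")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def intron_length(self) -> int:
        return self.acceptor_end - self.donor_end


@dataclass(frozen=True)
class JWR:
    """One junction-within-read plus the alignment context needed to score it.

    ``junction_qpos`` is the query position (orientation of the stored
    query sequence) of the first base after the splice; ``read_span`` is the
    JWR window converted to original basecalled-read coordinates, which is
    what signal event tables index.
    """

    read_id: str
    junction: SpliceJunction
    junction_qpos: int
    read_span: tuple[int, int]
    cigar: tuple[tuple[int, int], ...]
    ref_start: int
    read_length: int
    is_reverse: bool = False
    usable: bool = True
    jaq: float | None = None

    def with_jaq(self, jaq: float) -> "JWR":
        if not 0.0 <= jaq <= 1.0:
            raise ValueError("JAQ must lie in [0, 1]")
        return replace(self, jaq=jaq)


def _strand_of(record) -> str:
    for tag in ("ts", "XS"):
        if record.has_tag(tag):
            val = record.get_tag(tag)
            if val in "+-":
                return val
    return "-" if record.is_reverse else "+"


def extract_jwrs(record, flank: int = 25, min_side: int = 10) -> list[JWR]:
    """One JWR per CIGAR N operation of a mapped spliced record.

    The JWR window covers ``flank`` read bases on each side of the splice,
    clipped to the aligned portion of the read; JWRs with fewer than
    ``min_side`` aligned read bases on either side are flagged unusable.
    Unmapped or CIGAR-less records yield an empty list.
    """
    if record.is_unmapped or not record.cigartuples:
        return []
    cigar = tuple(record.cigartuples)
    read_len = record.query_length or sum(l for op, l in cigar if op in _QUERY_OPS)
    strand = _strand_of(record)
    aln_q_start = record.query_alignment_start
    aln_q_end = record.query_alignment_end

    jwrs: list[JWR] = []
    qpos, rpos = 0, record.reference_start
    for op, length in cigar:
        if op == _N:
            junction = SpliceJunction(
                chrom=record.reference_name,
                donor_end=rpos,
                acceptor_end=rpos + length,
                strand=strand,
            )
            left = qpos - aln_q_start
            right = aln_q_end - qpos
            q_lo = max(aln_q_start, qpos - flank)
            q_hi = min(aln_q_end, qpos + flank)
            if record.is_reverse:
                span = (read_len - q_hi, read_len - q_lo)
            else:
                span = (q_lo, q_hi)
            jwrs.append(
                JWR(
                    read_id=record.query_name,
                    junction=junction,
                    junction_qpos=qpos,
                    read_span=span,
                    cigar=cigar,
                    ref_start=record.reference_start,
                    read_length=read_len,
                    is_reverse=record.is_reverse,
                    usable=left >= min_side and right >= min_side,
                )
            )
        if op in _REF_OPS:
            rpos += length
        if op in _QUERY_OPS:
            qpos += length
    return jwrs


def compute_jaq(
    jwr: JWR,
    read_seq: str,
    ref_seq: str | Callable[[int], str],
    *,
    ref_offset: int = 0,
    flank: int = 25,
) -> float:
    """Fraction of matched bases within ``flank`` read bases of the splice.

    ``read_seq`` is the stored query sequence (same orientation the CIGAR
    was written against, soft clips included).  ``ref_seq`` is either the
    chromosome sequence as a string indexed by genomic coordinate minus
    ``ref_offset``, or a callable returning the base at a genomic position.
    Soft-clipped bases are outside the window by construction; deleted
    reference bases are attributed to the read position at which the
    deletion occurs.
    """
    if callable(ref_seq):
        ref_at = ref_seq
    else:

        def ref_at(g: int, _s=ref_seq, _o=ref_offset) -> str:
            return _s[g - _o]

    w_lo = jwr.junction_qpos - flank
    w_hi = jwr.junction_qpos + flank
    matches = mismatches = insertions = deletions = 0
    qpos, rpos = 0, jwr.ref_start
    for op, length in jwr.cigar:
        if op in (_M, _EQ, _X):
            lo = max(qpos, w_lo)
            hi = min(qpos + length, w_hi)
            for q in range(lo, hi):
                r = rpos + (q - qpos)
                if read_seq[q].upper() == ref_at(r).upper():
                    matches += 1
                else:
                    mismatches += 1
        elif op == _I:
            insertions += max(0, min(qpos + length, w_hi) - max(qpos, w_lo))
        elif op == _D:
            if w_lo <= qpos < w_hi:
                deletions += length
        if op in _REF_OPS:
            rpos += length
        if op in _QUERY_OPS:
            qpos += length
    total = matches + mismatches + insertions + deletions
    if total == 0:
        raise ValueError("no aligned bases within the JAQ window")
    return matches / total


def jaq_for_record(record, refsource=None, flank: int = 25) -> list[JWR]:
    """Extract JWRs from a pysam record and attach JAQ to each.

    Reference bases come from the record's MD tag when present, otherwise
    from ``refsource`` (a :class:`~splicewarp.reference.ReferenceSource`).
    """
    jwrs = extract_jwrs(record, flank=flank)
    if not jwrs:
        return []
    read_seq = record.query_sequence or ""
    if record.has_tag("MD"):
        ref_bases = {
            r: (b or "N").upper()
            for _, r, b in record.get_aligned_pairs(with_seq=True)
            if r is not None
        }

        def ref_at(g: int) -> str:
            return ref_bases.get(g, "N")

    elif refsource is not None:
        chrom = record.reference_name
        start, end = record.reference_start, record.reference_end
        seq = refsource.fetch(chrom, start, end)

        def ref_at(g: int, _s=seq, _o=start) -> str:
            return _s[g - _o]

    else:
        raise ValueError(
            "record lacks an MD tag; supply a reference FASTA to compute JAQ"
        )
    return [j.with_jaq(compute_jaq(j, read_seq, ref_at, flank=flank)) for j in jwrs]
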