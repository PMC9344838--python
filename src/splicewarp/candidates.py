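"""Candidate splice junctions and junction motifs for a JWR.

For each JWR the mapped junction is kept and nearby alternatives are
enumerated: by default every pairing of a canonical donor (intron starting
GT) and acceptor (intron ending AG) found within ``window`` nt of the
mapped splice sites, optionally extended with GC-AG / AT-AC pairings,
annotated junctions and user-supplied lists.  Each candidate's *junction
motif* is the spliced exonic sequence around it, extended on both sides to
genomic endpoints common to all candidates so that every motif begins and
ends with the same sequence — differences between candidate squiggles are
then due solely to the junction choice.  A few extra ``buffer`` bases are
appended at each end for the aligner's open starts/ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .jwr import JWR, SpliceJunction
from .pore_model import CandidateSquiggle, PoreModel, predict_candidate_squiggle
from .reference import ReferenceSource, revcomp

__all__ = [
    "CandidateOptions",
    "CandidateSet",
    "enumerate_candidates",
    "build_junction_motifs",
    "read_annotation_junctions",
    "read_junction_bed",
]

logger = logging.getLogger(__name__)

# intron-boundary dinucleotides on the forward genome strand, per transcript
# strand: (first two intron bases, last two intron bases, provenance tag)
_CANONICAL = {"+": ("GT", "AG"), "-": ("CT", "AC")}
_NONCANONICAL = {
    "+": [("GC", "AG", "GC_AG"), ("AT", "AC", "AT_AC")],
    "-": [("CT", "GC", "GC_AG"), ("GT", "AT", "AT_AC")],
}

_SOURCE_PRIORITY = ("mapped", "canonical_scan", "annotation", "user", "GC_AG", "AT_AC")


@dataclass(frozen=True)
class CandidateOptions:
    """Knobs for candidate enumeration (all sources beyond the default scan)."""

    window: int = 10
    noncanonical: bool = False
    annotation: tuple[SpliceJunction, ...] | None = None
    user_junctions: tuple[SpliceJunction, ...] | None = None
    annotation_only: bool = False
    max_candidates: int = 32


@dataclass(frozen=True)
class CandidateSet:
    """Candidate junctions for one JWR with common-flank motifs and priors."""

    junctions: tuple[SpliceJunction, ...]
    motifs: tuple[str, ...]
    sources: tuple[str, ...]
    prior_weights: np.ndarray
    buffer_head: int
    buffer_tail: int
    common_start: int
    common_end: int
    jwr: JWR | None = None

    def __post_init__(self) -> None:
        m = len(self.junctions)
        if m < 1:
            raise ValueError("candidate set must contain at least one junction")
        if not (len(self.motifs) == len(self.sources) == m):
            raise ValueError("junctions, motifs and sources must align")
        w = np.asarray(self.prior_weights, dtype=float)
        object.__setattr__(self, "prior_weights", w)
        if w.shape != (m,) or np.any(w <= 0):
            raise ValueError("prior weights must be positive, one per candidate")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("prior weights must sum to 1")

    @property
    def M(self) -> int:
        return len(self.junctions)

    def squiggles(self, model: PoreModel) -> list[CandidateSquiggle]:
        return [
            predict_candidate_squiggle(
                motif, model, buffer_head=self.buffer_head, buffer_tail=self.buffer_tail
            )
            for motif in self.motifs
        ]


def _near(j: SpliceJunction, mapped: SpliceJunction, window: int) -> bool:
    return (
        abs(j.donor_end - mapped.donor_end) <= window
        and abs(j.acceptor_end - mapped.acceptor_end) <= window
    )


def enumerate_candidates(
    jwr: JWR | SpliceJunction,
    ref: ReferenceSource,
    window: int = 10,
    options: CandidateOptions | None = None,
) -> tuple[list[SpliceJunction], list[str]]:
    """List candidate junctions for a JWR, mapped junction first.

    Scans ``window`` nt around each mapped splice site for donor/acceptor
    dinucleotides and cross-pairs them into valid introns (length >= 4,
    donor upstream of acceptor).  Returns parallel lists of junctions and
    provenance tags; the mapped junction is always first and retained even
    when non-canonical.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    opts = options or CandidateOptions(window=window)
    mapped = jwr.junction if isinstance(jwr, JWR) else jwr
    chrom, strand = mapped.chrom, mapped.strand

    found: dict[tuple[int, int], str] = {(mapped.donor_end, mapped.acceptor_end): "mapped"}

    def add(donor: int, acceptor: int, source: str) -> None:
        key = (donor, acceptor)
        if acceptor - donor < 4:
            return
        if key not in found:
            found[key] = source

    if not opts.annotation_only:
        pairs = [(*_CANONICAL[strand], "canonical_scan")]
        if opts.noncanonical:
            pairs += _NONCANONICAL[strand]
        lo = mapped.donor_end - window
        hi = mapped.acceptor_end + window
        seq = ref.fetch(chrom, lo - 2, hi + 2)

        def dinuc(pos: int) -> str:
            return seq[pos - (lo - 2) : pos - (lo - 2) + 2]

        for first2, last2, tag in pairs:
            donors = [
                d
                for d in range(mapped.donor_end - window, mapped.donor_end + window + 1)
                if dinuc(d) == first2
            ]
            acceptors = [
                a
                for a in range(
                    mapped.acceptor_end - window, mapped.acceptor_end + window + 1
                )
                if dinuc(a - 2) == last2
            ]
            for d in donors:
                for a in acceptors:
                    add(d, a, tag)

    for group, tag in ((opts.annotation, "annotation"), (opts.user_junctions, "user")):
        if group:
            for j in group:
                if j.chrom == chrom and j.strand == strand and _near(j, mapped, window):
                    add(j.donor_end, j.acceptor_end, tag)

    items = sorted(
        found.items(),
        key=lambda kv: (
            kv[1] != "mapped",
            abs(kv[0][0] - mapped.donor_end) + abs(kv[0][1] - mapped.acceptor_end),
            kv[0],
        ),
    )
    if len(items) > opts.max_candidates:
        logger.warning(
            "candidate set capped at %d (had %d) near %s:%d-%d",
            opts.max_candidates,
            len(items),
            chrom,
            mapped.donor_end,
            mapped.acceptor_end,
        )
        items = items[: opts.max_candidates]

    junctions = [
        SpliceJunction(chrom, d, a, strand) for (d, a), _ in items
    ]
    sources = [src for _, src in items]
    return junctions, sources


def build_junction_motifs(
    junctions: Sequence[SpliceJunction],
    ref: ReferenceSource,
    flank: int = 16,
    buffer: int = 10,
    sources: Sequence[str] | None = None,
    prior_weights: Sequence[float] | None = None,
    source_weights: dict[str, float] | None = None,
    jwr: JWR | None = None,
) -> CandidateSet:
    """Assemble common-flank junction motifs for a list of candidates.

    The common genomic start is ``min(donor) - flank`` and the common end
    ``max(acceptor) + flank``; each motif splices its own intron out of
    that interval, with ``buffer`` additional genomic bases at each end
    recorded for the aligner's open ends.  Minus-strand motifs are
    reverse-complemented so that all motifs run in read orientation.

    The defaults are matched to the squiggle-extraction geometry: with a
    junction squiggle spanning ``sf`` read bases per side and candidates
    scanned within ``window`` of the mapped sites, ``flank = sf - window``
    and ``buffer >= window`` guarantee that the true candidate's core
    states are covered by the squiggle while the overhang stays within the
    skippable buffer, whichever shift the true junction has.
    """
    if not junctions:
        raise ValueError("need at least one junction")
    chrom = junctions[0].chrom
    strand = junctions[0].strand
    if any(j.chrom != chrom or j.strand != strand for j in junctions):
        raise ValueError("all candidate junctions must share chrom and strand")
    if flank < 1:
        raise ValueError("flank must be positive")
    common_start = min(j.donor_end for j in junctions) - flank
    common_end = max(j.acceptor_end for j in junctions) + flank
    if common_start >= min(j.donor_end for j in junctions) or common_end <= max(
        j.acceptor_end for j in junctions
    ):
        raise ValueError("flank too small to reach past the widest candidate")

    motifs = []
    for j in junctions:
        up = ref.fetch(chrom, common_start - buffer, j.donor_end)
        down = ref.fetch(chrom, j.acceptor_end, common_end + buffer)
        motif = up + down
        motifs.append(revcomp(motif) if strand == "-" else motif)

    m = len(junctions)
    srcs = tuple(sources) if sources is not None else ("mapped",) + ("candidate",) * (m - 1)
    if prior_weights is not None:
        w = np.asarray(prior_weights, dtype=float)
    else:
        w = np.ones(m)
        if source_weights:
            w = np.array([source_weights.get(s, 1.0) for s in srcs], dtype=float)
    if np.any(w <= 0):
        raise ValueError("prior weights must be positive")
    w = w / w.sum()

    return CandidateSet(
        junctions=tuple(junctions),
        motifs=tuple(motifs),
        sources=srcs,
        prior_weights=w,
        buffer_head=buffer,
        buffer_tail=buffer,
        common_start=common_start,
        common_end=common_end,
        jwr=jwr,
    )


def read_annotation_junctions(gtf_path) -> list[SpliceJunction]:
    """Extract the deduplicated set of introns implied by GTF exon lines."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    by_tx: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [exon.id])[0]
        by_tx.setdefault(tid, []).append(exon)
    seen: set[SpliceJunction] = set()
    for exons in by_tx.values():
        exons.sort(key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start - 1 <= a.end:
                continue  # abutting/overlapping exon records carry no intron
            seen.add(
                SpliceJunction(
                    chrom=a.seqid,
                    donor_end=a.end,  # GFF is 1-based inclusive
                    acceptor_end=b.start - 1,
                    strand=a.strand if a.strand in "+-" else "+",
                )
            )
    return sorted(seen)


def read_junction_bed(path, score_as_weight: bool = False):
    """Read a BED6 of introns; optionally return the score column as weights."""
    import pandas as pd

    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    junctions = [
        SpliceJunction(str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in frame.itertuples()
    ]
    if score_as_weight:
        return junctions, frame["score"].astype(float).tolist()
    return junctions
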