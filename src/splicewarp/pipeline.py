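"""End-to-end run orchestration: BAM/SAM in, per-JWR junction calls out.

For every spliced alignment record the pipeline locates JWRs, computes
JAQ, enumerates candidate junctions, builds common-flank motifs and
candidate squiggles, extracts and aligns the junction squiggle, and emits
one TSV row per JWR with its category: called, skipped by the JAQ
prefilter, unusable, failed a filter, or errored.  Every input JWR appears
in exactly one category; per-JWR failures never abort a run.  Output rows
are written in input order, so identical inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .candidates import (
    CandidateOptions,
    build_junction_motifs,
    enumerate_candidates,
    read_annotation_junctions,
    read_junction_bed,
)
from .inference import (
    DEFAULT_PROB_THRESHOLD,
    DEFAULT_SIQ_THRESHOLD,
    JunctionCall,
    apply_thresholds,
    auto_siq_threshold,
    call_junction,
)
from .jwr import JWR, compute_jaq, extract_jwrs
from .pore_model import PoreModel, load_pore_model, synthetic_pore_model
from .reference import ReferenceSource
from .squiggle import extract_junction_squiggle, load_event_tables, load_signals, normalize_signal

__all__ = ["RunConfig", "RunSummary", "run_identify", "run_jaq"]

logger = logging.getLogger(__name__)

_TSV_HEADER = (
    "read_id\tchrom\tmapped_donor\tmapped_acceptor\tstrand\tJAQ\tM\tSIQ\t"
    "best_donor\tbest_acceptor\tbest_prob\tcandidates\tstatus\treason\n"
)


@dataclass(frozen=True)
class RunConfig:
    """All inputs and knobs for one identification run."""

    alignments: str | Path
    fasta: str | Path
    events: str | Path
    signals: str | Path
    pore_model: str | Path | PoreModel | None = None
    out_tsv: str | Path | None = None
    out_bed: str | Path | None = None
    out_log: str | Path | None = None
    region: str | None = None
    window: int = 10
    flank: int = 16
    buffer: int = 10
    squiggle_flank: int = 26
    tail_sd: float = 3.0
    siq_threshold: float = DEFAULT_SIQ_THRESHOLD
    prob_threshold: float = DEFAULT_PROB_THRESHOLD
    siq_auto: bool = False
    jaq_max: float = 0.95
    jaq_flank: int = 25
    min_seg_len: int = 1
    noncanonical: bool = False
    annotation: str | Path | None = None
    candidates_bed: str | Path | None = None
    annotation_only: bool = False
    max_candidates: int = 32
    source_weights: dict[str, float] | None = None

    def resolve_model(self) -> PoreModel:
        if isinstance(self.pore_model, PoreModel):
            return self.pore_model
        if self.pore_model is None:
            return synthetic_pore_model()
        return load_pore_model(self.pore_model)


@dataclass
class RunSummary:
    """Bookkeeping over one run; categories partition the input JWRs."""

    total: int = 0
    called: int = 0
    skipped_jaq: int = 0
    unusable: int = 0
    failed_siq: int = 0
    failed_prob: int = 0
    unalignable: int = 0
    no_segments: int = 0
    errors: int = 0
    siq_threshold_used: float = DEFAULT_SIQ_THRESHOLD

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def check(self) -> None:
        parts = (
            self.called
            + self.skipped_jaq
            + self.unusable
            + self.failed_siq
            + self.failed_prob
            + self.unalignable
            + self.no_segments
            + self.errors
        )
        if parts != self.total:
            raise AssertionError("run categories do not partition the JWRs")


def _parse_region(region: str | None):
    if region is None:
        return None
    chrom, _, rest = region.partition(":")
    if not rest:
        return chrom, None, None
    start, _, end = rest.partition("-")
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def _fmt(v: float | None, digits: int = 6) -> str:
    if v is None:
        return "NA"
    return f"{v:.{digits}g}"


def _iter_records(path, region):
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as fh:
        parsed = _parse_region(region)
        if parsed is None:
            yield from fh.fetch(until_eof=True)
        elif fh.has_index():
            chrom, start, end = parsed
            yield from fh.fetch(chrom, start, end)
        else:
            chrom, start, end = parsed
            for rec in fh.fetch(until_eof=True):
                if rec.is_unmapped or rec.reference_name != chrom:
                    continue
                if start is not None and (
                    rec.reference_end <= start or rec.reference_start >= end
                ):
                    continue
                yield rec


def run_jaq(config: RunConfig) -> list[JWR]:
    """JAQ-only mode: locate every JWR and attach its alignment quality."""
    ref = ReferenceSource.from_fasta(config.fasta)
    out: list[JWR] = []
    for rec in _iter_records(config.alignments, config.region):
        jwrs = extract_jwrs(rec, flank=config.jaq_flank)
        if not jwrs:
            continue
        read_seq = rec.query_sequence or ""
        chrom = rec.reference_name
        span = ref.fetch(chrom, rec.reference_start, rec.reference_end)
        for j in jwrs:
            jaq = compute_jaq(
                j, read_seq, span, ref_offset=rec.reference_start, flank=config.jaq_flank
            )
            out.append(j.with_jaq(jaq))
    return out


def run_identify(config: RunConfig):
    """Run the full identification pipeline; returns (rows, summary).

    Each row is a dict mirroring the output TSV.  When ``config.siq_auto``
    is set the SIQ threshold is chosen from the pooled empirical SIQ
    distribution (first pass computes, second applies); thresholds never
    change the probabilities, only the pass/fail status.
    """
    model = config.resolve_model()
    ref = ReferenceSource.from_fasta(config.fasta)
    events = load_event_tables(config.events)
    raw_signals = load_signals(config.signals)
    normalized: dict[str, np.ndarray] = {}

    annotation = (
        tuple(read_annotation_junctions(config.annotation))
        if config.annotation
        else None
    )
    user = (
        tuple(read_junction_bed(config.candidates_bed))
        if config.candidates_bed
        else None
    )
    options = CandidateOptions(
        window=config.window,
        noncanonical=config.noncanonical,
        annotation=annotation,
        user_junctions=user,
        annotation_only=config.annotation_only,
        max_candidates=config.max_candidates,
    )

    summary = RunSummary()
    pending: list[tuple[dict, JunctionCall | None]] = []
    for rec in _iter_records(config.alignments, config.region):
        # read_span (squiggle extraction window) uses squiggle_flank; the JAQ
        # window is set independently below via jaq_flank
        jwrs = extract_jwrs(rec, flank=config.squiggle_flank)
        if not jwrs:
            continue
        read_seq = rec.query_sequence or ""
        chrom = rec.reference_name
        span = ref.fetch(chrom, rec.reference_start, rec.reference_end)
        for j in jwrs:
            summary.total += 1
            row = {
                "read_id": j.read_id,
                "chrom": chrom,
                "mapped_donor": j.junction.donor_end,
                "mapped_acceptor": j.junction.acceptor_end,
                "strand": j.junction.strand,
                "JAQ": None,
                "M": 0,
                "SIQ": None,
                "best_donor": None,
                "best_acceptor": None,
                "best_prob": None,
                "candidates": "",
                "status": "",
                "reason": "",
            }
            try:
                jaq = compute_jaq(
                    j,
                    read_seq,
                    span,
                    ref_offset=rec.reference_start,
                    flank=config.jaq_flank,
                )
                row["JAQ"] = jaq
                if not j.usable:
                    summary.unusable += 1
                    row["status"] = "unusable"
                    pending.append((row, None))
                    continue
                if jaq > config.jaq_max:
                    summary.skipped_jaq += 1
                    row["status"] = "skipped_jaq"
                    pending.append((row, None))
                    continue
                junctions, sources = enumerate_candidates(
                    j, ref, window=config.window, options=options
                )
                cands = build_junction_motifs(
                    junctions,
                    ref,
                    flank=config.flank,
                    buffer=config.buffer,
                    sources=sources,
                    source_weights=config.source_weights,
                    jwr=j,
                )
                row["M"] = cands.M
                if j.read_id not in normalized:
                    normalized[j.read_id] = normalize_signal(raw_signals[j.read_id])
                x = extract_junction_squiggle(
                    j, events[j.read_id], normalized[j.read_id]
                )
                call = call_junction(
                    cands,
                    x,
                    model,
                    tail_sd=config.tail_sd,
                    siq_threshold=config.siq_threshold,
                    prob_threshold=config.prob_threshold,
                    min_seg_len=config.min_seg_len,
                )
                pending.append((row, call))
            except Exception as exc:  # per-JWR failures never abort the batch
                logger.warning("JWR %s %s:%d failed: %s", j.read_id, chrom, j.junction.donor_end, exc)
                summary.errors += 1
                row["status"] = "error"
                row["reason"] = str(exc)[:120]
                pending.append((row, None))

    siq_threshold = config.siq_threshold
    if config.siq_auto:
        pooled = [c.siq for _, c in pending if c is not None]
        siq_threshold = auto_siq_threshold(pooled, floor=config.siq_threshold)
        logger.info("auto SIQ threshold: %.4f", siq_threshold)
    summary.siq_threshold_used = siq_threshold

    rows = []
    for row, call in pending:
        if call is not None:
            call = apply_thresholds(
                call, siq_threshold=siq_threshold, prob_threshold=config.prob_threshold
            )
            row["SIQ"] = call.siq if np.isfinite(call.siq) else None
            row["candidates"] = ";".join(
                f"{j.donor_end}:{j.acceptor_end}:{_fmt(float(p), 4)}"
                for j, p in zip(call.cands.junctions, call.probs)
            )
            if call.passed_filters:
                summary.called += 1
                best = call.best_junction
                row["status"] = "called"
                row["best_donor"] = best.donor_end
                row["best_acceptor"] = best.acceptor_end
                row["best_prob"] = float(call.probs[call.best])
            else:
                row["status"] = "filtered"
                row["reason"] = call.reason or ""
                row["best_prob"] = float(call.probs.max()) if call.probs.size else None
                if call.reason == "failed_siq":
                    summary.failed_siq += 1
                elif call.reason == "failed_prob":
                    summary.failed_prob += 1
                elif call.reason == "no_segments":
                    summary.no_segments += 1
                else:
                    summary.unalignable += 1
        rows.append(row)
    summary.check()

    if config.out_tsv:
        _write_rows(rows, config.out_tsv)
    if config.out_bed:
        _write_bed(rows, config.out_bed)
    if config.out_log:
        _write_log(config, summary, config.out_log)
    return rows, summary


def _write_rows(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r["read_id"],
                        r["chrom"],
                        str(r["mapped_donor"]),
                        str(r["mapped_acceptor"]),
                        r["strand"],
                        _fmt(r["JAQ"], 4),
                        str(r["M"]),
                        _fmt(r["SIQ"], 6),
                        "NA" if r["best_donor"] is None else str(r["best_donor"]),
                        "NA" if r["best_acceptor"] is None else str(r["best_acceptor"]),
                        _fmt(r["best_prob"], 4),
                        r["candidates"],
                        r["status"],
                        r["reason"],
                    ]
                )
                + "\n"
            )


def _write_bed(rows, path) -> None:
    """Corrected junctions (called JWRs only) as BED6 intron intervals."""
    with open(path, "w") as fh:
        for r in rows:
            if r["status"] == "called":
                fh.write(
                    f"{r['chrom']}\t{r['best_donor']}\t{r['best_acceptor']}\t"
                    f"{r['read_id']}\t{_fmt(r['best_prob'], 4)}\t{r['strand']}\n"
                )


def _write_log(config: RunConfig, summary: RunSummary, path) -> None:
    cfg = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, PoreModel):
            v = f"<PoreModel k={v.k}>"
        elif isinstance(v, Path):
            v = str(v)
        cfg[f.name] = v
    with open(path, "w") as fh:
        json.dump({"config": cfg, "summary": summary.as_dict()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
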