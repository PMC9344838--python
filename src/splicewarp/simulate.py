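"""Synthetic squiggles, genomes and JWR datasets with known ground truth.

The generator inverts the pore model: for each motif state it draws a
dwell (shifted-geometric number of samples, minimum 1) and emits Gaussian
current around the state mean, optionally corrupted by +/-10 sigma spikes.
Dataset simulation writes a small genome with planted splice junctions and
decoy GT/AG dinucleotides at controlled offsets of the true sites, spliced
reads aligned either to the true junction or (with probability
1 - p_correct) to a planted decoy — emulating inconsistently mapped
junctions — plus a fraction of *off-target* reads whose signal comes from
an unrelated motif, exercising the SIQ filter.  Raw signals are written on
a picoampere-like scale (per-read affine transform of the normalized
signal) so the pipeline's median/MAD normalization is exercised end to end.

Everything is deterministic under the config seed: identical configs give
byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .jwr import SpliceJunction
from .pore_model import PoreModel, predict_candidate_squiggle
from .squiggle import EventTable, write_event_tables, write_signals

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_squiggle",
    "make_synthetic_genome",
    "simulate_jwr_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    dwell_mean is the expected number of samples per state (the parameter
    of the shifted geometric dwell distribution); noise_scale multiplies
    the pore-model sd; spike_rate is the per-sample probability of a
    +/-10 sigma spike; offtarget_rate the fraction of JWRs whose signal is
    drawn from an unrelated motif; p_correct the probability that the
    mapped junction equals the truth (otherwise a planted decoy).
    """

    seed: int = 0
    dwell_mean: float = 8.0
    noise_scale: float = 1.0
    spike_rate: float = 0.0
    offtarget_rate: float = 0.0
    p_correct: float = 0.92

    def __post_init__(self) -> None:
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        for name in ("spike_rate", "offtarget_rate", "p_correct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_squiggle(
    motif: str,
    model: PoreModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, EventTable]:
    """Draw a squiggle for ``motif`` and the ground-truth event table.

    State i emits ``d_i ~ shifted-Geometric(1/dwell_mean)`` samples from
    Normal(mu_i, noise_scale * sigma_i); spiked samples are replaced by
    mu_i +/- 10 sigma_i.  The event table records, per motif base that owns
    a state, the half-open sample range emitted for it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cand = predict_candidate_squiggle(motif, model)
    pieces = []
    starts, ends = [], []
    pos = 0
    for mu, sigma in zip(cand.means, cand.sds):
        d = int(rng.geometric(1.0 / cfg.dwell_mean)) if cfg.dwell_mean > 1 else 1
        samples = rng.normal(mu, cfg.noise_scale * sigma, size=d)
        if cfg.spike_rate > 0:
            spiked = rng.random(d) < cfg.spike_rate
            if spiked.any():
                signs = rng.choice([-1.0, 1.0], size=int(spiked.sum()))
                samples[spiked] = mu + signs * 10.0 * sigma
        pieces.append(samples)
        starts.append(pos)
        ends.append(pos + d)
        pos += d
    events = EventTable(
        read_id="",
        base_index=np.arange(cand.n_states),
        start=np.array(starts),
        end=np.array(ends),
    )
    return np.concatenate(pieces), events


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _plant(seq: list[str], pos: int, dinuc: str) -> None:
    seq[pos] = dinuc[0]
    seq[pos + 1] = dinuc[1]


def make_synthetic_genome(
    rng: np.random.Generator,
    n_loci: int = 4,
    exon_flank: int = 1000,
    intron_len: int = 200,
    decoy_offsets: tuple[int, ...] = (-7, -5, -3, 3, 5, 7),
    n_decoys_per_site: int = 2,
    chrom: str = "chrS",
) -> tuple[dict[str, str], list[SpliceJunction], dict[SpliceJunction, list[SpliceJunction]]]:
    """Random genome with planted canonical junctions and nearby decoys.

    Each locus carries one true GT..AG intron plus ``n_decoys_per_site``
    extra GT (donor side) and AG (acceptor side) dinucleotides at offsets
    drawn from ``decoy_offsets``, creating realistic multi-candidate sets.
    Returns the genome, the true junctions, and per-junction decoy
    junctions a misaligned read could plausibly be mapped to.
    """
    spacing = 2 * exon_flank + intron_len + 200
    total = 200 + n_loci * spacing
    seq = list(_random_seq(rng, total))
    junctions: list[SpliceJunction] = []
    decoys: dict[SpliceJunction, list[SpliceJunction]] = {}
    for i in range(n_loci):
        donor = 100 + exon_flank + i * spacing
        acceptor = donor + intron_len
        _plant(seq, donor, "GT")
        _plant(seq, acceptor - 2, "AG")
        true_j = SpliceJunction(chrom, donor, acceptor, "+")
        junctions.append(true_j)
        alts: list[SpliceJunction] = []
        donor_offs = rng.choice(decoy_offsets, size=n_decoys_per_site, replace=False)
        acc_offs = rng.choice(decoy_offsets, size=n_decoys_per_site, replace=False)
        for off in donor_offs:
            _plant(seq, donor + int(off), "GT")
            alts.append(SpliceJunction(chrom, donor + int(off), acceptor, "+"))
        for off in acc_offs:
            _plant(seq, acceptor + int(off) - 2, "AG")
            alts.append(SpliceJunction(chrom, donor, acceptor + int(off), "+"))
        # re-assert the true motif in case a decoy overlapped it
        _plant(seq, donor, "GT")
        _plant(seq, acceptor - 2, "AG")
        decoys[true_j] = [a for a in alts if (a.donor_end, a.acceptor_end) != (donor, acceptor)]
    return {chrom: "".join(seq)}, junctions, decoys


@dataclass(frozen=True)
class SimulatedDataset:
    """Paths of the fixture files written by :func:`simulate_jwr_dataset`."""

    genome_fasta: Path
    truth_bed: Path
    jwr_tsv: Path
    event_tsv: Path
    signal_tsv: Path
    sam: Path
    config_json: Path
    genome: dict[str, str]
    true_junctions: list[SpliceJunction]


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def simulate_jwr_dataset(
    outdir,
    model: PoreModel,
    cfg: SimulationConfig,
    n: int = 100,
    n_loci: int = 4,
    exon_flank: int = 1000,
    intron_len: int = 200,
    reference: dict[str, str] | None = None,
    true_junctions: list[SpliceJunction] | None = None,
) -> SimulatedDataset:
    """Write a complete ground-truthed fixture set for ``n`` JWRs.

    Files: genome FASTA, truth BED, JWR truth TSV, event TSV, raw signal
    TSV, spliced SAM, and a config JSON echoing all parameters.  Reads are
    the spliced exonic sequence (``exon_flank`` bases each side of the
    junction); long flanks keep per-read median/MAD statistics close to the
    model scale, as read-level normalization assumes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    if reference is None:
        reference, true_junctions, decoys = make_synthetic_genome(
            rng, n_loci=n_loci, exon_flank=exon_flank, intron_len=intron_len
        )
    else:
        if not true_junctions:
            raise ValueError("true_junctions required with an explicit reference")
        decoys = {j: [] for j in true_junctions}
    for j in true_junctions:
        chrom_len = len(reference[j.chrom])
        if j.donor_end - exon_flank < 0 or j.acceptor_end + exon_flank > chrom_len:
            raise ValueError(f"junction {j} outside reference (length {chrom_len})")

    chrom = true_junctions[0].chrom if true_junctions else "chrS"
    seq = reference[chrom]

    jwr_rows = []
    event_tables = {}
    signals = {}
    sam_records = []
    for i in range(n):
        read_id = f"read{i:05d}"
        true_j = true_junctions[i % len(true_junctions)]
        motif = (
            seq[true_j.donor_end - exon_flank : true_j.donor_end]
            + seq[true_j.acceptor_end : true_j.acceptor_end + exon_flank]
        )
        offtarget = bool(rng.random() < cfg.offtarget_rate)
        signal_motif = _random_seq(rng, len(motif)) if offtarget else motif
        sig, events = simulate_squiggle(signal_motif, model, cfg, rng)
        # write on a pA-like scale; the pipeline re-normalizes per read
        scale = rng.uniform(8.0, 12.0)
        shift = rng.uniform(80.0, 120.0)
        signals[read_id] = shift + scale * sig
        event_tables[read_id] = dataclasses.replace(events, read_id=read_id)

        alts = decoys.get(true_j, [])
        if alts and rng.random() >= cfg.p_correct:
            mapped = alts[int(rng.integers(len(alts)))]
        else:
            mapped = true_j
        jwr_rows.append(
            (
                read_id,
                chrom,
                mapped.donor_end,
                mapped.acceptor_end,
                true_j.donor_end,
                true_j.acceptor_end,
                int(offtarget),
                "+",
            )
        )
        cigar = (
            f"{exon_flank}M{mapped.acceptor_end - mapped.donor_end}N{exon_flank}M"
        )
        sam_records.append(
            (read_id, mapped.donor_end - exon_flank, cigar, motif)
        )

    genome_fasta = outdir / "genome.fa"
    truth_bed = outdir / "truth.bed"
    jwr_tsv = outdir / "jwrs.tsv"
    event_tsv = outdir / "events.tsv"
    signal_tsv = outdir / "signals.tsv"
    sam_path = outdir / "reads.sam"
    config_json = outdir / "config.json"

    _write_fasta(reference, genome_fasta)
    with open(truth_bed, "w") as fh:
        for j in true_junctions:
            fh.write(
                f"{j.chrom}\t{j.donor_end}\t{j.acceptor_end}\tintron\t0\t{j.strand}\n"
            )
    with open(jwr_tsv, "w") as fh:
        fh.write(
            "read_id\tchrom\tmapped_donor\tmapped_acceptor\t"
            "true_donor\ttrue_acceptor\tofftarget\tstrand\n"
        )
        for row in jwr_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    write_event_tables(event_tables, event_tsv)
    write_signals(signals, signal_tsv)

    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(s)} for name, s in reference.items()],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for read_id, pos, cigar, read_seq in sam_records:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read_id
            rec.query_sequence = read_seq
            rec.flag = 0
            rec.reference_id = list(reference).index(chrom)
            rec.reference_start = pos
            rec.mapping_quality = 60
            rec.cigarstring = cigar
            rec.set_tag("XS", "+")
            out.write(rec)

    with open(config_json, "w") as fh:
        json.dump(
            {
                **dataclasses.asdict(cfg),
                "n": n,
                "n_loci": n_loci,
                "exon_flank": exon_flank,
                "intron_len": intron_len,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return SimulatedDataset(
        genome_fasta=genome_fasta,
        truth_bed=truth_bed,
        jwr_tsv=jwr_tsv,
        event_tsv=event_tsv,
        signal_tsv=signal_tsv,
        sam=sam_path,
        config_json=config_json,
        genome=reference,
        true_junctions=list(true_junctions),
    )
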