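import numpy as np
import pysam
import pytest

import splicewarp as sw


@pytest.fixture(scope="session")
def model6():
    """Bundled synthetic 6-mer pore model (deterministic)."""
    return sw.synthetic_pore_model()


@pytest.fixture()
def toy_model2():
    """Complete 2-mer model: means 0..15 in fixed k-mer order, sd 1."""
    import itertools

    table = {
        "".join(kmer): (float(i), 1.0)
        for i, kmer in enumerate(itertools.product("ACGT", repeat=2))
    }
    return sw.PoreModel(k=2, table=table)


def make_record(
    cigar: str,
    pos: int = 1000,
    chrom: str = "chr1",
    read_id: str = "read1",
    seq: str | None = None,
    chrom_len: int = 100000,
    reverse: bool = False,
):
    """In-memory pysam record for CIGAR-walking tests."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = read_id
    rec.reference_id = 0
    rec.reference_start = pos
    rec.cigarstring = cigar
    rec.flag = 16 if reverse else 0
    rec.mapping_quality = 60
    if seq is None:
        qlen = sum(l for op, l in rec.cigartuples if op in (0, 1, 4, 7, 8))
        seq = "A" * qlen
    rec.query_sequence = seq
    return rec


@pytest.fixture(scope="session")
def two_candidate_locus(model6):
    """A locus with one GT donor and two AG acceptors 5 nt apart (plus decoy-free
    background), the classic near-miss situation, with a builder for simulated
    junction squiggles from the true junction."""
    rng = np.random.default_rng(2024)
    L = 400
    donor, acceptor, offset = 150, 250, 5
    while True:
        seq = list("".join(rng.choice(list("ACGT"), L)))
        seq[donor : donor + 2] = "GT"
        seq[acceptor - 2 : acceptor] = "AG"
        seq[acceptor - 2 + offset : acceptor + offset] = "AG"
        s = "".join(seq)
        # require no other donor/acceptor motifs within the scan window
        n_gt = sum(
            1 for p in range(donor - 10, donor + 11) if s[p : p + 2] == "GT"
        )
        n_ag = sum(
            1
            for p in range(acceptor - 10, acceptor + 11)
            if s[p - 2 : p] == "AG"
        ) + sum(
            1
            for p in range(acceptor + offset - 10, acceptor + offset + 11)
            if s[p - 2 : p] == "AG"
        )
        if n_gt == 1:
            break
    ref = sw.ReferenceSource.from_dict({"c": s})
    j_true = sw.SpliceJunction("c", donor, acceptor, "+")
    j_alt = sw.SpliceJunction("c", donor, acceptor + offset, "+")
    region = s[donor - 26 : donor] + s[acceptor : acceptor + 26]

    def simulate_x(rng, noise_scale=1.0, dwell_mean=8.0, spike_rate=0.0):
        cfg = sw.SimulationConfig(
            seed=0,
            dwell_mean=dwell_mean,
            noise_scale=noise_scale,
            spike_rate=spike_rate,
        )
        sig, _ = sw.simulate_squiggle(region, model6, cfg, rng)
        return sw.JunctionSquiggle(sig)

    return {
        "seq": s,
        "ref": ref,
        "true": j_true,
        "alt": j_alt,
        "simulate_x": simulate_x,
    }


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory, model6):
    """Small end-to-end dataset: 30 JWRs, 10% off-target, 10% mismapped."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = sw.SimulationConfig(
        seed=7, p_correct=0.9, offtarget_rate=0.1, noise_scale=0.5
    )
    return sw.simulate_jwr_dataset(outdir, model6, cfg, n=30)
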