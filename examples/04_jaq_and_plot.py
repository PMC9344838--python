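"""Compute junction alignment qualities (JAQ) for a simulated run and
render the squiggle-vs-candidate diagnostic figure for one JWR.

JAQ is the fraction of matched bases within 25 read bases of the mapped
splice sites: reads mapped to the wrong junction accumulate mismatches
there, so a low JAQ marks the JWRs most likely to need squiggle-based
correction.  The figure overlays the junction squiggle on the candidate's
mean +/- 1 sd band at its aligned states.
"""

import tempfile
from pathlib import Path

import splicewarp as sw
from splicewarp.pipeline import _iter_records

model = sw.synthetic_pore_model()
cfg = sw.SimulationConfig(seed=5, p_correct=0.8, noise_scale=0.5)

with tempfile.TemporaryDirectory() as tmp:
    ds = sw.simulate_jwr_dataset(tmp, model, cfg, n=10)
    jwrs = sw.run_jaq(
        sw.RunConfig(
            alignments=ds.sam, fasta=ds.genome_fasta, events="", signals=""
        )
    )
    print("read_id      junction           JAQ")
    for j in jwrs:
        print(
            f"{j.read_id}  [{j.junction.donor_end}, {j.junction.acceptor_end})"
            f"   {j.jaq:.3f}"
        )
    print("(JAQ < 1 marks reads mapped to a decoy junction)")

    # plot the first JWR against its mapped candidate
    ref = sw.ReferenceSource.from_fasta(ds.genome_fasta)
    events = sw.load_event_tables(ds.event_tsv)
    signals = sw.load_signals(ds.signal_tsv)
    rec = next(_iter_records(ds.sam, None))
    (jwr,) = sw.extract_jwrs(rec, flank=26)
    junctions, sources = sw.enumerate_candidates(jwr, ref)
    cands = sw.build_junction_motifs(junctions, ref, sources=sources)
    x = sw.extract_junction_squiggle(
        jwr, events[jwr.read_id], sw.normalize_signal(signals[jwr.read_id])
    )
    squig = cands.squiggles(model)[0]
    res = sw.dtw_align(x, squig)
    out = Path("scratch")
    out.mkdir(exist_ok=True)
    fig = out / "alignment_example.png"
    sw.plot_alignment(x, squig, res, fig, title=f"{jwr.read_id}, mapped candidate")
    frac = sw.band_containment(x, squig, res)
    print(f"\nwrote {fig}; {100 * frac:.0f}% of measurements inside the +/-1 sd band")
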