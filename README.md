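# splicewarp

Splice junction identification for spliced nanopore long reads, directly
from the raw current signal.

## The problem

Oxford Nanopore sequencing reads full-length transcripts, but basecalling
the raw current trace (the *squiggle*) is error prone, and the errors
concentrate exactly where spliced alignment is hardest: within a few bases
of splice sites. A read split-mapped across an intron — a *junction within
read* (JWR) — is therefore often assigned to the wrong donor/acceptor pair,
producing phantom isoforms and hiding real ones. Annotation- or short-read-
based correctors need external data and cannot rescue unannotated or rare
junctions.

`splicewarp` goes back to the signal. For each JWR it asks: *of all the
splice junctions that could exist near the mapped one, whose predicted
squiggle does the observed squiggle actually look like?*

## The method

For a JWR with junction squiggle **x** = (x₁,…,x_K) (median/MAD-normalized
current measurements) and M candidate junctions:

1. **Candidates** — the mapped junction plus every pairing of a GT donor
   and AG acceptor within 10 nt of the mapped splice sites (optionally
   GC-AG/AT-AC, annotated, or user-supplied junctions). Each candidate's
   *junction motif* is its spliced exonic sequence, extended to genomic
   endpoints common to all candidates plus a few buffer bases.
2. **Candidate squiggles** — a k-mer pore model maps each motif to the
   per-position expected current c_m = ((μ₁ₘ,σ₁ₘ),…): the squiggle an
   error-free translocation would produce.
3. **Alignment** — a modified DTW assigns each measurement to exactly one
   state of each candidate, maximizing the summed flat-tailed normal
   log-density, with open ends restricted to the buffer states and every
   core state required to receive at least one measurement.
4. **Segmentation** — runs of measurements with identical alignment
   columns are summarized by their medians y = (y₁,…,y_N).
5. **Mixture model** — with latent z ∈ {1..M} indicating the generating
   candidate:

       P(y | z=m, Θ) = ∏ₙ N*(yₙ; μ_imₘ, σ_imₘ)
       P(z=m | y, Θ) ∝ P(y | z=m, Θ) · P(z=m)

   where N* is a normal density floored at its value 3 sd from the mean
   (flat tails bound the influence of spikes and variant bases). The
   posterior P(z=m | y, Θ) is the *assignment probability*.
6. **Quality filters** — *SIQ* (squiggle information quality): the best
   per-state average alignment log-likelihood across candidates; filters
   squiggles that match no candidate (off-target signal, artifacts).
   *JAQ* (junction alignment quality): fraction of matched bases within
   25 read bases of the mapped splice sites; near-perfect alignments
   (JAQ > 0.95) rarely need correction and can be skipped. A junction is
   reported when SIQ > −0.8 and the strongest assignment probability
   exceeds 0.8.

A fully ground-truthed simulator (pore-model inversion with geometric
dwells, Gaussian noise, current spikes, decoy junctions, mismapped reads
and off-target squiggles) makes every stage testable with no external
data.

## Worked example

`examples/02_simulate_and_call.py` simulates a squiggle from a known
junction and identifies it among two candidates whose acceptors differ by
10 nt:

```
two candidate junctions, acceptors 10 nt apart; truth is candidate 0
junction squiggle: 349 current measurements
  candidate 0 [150, 250): P = 1.0000 <- truth
  candidate 1 [150, 260): P = 0.0000
SIQ = 0.336 (threshold -0.8), segments used: 53
call: junction [150, 250) passes both filters
```

The assignment probability of 1.0000 says the squiggle overwhelmingly
supports the true candidate; SIQ well above −0.8 says the squiggle matches
at least one candidate well, so the call is trustworthy.

`examples/03_full_pipeline.py` runs the whole pipeline (SAM + FASTA +
signal files in, calls out) on a simulated dataset where 8% of reads are
mapped to a decoy junction:

```
initial mapping correct: 38/40
calls correct:           36/36

JWRs whose mapped junction was wrong and got corrected:
  read00016: mapped [1100, 1293) -> called [1100, 1300) P=1.000 JAQ=0.70
  read00022: mapped [5900, 6093) -> called [5900, 6100) P=1.000 JAQ=0.58
```

Both mismapped reads have low JAQ — the signature of basecalling errors
near the junction — and both are corrected to the true junction with full
posterior confidence.

The other examples cover candidate-squiggle prediction (`01`) and
JAQ-only mode plus the diagnostic alignment plot (`04`). The same
functionality is exposed as a CLI:

```bash
splicewarp simulate -o fixtures --n 100 --write-pore-model
splicewarp identify -a fixtures/reads.sam -f fixtures/genome.fa \
    -e fixtures/events.tsv -s fixtures/signals.tsv -o calls.tsv
splicewarp jaq -a fixtures/reads.sam -f fixtures/genome.fa
splicewarp plot -a ... --read-id read00000 -o alignment.png
```

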