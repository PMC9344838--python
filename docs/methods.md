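# Methods

## Model and procedure

A nanopore squiggle is modelled, per candidate junction, as a sequence of
current levels: the pore model assigns every k-mer (k = 6 by default) an
expected mean and standard deviation in normalized-current units, and
sliding it over a candidate's junction motif yields the candidate squiggle
c_m, one (μ, σ) state per motif position (left-anchored: state i belongs to
the k-mer starting at position i; any fixed convention works because all
candidates use the same one).

The junction squiggle x = (x₁,…,x_K) is treated as observations from one of
the M candidate models. Identification proceeds in five steps:

1. **Alignment.** x is aligned to each candidate with a dynamic-programming
   recursion over monotone state assignments with steps {stay, advance-by-1},
   maximizing Σₖ log N*(xₖ; μ_aₖ, σ_aₖ). The path may start anywhere in the
   first `buffer` states and end anywhere in the last `buffer` states (open
   ends), and — because no state can be skipped — every core (non-buffer)
   state receives at least one measurement, which prevents the squiggle from
   collapsing onto a small part of the candidate. If K is smaller than the
   core state count no path exists and the candidate is flagged unalignable.
2. **Segmentation.** Maximal runs of measurements whose alignment columns
   (across all M candidates) are identical become segments; each segment is
   summarized by its median, which is robust to outliers. Segments longer
   than the 99.5th percentile of the squiggle's own segment lengths are
   dropped as dwell-time artifacts.
3. **Likelihood.** Conditional on the candidate, summaries are independent:
   log P(y | z=m) = Σₙ log N*(yₙ; μ, σ) at the states the summarized
   alignment matrix assigns.
4. **Posterior.** Bayes' rule with the candidate prior (uniform by default;
   per-source multipliers or arbitrary per-candidate weights can encode
   splice-site preferences or annotation trust) gives the assignment
   probability per candidate, computed as a max-subtracted softmax.
5. **Filters.** SIQ = maxₘ (alignment log-likelihood / core state count);
   a call is emitted when SIQ > −0.8 and the top assignment probability
   exceeds 0.8. SIQ is computed on the unsegmented alignment scores because
   it measures alignment quality, which precedes summarization, and its
   denominator excludes buffer states so buffer size cannot distort it.

N* is the normal log-density floored at its value `tail_sd` = 3 standard
deviations from the mean. The floor breaks the unit integral, so N* is used
unnormalized; this is sound because posteriors only ever compare candidates
at the same observation values, where the common normalizer cancels.

## Signal conventions

Raw per-read signals are normalized by median/MAD of the whole read, and
pore-model levels are assumed to be expressed on that same scale; no
rescaling happens at load time. The bundled synthetic model is generated
from a seeded hash of each k-mer (means spanning ≈ [−2, 2], sds
≈ 0.15–0.35) and then calibrated, via the k-mer mixture CDF, so that the
mixture of its state distributions has median 0 and MAD 1 — making the
model self-consistent with read-level normalization. Residual per-read
normalization error shrinks with read length; it is the main source of SIQ
spread in short simulated reads, which is why the simulator defaults to
~2 kb reads (typical for cDNA).

Signal-to-base assignments are consumed as a plain event-table TSV
(`read_id, base_index, start, end`), one row per basecalled position with
its half-open raw-sample interval. During extraction, samples more than 5
normalized units from their event's median are dropped as current spikes
(configurable); the flat likelihood tails bound whatever survives.

## Geometry of candidates and squiggles

The extracted junction squiggle spans `squiggle_flank` = 26 read bases on
each side of the splice (a ~52 nt JWR region). Candidate motifs share a
common genomic start/end at `flank` = 16 bases beyond the widest
candidate's splice sites, plus `buffer` = 10 bases per side for the open
ends. These three defaults are deliberately coupled: with candidates
scanned within `window` = 10 nt of the mapped sites,
`flank = squiggle_flank − window` and `buffer ≥ window` guarantee that for
the true candidate — wherever it sits inside the scan window — the core
states are fully covered by the squiggle while the squiggle's overhang
stays within the skippable buffer. Decoupling them (e.g. a small buffer
with a wide squiggle) forces end-state pile-ups that depress SIQ for
perfectly good on-target squiggles.

Candidate enumeration cross-pairs every donor dinucleotide with every
acceptor dinucleotide found in the window (GT–AG by default; GC–AG and
AT–AC as an option), keeps introns of length ≥ 4, always retains the
mapped junction (even when non-canonical), and caps the set at 32
candidates (mapped plus nearest by total shift) to guard against motif-rich
regions. On the minus strand the genomic intron reads CT…AC and motifs are
reverse-complemented into read orientation.

## Segment length filter

Only segments of at least `min_seg_len` measurements enter the likelihood;
the default is 1 (keep everything). A minimum of 2 looks attractive for
suppressing single-sample noise, but with realistic candidate sets (10–25
candidates from the cross product) it is actively harmful: a wrong
candidate's optimal alignment compresses its mismatching states into 1–2
sample segments, so discarding short segments deletes precisely the
evidence against wrong candidates. In a measured 16-candidate case the true
junction's posterior was 1.0 with the filter off and 0.13 with it on. The
upper length filter and the median summaries already provide the dwell
robustness the minimum filter was meant to add.

## Simulator

The generator inverts the forward model: per state it draws a dwell from a
shifted geometric distribution (minimum 1 sample, mean `dwell_mean` = 8 —
memoryless, consistent with per-sample independence) and emits Gaussian
current with sd `noise_scale` × the model sd; spiked samples are replaced
by μ ± 10σ. Dataset simulation plants true GT..AG introns in a random
genome with decoy GT/AG dinucleotides at ±3–7 nt offsets, maps each read
to the truth with probability `p_correct` = 0.92 (emulating the ~92%
initial-mapping accuracy regime of spliced long-read aligners on synthetic
controls) and otherwise to a planted decoy, and draws a fraction
`offtarget_rate` of signals from unrelated motifs to exercise the SIQ
filter. Raw signals are written on a picoampere-like scale through a
per-read affine transform so the pipeline's normalization is exercised end
to end. Everything is byte-deterministic under the config seed.

What the simulator does **not** emulate: basecalling errors in the read
sequence itself (reads are error-free, so JAQ < 1 arises only from
mismapping), correlated noise and slowly drifting baselines, realistic
k-mer level correlations (neighbouring k-mers get independent hashed
levels, making candidates *more* distinguishable per differing state than
a real pore model), multi-isoform loci, and dwell-time dependence on
sequence. Passing tests therefore demonstrate the correctness and internal
consistency of the machinery and its qualitative behaviour (recovery
degrading with noise, SIQ separating off-target signal), not performance
figures transferable to real flow-cell data.

## Numerical choices

- DTW tie-breaks: on equal scores prefer the predecessor already at the
  state (the advance happened earlier — leftmost path); among equal-score
  admissible end states prefer the largest. Traceback is deterministic.
- Posteriors use max-subtracted exponentiation; likelihood ties reduce
  exactly to the prior; a common additive shift of all log-likelihoods
  changes nothing.
- Segment upper filter uses the "higher" percentile method so the longest
  segment is only dropped when it is a genuine outlier, not by
  interpolation artifacts.
- The auto SIQ threshold is Q1 − 3·IQR of the pooled finite SIQs, floored
  at −0.8 (assumes most JWRs align to the right signal region).
- Degenerate inputs fail loudly and locally: constant signal (MAD = 0),
  empty candidate sets, squiggles shorter than a candidate's core, spans
  not covered by the event table, and all-filtered segmentations each raise
  with a specific message; inside the pipeline such failures are recorded
  per JWR and never abort the run. Every input JWR lands in exactly one
  output category.

## Evaluation problem sizes

The test-suite and acceptance studies use: 200 brute-force-checked DTW
instances (K ≤ 8, ≤ 5 states); 1000 two-candidate recovery replicates per
noise level ∈ {0.5, 1, 2, 4} with common random numbers across levels;
150-JWR datasets for SIQ discrimination (20% off-target, noise 0.5) and
240-JWR datasets for the end-to-end initial-vs-corrected comparison; 200
replicates for spike robustness. These sizes give binomial standard errors
of ~0.7–3% on the reported proportions while keeping the full evaluation
around a minute on one CPU.

## Known limitations

- Identification is closed-world: if the true junction is not among the
  candidates, the best wrong candidate wins or the filters reject the JWR;
  candidate options (annotation, user lists, non-canonical pairs) are the
  mitigation.
- Per-read median/MAD normalization leaves a small systematic shift/scale
  error that all candidates share; very short reads amplify it.
- Dwell time carries no information in the model (a state's evidence is
  its measurements, not their number); dwell modelling is out of scope.
- Genetic variants are not incorporated into motifs; the flat tails absorb
  isolated variant states at a bounded likelihood cost.
- The fast5 adapter (`read_resquiggled_fast5`) is a convenience for data
  in resquiggle-annotated containers and is not exercised by the test
  suite; the event-table TSV is the supported interchange format.
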