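# Methods

## Scope and model

`fragbias` treats an RNA-seq library as a sample of fragments from spliced
transcript sequences, each fragment observed through two reads: a 50-mer
from the 5' end (sense strand) and a 35-mer from the 3' end, emitted as the
reverse complement of the fragment's last 35 bases so that read position 1
is the fragment's 3'-terminal base. Three stages carry the science:

1. **Pile-up statistics** summarize duplication: reads grouped by
   (reference, start, strand, end type, sequence), the pile-up-to-read
   ratio curve over the minimum group size k, and redundancy.
2. **Positional profiles** summarize composition: per-position base
   frequencies, Shannon entropy in bits, and logo heights
   `R·P_b` with `R = 2 − H`.
3. **The resampling null** ties the two together: for each mapped read a
   200 bp cDNA window is predicted from the transcript model at the read's
   location and random 50/35-mers are redrawn from it, so the null carries
   the library's positional composition but no end preference.

## Fragmentation simulator

The generative model is: sample a fragment **start** position with
per-position weights, then an **end** position with weight × a Gaussian
length kernel (mean `target_len` = 200 nt, sd `len_sd` = 25 nt), truncated
to the transcript and to a 50 nt minimum (a fragment must cover the longer
read). Modes differ only in the weights:

* `heat` — all weights 1: breakpoints uniform over internal bonds,
  modelling thermal fragmentation where every phosphodiester bond is
  equally exposed.
* `rnaseiii` — candidate starts whose dinucleotide equals `motif5`
  (default `AA`) and ends preceded by `motif3` (default `CC`) carry
  relative weight λ = `bias_strength` ≥ 1. λ is a dial, not a measured
  constant: at λ = 1 the sampler is bit-identical to `heat`; λ = 50 gives
  the qualitative regime where most fragments start at motif sites. Start
  and end are biased independently; nothing in the end-sequence statistics
  the package computes distinguishes joint from independent cutting, so
  the simpler model was chosen.
* `t4pnk_after_heat` — heat fragmentation followed by per-base acceptance
  weights on the first and last fragment base (kept with probability
  `end5_w[first] · end3_w[last]`). Defaults emulate a strong A/T
  3'-terminal (phosphatase) preference (`A=T=1, C=G=0.25`) and a minor 5'
  (kinase) bias (`A=T=1, C=G=0.8`). These default magnitudes are a
  modelling choice: strong enough that the 3' A/T preference is obvious in
  a 10,000-read logo, weak enough at the 5' end to stay "minor".
* `optik_then_t4pnk` — the same weights shrunk toward uniform by a convex
  combination with shrink factor 0.9 (90 % of the bias removed), modelling
  an alternative kinase that largely, but not completely, removes the
  end-selection bias.

Only the long fragments are modelled; the short by-product of paired
nuclease cuts is never sequenced and is therefore not simulated. Each
emitted read pair carries true simulated coordinates — no aligner runs, so
mapping error is exactly zero by construction.

Read qualities are Phred+33. Baseline calls are drawn from Q30–Q40 (never
below the Q8 threshold); a `lowq_fraction` of reads (independently per
end) instead receives 14–21 (50-mers) or 10–15 (35-mers) calls below Q8 at
random positions — just past the filter's allowance, so the fraction of
filter failures equals `lowq_fraction` exactly in expectation. This is a
mechanism for exercising the filter, not a model of real quality decay.

### What the simulator does not emulate

Expression heterogeneity beyond length-proportional fragment allocation,
PCR amplification and GC bias, adaptor read-through, sequencing error in
the base calls, intron retention, and any secondary-structure mechanism
behind cut-site preference. Passing tests therefore demonstrate that the
statistics detect *planted end preferences against a composition-matched
null*, not that any particular enzyme behaves as modelled.

## Quality and contaminant filters

A base call is "low quality" when its Phred score is **strictly below 8**;
a 50-mer is dropped when **more than 13** such calls occur, a 35-mer when
**more than 9**. All three inequalities are strict, following the rule's
wording rather than the ≥ conventions of some kits. Other read lengths use
the nearest rule (≥ 43 nt → the 50-mer allowance) with a logged warning.

The contaminant screen compares each read's first 20 bases against every
20-mer window of every supplied contaminant, both strands, and drops the
read at ≤ 2 mismatches. This prefix-versus-window Hamming scan reproduces
the 2-of-20 criterion without re-implementing a full mapper and is an
approximation: a mapper allowing indels or seeding away from the read
start would make slightly different calls.

Multi-mapped reads are resolved by choosing one candidate placement
uniformly at random under a fixed seed; the chosen record keeps the
candidate count in `n_candidate_locations`.

## Pile-ups

The default group key includes the read sequence ("same location and
exactly the same sequence"); a position-only key is available as
`key_mode="position"`. `remove_pileup_reads` keeps one representative per
large group — the lexicographically smallest read id, a deterministic
tie-break — rather than deleting whole groups, so downstream profiles
retain one witness per site. Deduplication interacts with transcriptome
size: when reads saturate every position of a small reference, the
deduplicated read set approaches "all positions once" and any start-site
preference flattens. The persistence of bias after deduplication is
therefore a sparse-regime property, and tests probe it with transcriptomes
large relative to the read count.

## Profiles and logos

Entropy uses log base 2 throughout; the 2-bit ceiling makes logo heights
conventional. The small-sample correction `e_n = 3/(2 ln 2 · n)` is off by
default (profiles here are computed from ≥ 10³ reads where it is < 0.002
bits) and available as a flag. Ambiguous bases are excluded per column
with renormalization and a logged count. Logo subsamples default to 10,000
reads, drawn uniformly without replacement under a fixed seed.

3' reads are profiled **as sequenced** for ordinary logos; only the
cutter-signature summary reverse-complements them, so a `GG` read-start
preference surfaces as a `CC` fragment end.

## The null model

Window anchoring is the least-assumption reading of "based on mapped read
locations": a 5' read's window starts at its 5' start and extends 3'-ward
(shifted upstream at the transcript end); a 3' read's window ends at the
fragment end and is reverse-complemented into read orientation. Reads
falling outside every supplied transcript are skipped with a logged count;
the null is defined over whatever transcript models are given.

Replicate RNG: one master seed spawns an independent stream per replicate
index (`default_rng([seed, replicate])`), so envelopes are reproducible
and order-independent, and a single replicate (used for logo-style control
displays) is addressable directly. The envelope records per-position mean
and sd of both entropy and the base frequencies; 1000 replicates is the
default, and analyses that only need the envelope's location (signature
calls in tests) use 20–50 replicates, which changes the sd estimate by
well under the decision margins involved.

A numerical note: for near-uniform composition the first-order delta-method
variance term of the plug-in entropy estimator vanishes, so the replicate
sd scales like 1/n in reads rather than 1/√n; the 1/√n regime appears for
skewed composition. The estimator's downward bias, ≈ 3/(2 ln 2 · n), is
0.0011 bits at n = 2000 — the reason the "flatness" acceptance check on a
uniform transcriptome passes with margin at that read count.

## Enrichment and signature calls

Per position the enrichment table reports observed and control-mean base
frequencies, per-base z-scores `(obs − mean)/sd`, the entropy z-score, and
the information excess `control H mean − observed H`. Positions with zero
control sd get NaN z-scores (flagged, never infinite). The signature takes
the argmax base at positions 1–2 of each end where the information excess
clears a floor of **0.15 bits** (an invented operating point: comfortably
above the ≲ 0.01-bit excesses of unbiased simulations and far below the
~1-bit excesses of strong motif bias; exposed as a parameter). Signature
width is fixed at two bases per end.

## Problem sizes and determinism

Default study conditions: toy transcriptomes of 10–20 transcripts around
1000–1500 nt at GC 0.5; libraries of 15,000–50,000 fragments; 10,000-read
logo subsamples; 1000-replicate envelopes where the envelope itself is the
object under study and 20–50 where only its location matters. Every
stochastic step takes an explicit seed and the full pipeline writes a
manifest with seeds and output checksums; reruns are bit-identical.

## Known limitations

* The contaminant filter is a prefix scan, not an alignment (above).
* Transcript models assume non-overlapping exons per transcript and
  resolve genome-coordinate reads to the first containing transcript.
* SAM ingestion handles ungapped primary alignments; spliced alignments
  contribute their leftmost block only.
* The signature caller reports dinucleotides only; longer or gapped motifs
  are out of scope.
* Pile-up statistics assume reads are already uniquely assigned; feeding
  multi-mapped duplicates inflates group counts.
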