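# fragbias

Detection and simulation of **fragment-end sequence bias** in RNA-seq
libraries.

Library-preparation enzymes are not neutral. A fragmentation nuclease with a
preferred cut site, or an end-repair kinase/phosphatase that accepts some
terminal bases more readily than others, concentrates fragment ends on a
subset of positions. In mapped reads this shows up as *pile-ups* — many reads
with exactly the same coordinates and sequence — and as a depression of the
per-position base-composition entropy at the first read positions. `fragbias`
quantifies both effects and, because its null model resamples the transcript
sequence at the very locations where the reads map, it separates genuine
end preference from local base composition.

The package is aimed at people building or debugging RNA-seq library
protocols and at anyone who needs pile-up/duplication statistics with a
composition-matched null. A bundled simulator generates libraries under
heat fragmentation (uniform breakpoints), motif-biased nuclease cutting,
and A/T-preferring end repair, so every stage is testable against known
truth without downloading any data.

## The statistics

For reads of fixed length, let `P_A, P_C, P_G, P_T` be the relative base
abundances at read position *i*. The positional entropy is

    H_i = − Σ_b P_b log2 P_b        (bits; 2 = no preference, 0 = fixed base)

and the sequence-logo letter height at position *i* is `R_i · P_b` with
information content `R_i = 2 − H_i` (optionally minus the small-sample
correction `e_n = 3 / (2 ln 2 · n)`).

Pile-ups are groups of reads sharing location (and, by default, sequence).
With group sizes `c_1, c_2, …` over `N` reads, the **pile-up-to-read ratio**
at minimum pile-up size *k* is

    ratio(k) = Σ_{c_j ≥ k} c_j / N      (ratio(1) = 1; non-increasing in k)

and the **redundancy** is `(N − #groups) / N`.

The **computational control** predicts a 200 bp cDNA window per mapped read
from the transcript model, redraws random 50 bp (5' reads) or 35 bp
(3' reads) subsequences from those windows, and repeats the draw 1000 times
to produce a per-position mean ± sd entropy envelope. Observed-minus-control
comparisons yield per-base z-scores and an *information excess*
(control mean H − observed H, in bits). The **cutter signature** reports the
dominant bases at positions 1–2 of both read ends (the 3' dinucleotide
reverse-complemented into fragment sense), with positions below an
information-excess floor reported as `N`.

## Worked example

```python
import fragbias as fb
from fragbias.control import ControlConfig

# a toy transcriptome and a strongly motif-biased library (lambda = 50)
transcripts = fb.make_transcriptome(n_transcripts=20, len_mean=1500, gc=0.5, seed=7)
cfg = fb.FragSimConfig(mode="rnaseiii", bias_strength=50.0, n_fragments=20_000, seed=8)
fastq, mapped, frags = fb.simulate_library(transcripts, cfg)

table = fb.group_pileups(mapped)
print(fb.ratio_curve(table, k_max=5).ratio.round(3))   # [1. 0.795 0.747 0.729 0.701]
print(round(fb.redundancy(table), 3))                  # 0.685

reads5 = [r for r in mapped if r.end_type == "5p"]
sample = fb.subsample_reads(reads5, n=10_000, seed=8)
profile = fb.profile_reads(sample)
print(profile.entropy[:4].round(3))                    # [0.998 0.988 1.999 2.]

env = fb.control_entropy_envelope(
    sample, transcripts, ControlConfig(read_len=50, n_replicates=50, seed=8))
enr5 = fb.enrichment(profile, env)
# ... same for 3' reads with read_len=35, then:
# sig = fb.cutter_signature(enr5, enr3)
# -> signature: 5'-AA ... CC-3', info excess ~1.0 bits at positions 1-2
```

The ratio curve staying near 0.8 at k = 2 and the entropy dropping to ~1.0
bit at read positions 1–2 (against a flat ≈2-bit control) are the two
fingerprints of fragment-end bias; the recovered `5'-AA ... CC-3'` signature
matches the motif the simulator planted.

The same analysis is available from the shell:

```sh
fragbias make-demo --out demo.yaml
fragbias run-all --config demo.yaml --outdir demo_out
```

which simulates three libraries (motif-biased nuclease, heat + end repair,
heat + shrunk end repair), runs QC, pile-up curves, profiles, controls, and
signature calls, and writes a manifest with seeds and output checksums.

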