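"""Synthetic transcriptomes and fragmentation/library-construction simulation.

The simulator emulates the library-construction regimes whose end biases the
analysis stages are designed to detect:

* ``heat`` — thermal fragmentation: every internal phosphodiester bond is
  equally likely to break, so fragment start positions are uniform.
* ``rnaseiii`` — nuclease fragmentation with a cut-site motif preference:
  candidate fragment starts matching ``motif5`` (default ``AA``) and ends
  matching ``motif3`` (default ``CC``) are up-weighted by ``bias_strength``
  (lambda; lambda = 1 reduces exactly to ``heat``).
* ``t4pnk_after_heat`` — heat fragmentation followed by enzymatic end repair
  whose phosphatase step prefers A/T 3'-terminal fragments (per-base
  acceptance weights on the first and last fragment base).
* ``optik_then_t4pnk`` — as above but with the acceptance weights shrunk
  toward uniform (an alternative kinase that largely removes the
  end-selection bias).

Fragments are ~200 bp; each yields a 50-mer 5' read (sense) and a 35-mer 3'
read emitted as the reverse complement of the fragment's last 35 bases, so
read position 1 is the fragment's 3'-terminal base. Mapped coordinates are
the true simulated transcript coordinates — no aligner is involved.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np

from ._util import encode_seq, log, revcomp
from .io import FastqRead, MappedRead

MODES = ("heat", "rnaseiii", "t4pnk_after_heat", "optik_then_t4pnk")

#: minimum fragment length retained (must cover the longer read)
MIN_FRAG_LEN = 50

#: default end-repair acceptance weights: minor 5' (kinase) bias, strong
#: A/T 3'-terminal (phosphatase) preference
DEFAULT_END5_WEIGHTS = {"A": 1.0, "C": 0.8, "G": 0.8, "T": 1.0}
DEFAULT_END3_WEIGHTS = {"A": 1.0, "C": 0.25, "G": 0.25, "T": 1.0}


@dataclasses.dataclass(frozen=True)
class TranscriptModel:
    """A transcript: exon structure on the genome plus its spliced sequence."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    spliced_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        prev_end = -1
        total = 0
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise ValueError(f"{self.transcript_id}: bad exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = end
            total += end - start
        if total != len(self.spliced_seq):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {total}, "
                f"spliced_seq has {len(self.spliced_seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.spliced_seq)


@dataclasses.dataclass(frozen=True)
class Fragment:
    """A fragment of a transcript in spliced (transcript) coordinates."""

    transcript_id: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")
        if len(self.seq) != self.end - self.start:
            raise ValueError("fragment seq length does not match its interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class FragSimConfig:
    """Parameters of the fragmentation + end-selection model.

    ``bias_strength`` (lambda >= 1) multiplies the sampling weight of
    candidate starts/ends matching ``motif5``/``motif3``; 1 means unbiased.
    ``end5_weights``/``end3_weights`` are per-base acceptance probabilities
    in [0, 1] applied to the first/last fragment base during end repair.
    ``lowq_fraction`` of emitted reads receive enough sub-threshold quality
    calls to fail the downstream quality filter.
    """

    mode: str = "heat"
    target_len: int = 200
    len_sd: float = 25.0
    motif5: str = "AA"
    motif3: str = "CC"
    bias_strength: float = 1.0
    end5_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_END5_WEIGHTS)
    )
    end3_weights: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_END3_WEIGHTS)
    )
    optik_shrink: float = 0.9
    n_fragments: int = 10_000
    lowq_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.bias_strength < 1:
            raise ValueError("bias_strength (lambda) must be >= 1")
        if not (0 <= self.lowq_fraction <= 1):
            raise ValueError("lowq_fraction must lie in [0, 1]")
        if self.target_len < MIN_FRAG_LEN or self.len_sd <= 0:
            raise ValueError("target_len must be >= 50 and len_sd positive")
        if not (0 <= self.optik_shrink <= 1):
            raise ValueError("optik_shrink must lie in [0, 1]")
        for table in (self.end5_weights, self.end3_weights):
            if set("ACGT") - set(table):
                raise ValueError("end weights must cover all of A, C, G, T")
            if any(not (0 <= w <= 1) for w in table.values()):
                raise ValueError("end weights must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def make_transcriptome(
    n_transcripts: int,
    len_mean: int = 1500,
    gc: float = 0.5,
    seed: int = 0,
    max_exons: int = 3,
) -> list[TranscriptModel]:
    """Generate a toy transcriptome with i.i.d. bases at a given GC content.

    Spliced lengths are drawn around ``len_mean`` (never below 300); each
    transcript gets 1..``max_exons`` exons laid out with random intron gaps
    on its own synthetic locus. Deterministic given ``seed``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if len_mean < 300:
        raise ValueError("len_mean must be >= 300")
    if not (0 <= gc <= 1):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    transcripts = []
    for i in range(n_transcripts):
        length = max(300, int(round(rng.normal(len_mean, 0.15 * len_mean))))
        seq = rng.choice(bases, size=length, p=p).tobytes().decode("ascii")
        n_exons = int(rng.integers(1, max_exons + 1))
        # split spliced length into n_exons parts of >= 50 nt where possible
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) \
            if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate(([0], cuts, [length])))
        pos = int(rng.integers(0, 1000))
        exons = []
        for el in exon_lens:
            exons.append((pos, pos + int(el)))
            pos += int(el) + int(rng.integers(50, 500))  # intron gap
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{i:04d}",
                chrom=f"chr{i + 1}",
                strand="+",
                exons=tuple(exons),
                spliced_seq=seq,
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def _motif_weights(seq: str, motif: str, lam: float, anchor: str) -> np.ndarray:
    """Per-position sampling weights: lam where the motif sits, else 1.

    ``anchor='start'`` weights position i by seq[i:i+k] == motif;
    ``anchor='end'`` weights the half-open end coordinate j by
    seq[j-k:j] == motif (array indexed 0..L, entry 0..k-1 unused).
    """
    codes = encode_seq(seq)
    target = encode_seq(motif)
    k = len(motif)
    L = len(seq)
    hit = np.ones(L - k + 1, dtype=bool)
    for off in range(k):
        hit &= codes[off : L - k + 1 + off] == target[off]
    if anchor == "start":
        w = np.ones(L)
        w[: L - k + 1][hit] = lam
    else:
        w = np.ones(L + 1)
        w[k:][hit] = lam
    return w


def _sample_fragments(
    t: TranscriptModel,
    cfg: FragSimConfig,
    start_weights: np.ndarray,
    end_weights: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Sample fragments: a start by weight, then an end by weight times a
    Gaussian length kernel centred on ``target_len`` (sd ``len_sd``),
    truncated to the transcript."""
    L = t.length
    if L < MIN_FRAG_LEN + 1 or L < cfg.target_len / 2:
        log.warning(
            "%s: transcript length %d too short to fragment (target %d); skipping",
            t.transcript_id, L, cfg.target_len,
        )
        return []
    d_max = min(L, int(cfg.target_len + 5 * cfg.len_sd))
    d_grid = np.arange(MIN_FRAG_LEN, d_max + 1)
    kernel = np.exp(-0.5 * ((d_grid - cfg.target_len) / cfg.len_sd) ** 2)

    ws = start_weights.copy()
    ws[L - MIN_FRAG_LEN + 1 :] = 0.0  # a start must leave room for a fragment
    starts = rng.choice(L, size=n, p=ws / ws.sum())

    we_pad = np.zeros(L + d_max + 2)
    we_pad[: L + 1] = end_weights

    seq = t.spliced_seq
    frags: list[Fragment] = []
    for lo in range(0, n, 8192):
        chunk = starts[lo : lo + 8192]
        j = chunk[:, None] + d_grid[None, :]
        w = kernel[None, :] * we_pad[j]
        c = np.cumsum(w, axis=1)
        tot = c[:, -1]
        ok = tot > 0
        u = rng.random(len(chunk)) * tot
        pick = np.minimum((c <= u[:, None]).sum(axis=1), len(d_grid) - 1)
        ends = chunk + d_grid[pick]
        for s, e, keep in zip(chunk.tolist(), ends.tolist(), ok.tolist()):
            if keep:
                frags.append(Fragment(t.transcript_id, s, e, seq[s:e]))
    return frags


def fragment_heat(
    t: TranscriptModel,
    cfg: FragSimConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Thermal fragmentation: breakpoints uniform over internal bonds."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_fragments if n is None else n
    return _sample_fragments(
        t, cfg, np.ones(t.length), np.ones(t.length + 1), n, rng
    )


def fragment_rnaseiii(
    t: TranscriptModel,
    cfg: FragSimConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Nuclease fragmentation with motif-biased cut sites.

    Start positions matching ``motif5`` and end positions preceded by
    ``motif3`` carry relative weight lambda = ``bias_strength``; at
    lambda = 1 the output distribution equals :func:`fragment_heat`'s.
    """
    if cfg.bias_strength < 1:
        raise ValueError("bias_strength (lambda) must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_fragments if n is None else n
    ws = _motif_weights(t.spliced_seq, cfg.motif5, cfg.bias_strength, "start")
    we = _motif_weights(t.spliced_seq, cfg.motif3, cfg.bias_strength, "end")
    return _sample_fragments(t, cfg, ws, we, n, rng)


# ---------------------------------------------------------------------------
# End selection (T4PNK / OptiKinase)
# ---------------------------------------------------------------------------

def effective_end_weights(cfg: FragSimConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Per-base acceptance weights actually applied in ``cfg.mode``.

    Fragmentation-only modes (heat, rnaseiii) select nothing (all 1);
    ``optik_then_t4pnk`` shrinks the configured weights toward uniform by
    ``optik_shrink`` (w' = shrink * 1 + (1 - shrink) * w).
    """
    if cfg.mode in ("heat", "rnaseiii"):
        ones = {b: 1.0 for b in "ACGT"}
        return ones, dict(ones)
    if cfg.mode == "optik_then_t4pnk":
        s = cfg.optik_shrink
        return (
            {b: s + (1 - s) * cfg.end5_weights[b] for b in "ACGT"},
            {b: s + (1 - s) * cfg.end3_weights[b] for b in "ACGT"},
        )
    return dict(cfg.end5_weights), dict(cfg.end3_weights)


def apply_end_selection(
    frags: Sequence[Fragment],
    cfg: FragSimConfig,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Thin fragments by end-repair acceptance: each fragment survives with
    probability end5_weight[first base] * end3_weight[last base].

    Sequences are never altered, only membership; order is preserved.
    """
    if not frags:
        return []
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    w5, w3 = effective_end_weights(cfg)
    p = np.array([w5.get(f.seq[0], 1.0) * w3.get(f.seq[-1], 1.0) for f in frags])
    keep = rng.random(len(frags)) < p
    return [f for f, k in zip(frags, keep) if k]


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _lowq_count_range(read_len: int) -> tuple[int, int]:
    # enough Q<8 calls to exceed the quality-filter allowance for this length
    max_low = 13 if read_len >= 43 else 9
    return max_low + 1, min(read_len, max_low + 8)


def _make_quals(
    read_len: int, lowq: bool, rng: np.random.Generator
) -> tuple[int, ...]:
    quals = rng.integers(30, 41, size=read_len)
    if lowq:
        lo, hi = _lowq_count_range(read_len)
        n_low = int(rng.integers(lo, hi + 1))
        pos = rng.choice(read_len, size=n_low, replace=False)
        quals[pos] = rng.integers(0, 8, size=n_low)
    return tuple(int(q) for q in quals)


def fragments_to_reads(
    frags: Sequence[Fragment],
    cfg: FragSimConfig,
    len5: int = 50,
    len3: int = 35,
    rng: np.random.Generator | None = None,
    id_prefix: str = "sim",
) -> tuple[list[FastqRead], list[MappedRead]]:
    """Emit a 5' and a 3' read per fragment with true mapped coordinates.

    The 5' read is the first ``len5`` fragment bases (sense strand); the 3'
    read is the reverse complement of the last ``len3`` bases, so its first
    base is the fragment's 3'-terminal base. A ``lowq_fraction`` of reads
    (independently per end) receives more sub-Q8 base calls than the
    quality filter tolerates. Fragments shorter than either read length are
    skipped with a logged count.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    fastq: list[FastqRead] = []
    mapped: list[MappedRead] = []
    n_skipped = 0
    for k, frag in enumerate(frags):
        if frag.length < max(len5, len3):
            n_skipped += 1
            continue
        rid = f"{id_prefix}{k:07d}"
        seq5 = frag.seq[:len5]
        seq3 = revcomp(frag.seq[-len3:])
        q5 = _make_quals(len5, rng.random() < cfg.lowq_fraction, rng)
        q3 = _make_quals(len3, rng.random() < cfg.lowq_fraction, rng)
        fastq.append(FastqRead(rid + "_5p", seq5, list(q5)))
        fastq.append(FastqRead(rid + "_3p", seq3, list(q3)))
        mapped.append(
            MappedRead(rid + "_5p", frag.transcript_id, frag.start,
                       frag.start + len5, "+", "5p", seq5, q5)
        )
        mapped.append(
            MappedRead(rid + "_3p", frag.transcript_id, frag.end - len3,
                       frag.end, "-", "3p", seq3, q3)
        )
    if n_skipped:
        log.warning("fragments_to_reads: skipped %d fragments shorter than a read", n_skipped)
    return fastq, mapped


# ---------------------------------------------------------------------------
# Whole-library convenience
# ---------------------------------------------------------------------------

def simulate_library(
    transcripts: Sequence[TranscriptModel],
    cfg: FragSimConfig,
    len5: int = 50,
    len3: int = 35,
) -> tuple[list[FastqRead], list[MappedRead], list[Fragment]]:
    """Simulate one library under ``cfg.mode`` across a transcriptome.

    ``cfg.n_fragments`` fragments are allocated to transcripts in
    proportion to spliced length (multinomial), fragmented per mode,
    end-selected, and emitted as paired 5'/3' reads. Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = np.array([t.length for t in transcripts], dtype=float)
    alloc = rng.multinomial(cfg.n_fragments, lengths / lengths.sum())
    fragment = fragment_rnaseiii if cfg.mode == "rnaseiii" else fragment_heat
    frags: list[Fragment] = []
    for t, n in zip(transcripts, alloc):
        if n:
            frags.extend(fragment(t, cfg, n=int(n), rng=rng))
    frags = apply_end_selection(frags, cfg, rng=rng)
    fastq, mapped = fragments_to_reads(frags, cfg, len5=len5, len3=len3, rng=rng)
    return fastq, mapped, frags


def write_truth_table(frags: Sequence[Fragment], path) -> None:
    """Write true fragment coordinates as a TSV (transcript, start, end)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tstart\tend\n")
        for f in frags:
            fh.write(f"{f.transcript_id}\t{f.start}\t{f.end}\n")


def write_config(cfg: FragSimConfig, path) -> None:
    """Persist a simulation config as a flat key=value file."""
    with open(path, "w") as fh:
        for field in dataclasses.fields(cfg):
            value = getattr(cfg, field.name)
            if isinstance(value, Mapping):
                value = ",".join(f"{k}:{v}" for k, v in sorted(value.items()))
            fh.write(f"{field.name}={value}\n")


def transcripts_to_exon_table(transcripts: Sequence[TranscriptModel]):
    """Exon-table TSV layout (one row per exon) for transcript models."""
    import pandas as pd

    rows = []
    for t in transcripts:
        for start, end in t.exons:
            rows.append((t.transcript_id, t.chrom, t.strand, start, end))
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "strand", "start", "end"])


def write_transcripts(transcripts: Sequence[TranscriptModel], exon_path, fasta_path) -> None:
    """Write transcript models as an exon TSV plus spliced-sequence FASTA."""
    transcripts_to_exon_table(transcripts).to_csv(exon_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n{t.spliced_seq}\n")


def read_transcripts(exon_path, fasta_path) -> list[TranscriptModel]:
    """Rebuild transcript models from an exon TSV and spliced FASTA."""
    import pandas as pd
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(exon_path, sep="\t")
    transcripts = []
    for tid, grp in table.groupby("transcript_id", sort=False):
        exons = tuple(
            (int(r.start), int(r.end)) for r in grp.sort_values("start").itertuples()
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=str(tid),
                chrom=str(grp.iloc[0]["chrom"]),
                strand=str(grp.iloc[0]["strand"]),
                exons=exons,
                spliced_seq=seqs[str(tid)],
            )
        )
    return transcripts
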