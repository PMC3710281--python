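"""Resampling null model ("computational control") for positional bias.

For every mapped read a 200 bp cDNA window is predicted from the transcript
model at the read's location; control pseudo-reads are then drawn as random
contiguous 50 bp (or 35 bp) subsequences of those windows. Because the null
resamples only *where* reads map — not their sequences — it captures local
base composition while erasing any fragment-end preference. Repeating the
draw (1000 replicates by default) gives a per-position mean-and-sd entropy
envelope against which an observed profile is compared.

Window anchoring: a 5' read's window starts at the read's transcript-space
5' start and extends 3'-ward, shifted upstream when it would overrun the
transcript end; a 3' read's window ends at the read's fragment-end
coordinate and is reverse-complemented so that window position 1 aligns
with read position 1 in sequenced orientation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from ._util import BASES, encode_seqs, log, revcomp
from .io import MappedRead
from .profiles import column_frequencies, entropy_from_freqs
from .simulate import TranscriptModel


@dataclasses.dataclass(frozen=True)
class ControlConfig:
    """Null-model parameters: window and control-read lengths, replicates."""

    window_len: int = 200
    read_len: int = 50
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.window_len:
            raise ValueError("read_len must not exceed window_len")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclasses.dataclass
class ControlEnvelope:
    """Per-position entropy mean/sd (and base-frequency mean/sd) across
    control replicates."""

    entropy_mean: np.ndarray
    entropy_sd: np.ndarray
    freq_mean: pd.DataFrame
    freq_sd: pd.DataFrame
    n_replicates: int
    read_len: int

    def to_frame(self) -> pd.DataFrame:
        out = self.freq_mean.copy()
        out.columns = [f"P_{b}_mean" for b in out.columns]
        for b in BASES:
            out[f"P_{b}_sd"] = self.freq_sd[b].to_numpy()
        out["H_mean"] = self.entropy_mean
        out["H_sd"] = self.entropy_sd
        return out


# ---------------------------------------------------------------------------
# Window prediction
# ---------------------------------------------------------------------------

def _transcript_offset(t: TranscriptModel, genomic_pos: int) -> int | None:
    """Spliced-coordinate offset of a genomic position, or None if intronic."""
    spliced = 0
    for start, end in t.exons:
        if start <= genomic_pos < end:
            offset = spliced + (genomic_pos - start)
            if t.strand == "-":
                offset = t.length - 1 - offset
            return offset
        spliced += end - start
    return None


def _locate(read: MappedRead, by_id: dict, by_chrom: dict) -> tuple[TranscriptModel, int, int] | None:
    """Map a read to (transcript, spliced start, spliced end)."""
    if read.ref in by_id:
        t = by_id[read.ref]
        if read.end > t.length:
            return None
        return t, read.start, read.end
    for t in by_chrom.get(read.ref, ()):
        ts = _transcript_offset(t, read.start)
        te = _transcript_offset(t, read.end - 1)
        if ts is not None and te is not None:
            lo, hi = min(ts, te), max(ts, te)
            return t, lo, hi + 1
    return None


def predict_cdna_windows(
    reads: Sequence[MappedRead],
    transcripts: Sequence[TranscriptModel],
    cfg: ControlConfig | None = None,
) -> list[str]:
    """Predict one window of ``cfg.window_len`` nt per read from its
    transcript, oriented to match the read's sequenced direction.

    Reads may be addressed in transcript coordinates (``ref`` equals a
    transcript id) or genome coordinates (``ref`` equals a chromosome, with
    exon-aware projection across splice junctions). Reads with no containing
    transcript, and reads on transcripts shorter than the window, are
    skipped with a logged count.
    """
    cfg = cfg or ControlConfig()
    W = cfg.window_len
    by_id = {t.transcript_id: t for t in transcripts}
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)

    windows: list[str] = []
    n_unlocated = 0
    n_short = 0
    for read in reads:
        hit = _locate(read, by_id, by_chrom)
        if hit is None:
            n_unlocated += 1
            continue
        t, ts, te = hit
        if t.length < W:
            n_short += 1
            continue
        if read.end_type == "3p":
            # window ends at the fragment's 3' end, shifted downstream at 0
            w_end = min(max(te, W), t.length)
            windows.append(revcomp(t.spliced_seq[w_end - W : w_end]))
        else:
            # window starts at the read's 5' start, shifted upstream at the end
            w_start = max(0, min(ts, t.length - W))
            windows.append(t.spliced_seq[w_start : w_start + W])
    if n_unlocated:
        log.warning("predict_cdna_windows: %d reads had no containing transcript", n_unlocated)
    if n_short:
        log.warning("predict_cdna_windows: %d reads on transcripts shorter than %d nt", n_short, W)
    return windows


# ---------------------------------------------------------------------------
# Control-read sampling
# ---------------------------------------------------------------------------

def sample_control_reads(
    windows: Sequence[str], cfg: ControlConfig, replicate: int = 0
) -> list[str]:
    """Draw one control read per window: a contiguous ``read_len``
    subsequence at a start offset uniform on [0, window_len - read_len].

    Deterministic given (``cfg.seed``, ``replicate``).
    """
    rng = np.random.default_rng([cfg.seed, replicate])
    span = cfg.window_len - cfg.read_len + 1
    offsets = rng.integers(0, span, size=len(windows))
    return [w[o : o + cfg.read_len] for w, o in zip(windows, offsets.tolist())]


def _replicate_freqs(codes: np.ndarray, cfg: ControlConfig, replicate: int) -> np.ndarray:
    """(read_len, 4) base frequencies of one control replicate, drawn from
    the encoded (n, window_len) window matrix."""
    rng = np.random.default_rng([cfg.seed, replicate])
    n = codes.shape[0]
    span = cfg.window_len - cfg.read_len + 1
    offsets = rng.integers(0, span, size=n)
    cols = offsets[:, None] + np.arange(cfg.read_len)[None, :]
    sub = codes[np.arange(n)[:, None], cols]
    return column_frequencies(sub)


def control_entropy_envelope(
    reads: Sequence[MappedRead],
    transcripts: Sequence[TranscriptModel],
    cfg: ControlConfig | None = None,
    windows: Sequence[str] | None = None,
) -> ControlEnvelope:
    """Replicate the control draw and summarize per-position entropy (and
    base frequencies) as mean and sd across replicates.

    One master seed spawns a stream per replicate index, so results are
    independent of evaluation order. Precomputed ``windows`` may be passed
    to skip window prediction.
    """
    cfg = cfg or ControlConfig()
    if cfg.n_replicates < 2:
        raise ValueError("an envelope needs n_replicates >= 2")
    if windows is None:
        windows = predict_cdna_windows(reads, transcripts, cfg)
    if not windows:
        raise ValueError("no control windows could be predicted")
    codes = encode_seqs(list(windows))

    L = cfg.read_len
    h_sum = np.zeros(L)
    h_sq = np.zeros(L)
    f_sum = np.zeros((L, 4))
    f_sq = np.zeros((L, 4))
    for rep in range(cfg.n_replicates):
        freqs = _replicate_freqs(codes, cfg, rep)
        h = entropy_from_freqs(freqs)
        h_sum += h
        h_sq += h * h
        f_sum += freqs
        f_sq += freqs * freqs
    n = cfg.n_replicates
    h_mean = h_sum / n
    h_sd = np.sqrt(np.clip(h_sq / n - h_mean**2, 0.0, None))
    f_mean = f_sum / n
    f_sd = np.sqrt(np.clip(f_sq / n - f_mean**2, 0.0, None))
    idx = pd.RangeIndex(1, L + 1, name="pos")
    return ControlEnvelope(
        entropy_mean=h_mean,
        entropy_sd=h_sd,
        freq_mean=pd.DataFrame(f_mean, columns=list(BASES), index=idx),
        freq_sd=pd.DataFrame(f_sd, columns=list(BASES), index=idx),
        n_replicates=n,
        read_len=L,
    )


def control_profile(
    reads: Sequence[MappedRead],
    transcripts: Sequence[TranscriptModel],
    cfg: ControlConfig | None = None,
    replicate: int = 0,
):
    """Single-replicate control profile (the logo-style control, which uses
    one draw rather than the replicate envelope)."""
    from .profiles import profile_sequences

    cfg = cfg or ControlConfig()
    windows = predict_cdna_windows(reads, transcripts, cfg)
    if not windows:
        raise ValueError("no control windows could be predicted")
    return profile_sequences(sample_control_reads(windows, cfg, replicate))
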