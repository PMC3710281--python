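"""Positional base frequencies, entropy profiles, and sequence-logo
matrices for fixed-length read sets.

At each read position the base distribution (P_A, P_C, P_G, P_T) yields the
Shannon entropy H = -sum_i P_i log2 P_i in bits (2 bits = no preference,
0 bits = fixed base). The logo total height at a position is the
information content R = 2 - H, optionally reduced by the small-sample
correction e_n = 3 / (2 ln 2 n); each letter's height is R * P_base.
Ambiguous bases (N) are excluded per column with renormalization.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd

from ._util import BASES, encode_seqs, log, revcomp
from .io import MappedRead

#: logo subsample size conventionally used for display
LOGO_SAMPLE_SIZE = 10_000


@dataclasses.dataclass
class PositionProfile:
    """Per-position base frequencies, entropy and logo heights."""

    window_len: int
    freqs: pd.DataFrame          # index: 1-based position; columns A,C,G,T
    entropy: np.ndarray          # bits, one value per position
    logo_heights: pd.DataFrame   # same layout as freqs
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        out = self.freqs.copy()
        out["H"] = self.entropy
        out["R"] = self.logo_heights.sum(axis=1)
        return out


def column_frequencies(codes: np.ndarray) -> np.ndarray:
    """(L, 4) base frequencies from an (n, L) code matrix; codes >= 4
    (ambiguous bases) are dropped per column with renormalization."""
    n, L = codes.shape
    valid = codes < 4
    n_ambiguous = int((~valid).sum())
    if n_ambiguous:
        log.info("excluded %d ambiguous base calls from frequency columns", n_ambiguous)
    # per-column tally: offset each column into its own bincount stratum
    offsets = np.arange(L, dtype=np.intp) * 4
    idx = (codes[valid].astype(np.intp)
           + np.broadcast_to(offsets, codes.shape)[valid])
    counts = np.bincount(idx, minlength=L * 4).reshape(L, 4).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a column has no unambiguous bases")
    return counts / totals


def base_frequencies(seqs: Sequence[str]) -> pd.DataFrame:
    """Per-position base frequency table for equal-length sequences.

    Index is the 1-based read position; columns A, C, G, T sum to 1.
    """
    freqs = column_frequencies(encode_seqs(seqs))
    return pd.DataFrame(
        freqs, columns=list(BASES), index=pd.RangeIndex(1, freqs.shape[0] + 1, name="pos")
    )


def entropy_from_freqs(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits per row, with 0 * log 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def positional_entropy(freqs: pd.DataFrame, atol: float = 1e-6) -> np.ndarray:
    """Per-position entropy in bits from a frequency table.

    Columns must sum to 1 within ``atol`` or a validation error is raised.
    """
    p = np.asarray(freqs[list(BASES)], dtype=float)
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > atol):
        raise ValueError("frequency columns must sum to 1")
    return entropy_from_freqs(p)


def logo_matrix(
    freqs: pd.DataFrame,
    n_reads: int | None = None,
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Per-position, per-base logo letter heights.

    Total height per position is R = 2 - H, minus the small-sample
    correction e_n = 3 / (2 ln 2 n) when enabled (clamped at 0); each base's
    height is R * P_base.
    """
    H = positional_entropy(freqs)
    correction = 0.0
    if small_sample_correction:
        if not n_reads or n_reads <= 0:
            raise ValueError("small-sample correction requires n_reads > 0")
        correction = 3.0 / (2.0 * math.log(2.0) * n_reads)
    R = np.clip(2.0 - H - correction, 0.0, None)
    return freqs[list(BASES)].mul(R, axis=0)


def subsample_reads(reads: Sequence, n: int = LOGO_SAMPLE_SIZE, seed: int = 0) -> list:
    """Uniform sample of ``n`` reads without replacement (input order kept).

    If the input is smaller than ``n`` all reads are returned with a
    warning. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(reads) <= n:
        if len(reads) < n:
            log.warning("subsample_reads: only %d reads available (< %d)", len(reads), n)
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def orient_reads(
    reads: Sequence[MappedRead], signature_mode: bool = False
) -> list[str]:
    """Sequences ready for profiling.

    5' reads pass through as sequenced. 3' reads are profiled as sequenced
    for ordinary logos; with ``signature_mode=True`` (the cutter-signature
    summary) they are reverse-complemented. Mixed end types are an error.
    """
    end_types = {r.end_type for r in reads}
    if len(end_types) > 1:
        raise ValueError(f"mixed end types in read set: {sorted(end_types)}")
    if signature_mode and end_types == {"3p"}:
        return [revcomp(r.seq) for r in reads]
    return [r.seq for r in reads]


def profile_sequences(
    seqs: Sequence[str],
    small_sample_correction: bool = False,
) -> PositionProfile:
    """Full positional profile (frequencies, entropy, logo) of a read set."""
    freqs = base_frequencies(seqs)
    entropy = positional_entropy(freqs)
    heights = logo_matrix(freqs, n_reads=len(seqs),
                          small_sample_correction=small_sample_correction)
    return PositionProfile(
        window_len=freqs.shape[0],
        freqs=freqs,
        entropy=entropy,
        logo_heights=heights,
        n_reads=len(seqs),
    )


def profile_reads(
    reads: Sequence[MappedRead],
    signature_mode: bool = False,
    small_sample_correction: bool = False,
) -> PositionProfile:
    """Profile a mapped-read set (one end type), orienting 3' reads per
    ``signature_mode``."""
    return profile_sequences(
        orient_reads(reads, signature_mode=signature_mode),
        small_sample_correction=small_sample_correction,
    )


def plot_logo(profile: PositionProfile, ax=None, path=None):
    """Best-effort logo rendering with stacked matplotlib bars."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, profile.window_len / 6), 2.5))
    bottom = np.zeros(profile.window_len)
    pos = np.asarray(profile.logo_heights.index)
    for base in BASES:
        h = profile.logo_heights[base].to_numpy()
        ax.bar(pos, h, bottom=bottom, color=colors[base], width=0.9, label=base)
        bottom += h
    ax.set_xlabel("read position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.legend(ncol=4, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
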