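"""Read-quality filtering, contaminant screening, and multi-mapped read
assignment.

The quality rule counts base calls with Phred quality strictly below a
threshold (default 8) and drops a read when that count exceeds a
length-dependent allowance: more than 13 such calls in a 50-mer, more than
9 in a 35-mer. Both inequalities are strict, matching the rule's wording.
Reads of other lengths use the nearest rule (>= 43 nt -> the 50-mer
allowance, else the 35-mer one) with a logged warning.

The contaminant screen is a read-prefix versus contaminant-window Hamming
scan: a read is dropped when its first 20 bases match any 20-mer window of
any contaminant sequence (either strand) with at most 2 mismatches. This
reproduces the 2-of-20 criterion without re-implementing a full mapper and
is declared as an approximation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from ._util import encode_seq, log, revcomp
from .io import MappedRead


@dataclasses.dataclass(frozen=True)
class QcPolicy:
    """Thresholds of the quality and contaminant filters."""

    low_quality_threshold: int = 8
    max_low_50mer: int = 13
    max_low_35mer: int = 9
    contaminant_word: int = 20
    contaminant_max_mismatch: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.low_quality_threshold, self.max_low_50mer,
               self.max_low_35mer, self.contaminant_word,
               self.contaminant_max_mismatch) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.contaminant_max_mismatch >= self.contaminant_word:
            raise ValueError("contaminant_max_mismatch must be < contaminant_word")


def count_low_quality(quals: Sequence[int], threshold: int = 8) -> int:
    """Number of quality values strictly below ``threshold``."""
    return sum(1 for q in quals if q < threshold)


def _allowance(read_len: int, policy: QcPolicy, warned: set) -> int:
    if read_len == 50:
        return policy.max_low_50mer
    if read_len == 35:
        return policy.max_low_35mer
    if read_len not in warned:
        warned.add(read_len)
        log.warning(
            "quality filter: read length %d uses the %s-mer rule", read_len,
            "50" if read_len >= 43 else "35",
        )
    return policy.max_low_50mer if read_len >= 43 else policy.max_low_35mer


def filter_by_quality(reads, policy: QcPolicy | None = None):
    """Partition reads into (kept, dropped) by the low-quality-count rule.

    Works on any records exposing ``quals``; order-stable.
    """
    policy = policy or QcPolicy()
    kept, dropped = [], []
    warned: set[int] = set()
    for r in reads:
        n_low = count_low_quality(r.quals, policy.low_quality_threshold)
        if n_low > _allowance(len(r.quals), policy, warned):
            dropped.append(r)
        else:
            kept.append(r)
    return kept, dropped


def _contaminant_windows(
    contaminant_seqs: Sequence[str], policy: QcPolicy
) -> np.ndarray:
    """Stack every length-``contaminant_word`` window of every contaminant,
    both strands, as an (n_windows, word) code matrix."""
    word = policy.contaminant_word
    rows = []
    for seq in contaminant_seqs:
        if len(seq) < word:
            log.warning("contaminant of length %d < word %d skipped", len(seq), word)
            continue
        for s in (seq, revcomp(seq)):
            codes = encode_seq(s)
            n_win = len(s) - word + 1
            rows.append(
                np.lib.stride_tricks.sliding_window_view(codes, word)[:n_win]
            )
    if not rows:
        return np.empty((0, word), dtype=np.uint8)
    return np.vstack(rows)


def filter_contaminants(reads, contaminant_seqs: Sequence[str],
                        policy: QcPolicy | None = None):
    """Partition reads into (kept, dropped) by the prefix-window Hamming scan.

    A read is dropped iff its first ``contaminant_word`` bases are within
    ``contaminant_max_mismatch`` mismatches of some window of some
    contaminant on either strand. Reads shorter than the word are kept.
    """
    policy = policy or QcPolicy()
    windows = _contaminant_windows(contaminant_seqs, policy)
    word = policy.contaminant_word
    kept, dropped = [], []
    for r in reads:
        if len(r.seq) < word or windows.size == 0:
            kept.append(r)
            continue
        prefix = encode_seq(r.seq[:word])
        mm = (windows != prefix[None, :]).sum(axis=1)
        if mm.min() <= policy.contaminant_max_mismatch:
            dropped.append(r)
        else:
            kept.append(r)
    return kept, dropped


def assign_multimapped(
    candidate_groups: Sequence[Sequence[MappedRead]], seed: int = 0
) -> list[MappedRead]:
    """Resolve multi-mapped reads: pick one candidate placement per read,
    uniformly at random, deterministically given ``seed``.

    Each element of ``candidate_groups`` lists the candidate placements of
    one read; the chosen record gets ``n_candidate_locations`` set to the
    group size. An empty group is a validation error.
    """
    rng = np.random.default_rng(seed)
    out: list[MappedRead] = []
    for i, group in enumerate(candidate_groups):
        if len(group) == 0:
            raise ValueError(f"read group {i} has no candidate locations")
        chosen = group[int(rng.integers(len(group)))]
        out.append(dataclasses.replace(chosen, n_candidate_locations=len(group)))
    return out


def qc_report(n_input: int, n_after_quality: int, n_after_contaminant: int) -> dict:
    """Per-stage read accounting in a JSON-friendly shape."""
    return {
        "input_reads": n_input,
        "dropped_low_quality": n_input - n_after_quality,
        "dropped_contaminant": n_after_quality - n_after_contaminant,
        "kept_reads": n_after_contaminant,
    }
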