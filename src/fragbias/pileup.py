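"""Pile-up detection: grouping of co-located identical reads, the
pile-up-to-read ratio curve, redundancy, and pile-up deduplication.

A *pile-up* is a group of mapped reads sharing the same location and — by
default — exactly the same sequence; pile-ups indicate fragment-end bias or
duplication rather than genuine coverage. The ratio curve reports, for each
minimum group size k, the fraction of all reads that belong to groups of at
least k reads; it is 1 at k = 1 by construction and non-increasing in k.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .io import MappedRead

KEY_MODES = ("position+sequence", "position")


def _read_key(read: MappedRead, key_mode: str):
    if key_mode == "position+sequence":
        return (read.ref, read.start, read.strand, read.end_type, read.seq)
    if key_mode == "position":
        return (read.ref, read.start, read.strand, read.end_type)
    raise ValueError(f"unknown key_mode {key_mode!r}; expected one of {KEY_MODES}")


@dataclasses.dataclass
class PileupTable:
    """Groups of co-located identical reads with their sizes."""

    groups: list[tuple[tuple, int]]
    total_reads: int
    key_mode: str = "position+sequence"

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.groups], dtype=int)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclasses.dataclass
class RatioCurve:
    """Pile-up-to-read ratio as a function of the minimum pile-up size k."""

    k_values: np.ndarray
    ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "ratio": self.ratio})


def group_pileups(
    reads: Sequence[MappedRead], key_mode: str = "position+sequence"
) -> PileupTable:
    """Group reads by (ref, start, strand, end_type[, seq]).

    Groups are reported in order of first occurrence and partition the
    input. Reads are assumed QC-filtered and uniquely assigned.
    """
    if key_mode not in KEY_MODES:
        raise ValueError(f"unknown key_mode {key_mode!r}; expected one of {KEY_MODES}")
    counts: dict[tuple, int] = {}
    for r in reads:
        key = _read_key(r, key_mode)
        counts[key] = counts.get(key, 0) + 1
    return PileupTable(list(counts.items()), total_reads=len(reads), key_mode=key_mode)


def ratio_curve(table: PileupTable, k_max: int = 30) -> RatioCurve:
    """ratio(k) = (reads in groups of size >= k) / total reads, k = 1..k_max."""
    if table.total_reads == 0:
        raise ValueError("ratio curve undefined for an empty table")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts = table.counts
    ks = np.arange(1, k_max + 1)
    ratios = np.array([counts[counts >= k].sum() for k in ks]) / table.total_reads
    return RatioCurve(ks, ratios)


def redundancy(table: PileupTable) -> float:
    """(redundant mapped reads) / (mapped reads): reads in excess of one
    per distinct group, divided by total reads."""
    if table.total_reads == 0:
        raise ValueError("redundancy undefined for an empty table")
    return (table.total_reads - table.n_groups) / table.total_reads


def remove_pileup_reads(
    reads: Sequence[MappedRead],
    table: PileupTable | None = None,
    min_size: int = 2,
    key_mode: str = "position+sequence",
) -> list[MappedRead]:
    """Deduplicate pile-ups: groups of >= ``min_size`` reads are reduced to
    a single representative (the lexicographically smallest read_id);
    smaller groups pass through untouched. Input order is preserved.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if table is not None:
        key_mode = table.key_mode
    members: dict[tuple, list[int]] = {}
    keys = []
    for i, r in enumerate(reads):
        key = _read_key(r, key_mode)
        keys.append(key)
        members.setdefault(key, []).append(i)
    keep_idx = set()
    for key, idxs in members.items():
        if len(idxs) >= min_size:
            keep_idx.add(min(idxs, key=lambda i: reads[i].read_id))
        else:
            keep_idx.update(idxs)
    return [r for i, r in enumerate(reads) if i in keep_idx]
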