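"""Degradome (PARE) cleavage profiling over precursor contexts.

PARE tags are uncapped transcript 5' ends; the cleavage between nucleotides
i-1 and i is recorded at index i (0-based) by summing the TP10M-normalized
abundances of all tags whose 5' nucleotide aligns exactly there.  Tags map
sense-strand only, by exact match over their full length.  As with small
RNAs, a tag matching several homologous targets contributes fully to each
target's maximum-possible profile; the unique profile keeps single-target
tags only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import RnaSequence

MIN_TAG_LEN = 18
TP10M_SCALE = 1e7


@dataclass(frozen=True)
class PareLibrary:
    sample_id: str
    tags: tuple[tuple[str, float], ...]
    total_reads: float

    def __post_init__(self):
        seqs = [t for t, _ in self.tags]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate tag sequences")
        if any(c <= 0 for _, c in self.tags):
            raise ValueError("tag counts must be positive")

    @classmethod
    def from_pairs(cls, sample_id, pairs, total_reads=None):
        pairs = tuple((str(s).upper().replace("T", "U"), float(c)) for s, c in pairs)
        if total_reads is None:
            total_reads = sum(c for _, c in pairs)
        return cls(sample_id, pairs, float(total_reads))


@dataclass
class CleavageProfile:
    """Per-position 5'-end frequencies (TP10M) for a set of targets."""

    unique: dict[str, np.ndarray]
    max_possible: dict[str, np.ndarray]

    def modal_site(self, target_id: str, which: str = "max_possible") -> int:
        """Most frequently cleaved position; ties break 5'-most."""
        arr = getattr(self, which)[target_id]
        return int(np.argmax(arr))  # argmax returns the first (5'-most) maximum


def normalize_tp10m(lib: PareLibrary) -> dict[str, float]:
    """Tag abundances in transcripts per 10 million reads."""
    if lib.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return {tag: count * TP10M_SCALE / lib.total_reads for tag, count in lib.tags}


def _starts(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def profile(lib: PareLibrary, targets: list[RnaSequence],
            min_tag_len: int = MIN_TAG_LEN) -> CleavageProfile:
    """Map tags sense-strand to each target and accumulate 5'-end frequencies."""
    if not targets:
        raise ValueError("targets must be non-empty")
    norm = normalize_tp10m(lib)
    unique = {t.id: np.zeros(len(t)) for t in targets}
    maxp = {t.id: np.zeros(len(t)) for t in targets}
    for tag, _count in lib.tags:
        if len(tag) < min_tag_len:
            continue
        placements: dict[str, list[int]] = {}
        for t in targets:
            occ = _starts(t.residues, tag)
            if occ:
                placements[t.id] = occ
        multi = len(placements) > 1
        for tid, occ in placements.items():
            for s in occ:
                maxp[tid][s] += norm[tag]
                if not multi:
                    unique[tid][s] += norm[tag]
    return CleavageProfile(unique, maxp)


def aggregate(profiles: list[CleavageProfile]) -> CleavageProfile:
    """Position-wise sum across samples ("total cleavages")."""
    if not profiles:
        raise ValueError("need at least one profile")
    ids = set(profiles[0].unique)
    for p in profiles[1:]:
        if set(p.unique) != ids:
            raise ValueError("profiles cover different target sets")
    unique = {t: sum(p.unique[t] for p in profiles) for t in ids}
    maxp = {t: sum(p.max_possible[t] for p in profiles) for t in ids}
    return CleavageProfile(unique, maxp)


def to_frame(prof: CleavageProfile) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for tid, arr in sorted(prof.max_possible.items()):
        uarr = prof.unique[tid]
        for i in range(len(arr)):
            if arr[i] or uarr[i]:
                rows.append({"target": tid, "position": i,
                             "tp10m_unique": uarr[i], "tp10m_max_possible": arr[i]})
    return pd.DataFrame.from_records(rows)
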