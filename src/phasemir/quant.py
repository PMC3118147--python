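"""Small-RNA mapping, normalization, and phased-partition quantification.

Reads map to precursors by perfect match only.  Counts are normalized to
the mean total-read scale of the sample batch ("transcripts per mean of
total reads").  A read is assigned to the partition covering >= 80% of its
nucleotides; anything below that threshold on every partition is "leak" —
abundance inconsistent with phased processing.  Two accountings are kept
per (precursor, partition): ``unique`` sums only reads matching a single
precursor; ``max_possible`` adds reads shared with paralogs at full weight
to every precursor they match.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import PartitionScheme
from .sequences import RnaSequence

Interval = tuple[int, int]
LEAK = "leak"


@dataclass(frozen=True)
class SmallRNALibrary:
    sample_id: str
    records: tuple[tuple[str, float], ...]  # (read residues, raw count)
    total_reads: float
    pre_normalized: bool = False

    def __post_init__(self):
        seqs = [r for r, _ in self.records]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate read sequences in library")
        if any(c <= 0 for _, c in self.records):
            raise ValueError("read counts must be positive")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    @classmethod
    def from_pairs(cls, sample_id, pairs, total_reads=None, pre_normalized=False):
        pairs = tuple((str(s).upper().replace("T", "U"), float(c)) for s, c in pairs)
        if total_reads is None:
            total_reads = sum(c for _, c in pairs)
        return cls(sample_id, pairs, float(total_reads), pre_normalized)


@dataclass(frozen=True)
class QuantParams:
    overlap_fraction: float = 0.8
    ratio_floor: float = 1.0

    def __post_init__(self):
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ReadPlacement:
    read: str
    precursor_id: str
    interval: Interval
    multiplicity: int          # number of distinct precursors matched
    within_weight: float       # 1/k for k placements within one precursor

    @property
    def shared(self) -> bool:
        return self.multiplicity > 1


def read_library_tsv(path, sample_id: str, total_reads: float | None = None,
                     pre_normalized: bool = False) -> SmallRNALibrary:
    """Read a two-column (sequence, count) TSV into a library."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sequence", "count"],
                     comment="#")
    return SmallRNALibrary.from_pairs(
        sample_id, list(df.itertuples(index=False, name=None)),
        total_reads=total_reads, pre_normalized=pre_normalized,
    )


def read_collapsed_fasta(path, sample_id: str,
                         total_reads: float | None = None) -> SmallRNALibrary:
    """Read collapsed-FASTA reads with headers like '>read1_x123'."""
    from Bio import SeqIO

    pairs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tag = rec.id.rsplit("_x", 1)
        if len(tag) != 2:
            raise ValueError(f"header {rec.id!r} lacks an _xCOUNT suffix")
        pairs.append((str(rec.seq), float(tag[1])))
    return SmallRNALibrary.from_pairs(sample_id, pairs, total_reads=total_reads)


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_reads(
    reads: list[str] | SmallRNALibrary, precursors: list[RnaSequence]
) -> list[ReadPlacement]:
    """All exact substring placements of each read on each precursor.

    A read hitting one precursor at several positions splits its abundance
    equally among them; multiplicity counts distinct precursors hit.
    """
    if not precursors:
        raise ValueError("precursor set must be non-empty")
    seqs = reads.records if isinstance(reads, SmallRNALibrary) else [(r, 1.0) for r in reads]
    placements: list[ReadPlacement] = []
    for read, _count in seqs:
        per_precursor: dict[str, list[int]] = {}
        for p in precursors:
            occ = _occurrences(p.residues, read)
            if occ:
                per_precursor[p.id] = occ
        mult = len(per_precursor)
        for pid, positions in per_precursor.items():
            w = 1.0 / len(positions)
            for s in positions:
                placements.append(ReadPlacement(read, pid, (s, s + len(read)), mult, w))
    return placements


def normalize(libs: list[SmallRNALibrary]) -> dict[str, float]:
    """Per-sample scale factors: mean(total_reads) / total_reads_s.

    Pre-normalized libraries get factor 1.
    """
    if not libs:
        raise ValueError("need at least one library")
    if any(l.total_reads <= 0 for l in libs):
        raise ValueError("zero total reads")
    mean_total = sum(l.total_reads for l in libs) / len(libs)
    return {
        l.sample_id: (1.0 if l.pre_normalized else mean_total / l.total_reads)
        for l in libs
    }


def assign_partition(
    interval: Interval, scheme: PartitionScheme, params: QuantParams = QuantParams()
) -> str:
    """Partition with maximal overlap if it covers >= 80% of the read, else leak.

    For a 21-nt read the threshold is ceil(0.8 * 21) = 17 overlapping nt.
    """
    s, e = interval
    read_len = e - s
    best_name, best_ov = LEAK, 0
    for name in scheme.order:
        ps, pe = scheme.intervals[name]
        ov = max(0, min(e, pe) - max(s, ps))
        if ov > best_ov:
            best_name, best_ov = name, ov
    if best_ov / read_len + 1e-12 >= params.overlap_fraction:
        return best_name
    return LEAK


def quantify(
    libs: list[SmallRNALibrary],
    precursors: list[RnaSequence],
    schemes: dict[str, PartitionScheme],
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Per-sample, per-precursor, per-partition normalized expression.

    Returns a tidy frame with columns sample, precursor, partition (the nine
    names plus 'leak'), unique, max_possible.
    """
    factors = normalize(libs)
    rows: dict[tuple[str, str, str], dict[str, float]] = {}
    for lib in libs:
        f = factors[lib.sample_id]
        counts = dict(lib.records)
        placements = map_reads(lib, precursors)
        for pl in placements:
            if pl.precursor_id not in schemes:
                continue
            part = assign_partition(pl.interval, schemes[pl.precursor_id], params)
            key = (lib.sample_id, pl.precursor_id, part)
            cell = rows.setdefault(key, {"unique": 0.0, "max_possible": 0.0})
            norm = counts[pl.read] * f * pl.within_weight
            cell["max_possible"] += norm
            if not pl.shared:
                cell["unique"] += norm
    # densify: every (sample, precursor, partition) cell, zero-filled
    records = []
    for lib in libs:
        for pid, scheme in schemes.items():
            for part in (*scheme.order, LEAK):
                cell = rows.get((lib.sample_id, pid, part), {"unique": 0.0, "max_possible": 0.0})
                records.append(
                    {"sample": lib.sample_id, "precursor": pid, "partition": part, **cell}
                )
    return pd.DataFrame.from_records(records)


def pool_group(libs: list[SmallRNALibrary], group_name: str, members: list[str],
               precursors: list[RnaSequence],
               schemes: dict[str, PartitionScheme],
               params: QuantParams = QuantParams()) -> pd.DataFrame:
    """Pooled expression for a named paralog group.

    Shared reads are counted once per group: a read matching several members
    contributes its full normalized abundance a single time, at its (unique
    per-group) partition assignment from each member averaged by placement.
    """
    factors = normalize(libs)
    member_set = set(members)
    sub = [p for p in precursors if p.id in member_set]
    rows: dict[tuple[str, str], float] = {}
    for lib in libs:
        f = factors[lib.sample_id]
        counts = dict(lib.records)
        placements = [pl for pl in map_reads(lib, sub) if pl.precursor_id in member_set]
        by_read: dict[str, list[ReadPlacement]] = {}
        for pl in placements:
            by_read.setdefault(pl.read, []).append(pl)
        for read, pls in by_read.items():
            w = 1.0 / len(pls)
            for pl in pls:
                part = assign_partition(pl.interval, schemes[pl.precursor_id], params)
                key = (lib.sample_id, part)
                rows[key] = rows.get(key, 0.0) + counts[read] * f * w
    records = [
        {"sample": s, "precursor": group_name, "partition": p, "abundance": v}
        for (s, p), v in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(records)


def ratio_mut_wt(
    expr_mut: pd.DataFrame,
    expr_wt: pd.DataFrame,
    params: QuantParams = QuantParams(),
    value: str = "max_possible",
) -> pd.DataFrame:
    """Mutant / wild-type ratio per (precursor, partition).

    Replicates (multiple samples in either frame) are averaged first.  When
    both numerator and denominator fall below the floor the ratio is 1.0
    with flag 'absent'; when only the denominator does, it is replaced by
    the floor and the ratio flagged 'floored'.
    """
    mu = expr_mut.groupby(["precursor", "partition"])[value].mean()
    wt = expr_wt.groupby(["precursor", "partition"])[value].mean()
    idx = mu.index.union(wt.index)
    out = []
    for key in idx:
        m = float(mu.get(key, 0.0))
        w = float(wt.get(key, 0.0))
        if m < params.ratio_floor and w < params.ratio_floor:
            ratio, flag = 1.0, "absent"
        elif w < params.ratio_floor:
            ratio, flag = m / params.ratio_floor, "floored"
        else:
            ratio, flag = m / w, ""
        out.append({"precursor": key[0], "partition": key[1],
                    "mut": m, "wt": w, "ratio": ratio, "flag": flag})
    return pd.DataFrame.from_records(out)


def length_class_ratio(
    libs_mut: list[SmallRNALibrary],
    libs_wt: list[SmallRNALibrary],
    bins: list[tuple[int, int]],
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Mutant / wild-type ratio of normalized total abundance per read-length
    bin (bins inclusive on both ends), with the same floor conventions."""
    for a, b in bins:
        for c, d in bins:
            if (a, b) < (c, d) and not (b < c or d < a):
                raise ValueError("length bins must be disjoint")
    factors = normalize(libs_mut + libs_wt)

    def bin_totals(libs: list[SmallRNALibrary]) -> dict[tuple[int, int], float]:
        per_sample: list[dict[tuple[int, int], float]] = []
        for lib in libs:
            f = factors[lib.sample_id]
            tot = {b: 0.0 for b in bins}
            for read, count in lib.records:
                for lo, hi in bins:
                    if lo <= len(read) <= hi:
                        tot[(lo, hi)] += count * f
            per_sample.append(tot)
        return {b: sum(t[b] for t in per_sample) / len(per_sample) for b in bins}

    mt, wt = bin_totals(libs_mut), bin_totals(libs_wt)
    rows = []
    for b in bins:
        m, w = mt[b], wt[b]
        if m < params.ratio_floor and w < params.ratio_floor:
            ratio, flag = 1.0, "absent"
        elif w < params.ratio_floor:
            ratio, flag = m / params.ratio_floor, "floored"
        else:
            ratio, flag = m / w, ""
        rows.append({"bin": f"{b[0]}-{b[1]}", "mut": m, "wt": w, "ratio": ratio, "flag": flag})
    return pd.DataFrame.from_records(rows)
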