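"""RNA sequence container and plain-text sequence I/O.

All sequences are held 5'->3' over the RNA alphabet {A, C, G, U}; DNA input
is normalized on read (T -> U). Coordinates everywhere in the package are
0-based, half-open intervals on the given strand.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_RNA = set("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_residues(text: str, allow_n: bool = False) -> str:
    """Uppercase, T->U; reject anything outside the RNA alphabet."""
    s = text.strip().upper().replace("T", "U")
    allowed = _RNA | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")
    if not s:
        raise ValueError("empty sequence")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA sequence.

    ``allow_n`` permits N (never-matching ambiguity code) for homology-scan
    targets such as EST/GSS records; precursors must be N-free.
    """

    id: str
    residues: str

    def __init__(self, id: str, residues: str, allow_n: bool = False):
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "residues", normalize_residues(residues, allow_n))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def reverse_complement(self) -> "RnaSequence":
        rc = self.residues.translate(_COMPLEMENT)[::-1]
        return RnaSequence(self.id + "_rc", rc, allow_n=True)


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, allow_n: bool = False) -> list[RnaSequence]:
    return [
        RnaSequence(rec.id, str(rec.seq), allow_n=allow_n)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_vienna(path: str | Path) -> Iterator[tuple[RnaSequence, str]]:
    """Read Vienna-style records: '>id', sequence line, dot-bracket line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected FASTA header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines) + 0 and i + 2 > len(lines):
            raise ValueError(f"truncated record {name!r}")
        seq = RnaSequence(name, lines[i + 1])
        db = lines[i + 2].split()[0]
        if len(db) != len(seq):
            raise ValueError(f"structure length mismatch for {name!r}")
        yield seq, db
        i += 3


def write_vienna(records: Iterable[tuple[RnaSequence, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq, db in records:
            fh.write(f">{seq.id}\n{seq.residues}\n{db}\n")
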