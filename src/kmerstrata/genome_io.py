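"""Reading, sanitising and slicing genome sequences.

Sequences live in memory as uppercase strings over {A,C,G,T,N}.  All
coordinates are 0-based, half-open; interval tables follow BED.
Multi-chromosome assemblies are kept as ordered collections and are never
concatenated, so no k-mer window ever spans a chromosome junction.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._encoding import seq_to_codes


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: an id and its residues (uppercase ACGTN)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        seq_to_codes(self.residues)  # validates the alphabet
        if not self.residues.isupper() and self.residues:
            object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GenomeSet:
    """Ordered collection of sequences, order preserved from the input."""

    sequences: list[GenomeSequence] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> GenomeSet:
    """Read a (optionally gzip-compressed) FASTA file into a GenomeSet.

    Soft-masked lowercase residues are uppercased; any character outside
    {A,C,G,T,N,a,c,g,t,n} raises ValueError naming the record and offset.
    """
    out = GenomeSet()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            try:
                out.sequences.append(GenomeSequence(id=rec.id, residues=seq))
            except ValueError as exc:
                raise ValueError(f"record {rec.id!r}: {exc}") from None
    if not out.sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(genomes: GenomeSet | Iterable[GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    seqs = genomes.sequences if isinstance(genomes, GenomeSet) else list(genomes)
    with open(path, "w") as fh:
        for g in seqs:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.residues[i:i + width] + "\n")


def validate_intervals(intervals: Sequence[tuple[int, int]], length: int) -> None:
    prev_end = 0
    for start, end in intervals:
        if not (0 <= start < end <= length):
            raise ValueError(f"interval [{start},{end}) out of range for length {length}")
        if start < prev_end:
            raise ValueError(f"interval [{start},{end}) overlaps or is unsorted")
        prev_end = end


def excise_intervals(g: GenomeSequence,
                     intervals: Sequence[tuple[int, int]]) -> GenomeSet:
    """Remove sorted, non-overlapping [start,end) spans from a sequence.

    The complement segments are returned as separate sequences so that
    downstream counting never creates chimeric k-mers across an excision
    junction.  Removing everything yields an empty set (with a warning).
    """
    intervals = sorted(intervals)
    validate_intervals(intervals, g.length)
    segments: list[GenomeSequence] = []
    cursor = 0
    for start, end in intervals:
        if start > cursor:
            segments.append(
                GenomeSequence(id=f"{g.id}:{cursor}-{start}",
                               residues=g.residues[cursor:start]))
        cursor = end
    if cursor < g.length:
        segments.append(
            GenomeSequence(id=f"{g.id}:{cursor}-{g.length}",
                           residues=g.residues[cursor:g.length]))
    if not segments:
        warnings.warn(f"excision removed the whole of sequence {g.id!r}")
    return GenomeSet(sequences=segments)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], comment="#")
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
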