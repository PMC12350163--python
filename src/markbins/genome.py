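"""Genome assemblies: ordered named sequences with lengths and optional nucleotides.

All coordinates in this package are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GenomeAssembly:
    """Ordered set of named sequences.

    Nucleotide strings are optional; they are required only for mappability
    computation. Lengths are always available.
    """

    names: list[str]
    lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("sequence names must be unique")
        for name in self.names:
            length = self.lengths.get(name)
            if length is None or length <= 0:
                raise ValueError(f"sequence {name!r} must have a positive length")
            if self.sequences is not None:
                seq = self.sequences.get(name)
                if seq is None or len(seq) != length:
                    raise ValueError(
                        f"sequence {name!r}: nucleotide string does not match "
                        f"declared length {length}"
                    )

    @property
    def has_sequences(self) -> bool:
        return self.sequences is not None

    @property
    def total_length(self) -> int:
        return sum(self.lengths[n] for n in self.names)

    def __len__(self) -> int:
        return len(self.names)


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Load a genome from a FASTA file (sequences kept in memory)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        names.append(record.id)
        sequences[record.id] = str(record.seq).upper()
        lengths[record.id] = len(record.seq)
    if not names:
        raise ValueError(f"no sequences found in {path}")
    return GenomeAssembly(names=names, lengths=lengths, sequences=sequences)


def write_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    if not assembly.has_sequences:
        raise ValueError("assembly carries no nucleotide sequences")
    records = [
        SeqRecord(Seq(assembly.sequences[name]), id=name, description="")
        for name in assembly.names
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Load a two-column name<TAB>length table (UCSC chrom.sizes)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed chrom.sizes line: {line!r}")
            names.append(fields[0])
            lengths[fields[0]] = int(fields[1])
    if not names:
        raise ValueError(f"no sequences found in {path}")
    return GenomeAssembly(names=names, lengths=lengths)


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in assembly.names:
            handle.write(f"{name}\t{assembly.lengths[name]}\n")
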