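"""Genome sequences as an ordered set of named chromosomes.

Sequences are held in memory upper-cased (soft-masking is ignored for
digestion purposes).  Unplaced scaffolds are expected to be excluded by
the caller before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

__all__ = ["GenomeSequence"]


@dataclass
class GenomeSequence:
    """Ordered, named chromosome sequences with length bookkeeping.

    ``genome_id`` tags every derived cut-site index so that pre-computed
    digests of one assembly are never combined with another.
    """

    genome_id: str
    _sequences: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self._sequences:
            raise ValueError("genome has no chromosomes")
        for name, seq in self._sequences.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} is empty")
        self._sequences = {n: s.upper() for n, s in self._sequences.items()}

    @classmethod
    def from_dict(cls, genome_id: str, sequences: Mapping[str, str]) -> "GenomeSequence":
        return cls(genome_id=genome_id, _sequences=dict(sequences))

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None) -> "GenomeSequence":
        """Read a (multi-record, line-wrapped) FASTA file.

        ``genome_id`` defaults to the file stem.
        """
        path = Path(path)
        sequences: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate chromosome name {record.id!r} in {path}")
            sequences[record.id] = str(record.seq)
        if not sequences:
            raise ValueError(f"no FASTA records in {path}")
        return cls(genome_id=genome_id or path.stem, _sequences=sequences)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._sequences)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._sequences.values())

    def sequence(self, chrom: str) -> str:
        try:
            return self._sequences[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome {self.genome_id!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        """Write the genome as wrapped FASTA (deterministic byte output)."""
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self._sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
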