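"""In silico genome digestion: IUPAC motif scanning and cut-site indices.

Coordinates are 0-based: a cut at coordinate ``c`` severs the bond between
positions ``c - 1`` and ``c``, i.e. ``c`` is the first base after the
top-strand cut.  Fragment boundaries use the top-strand cut only; the
few-bp shift introduced by sticky-end overhangs is far below the size-
selection error modelled downstream and is absorbed into it.

A motif that equals its own IUPAC reverse complement (set-wise, e.g.
``CCGG`` or ``WCCGGW``) is scanned on one strand only, since every
bottom-strand match coincides with a top-strand match.  Non-palindromic
motifs are additionally scanned as their reverse complement, with the cut
coordinate mirrored within the motif.

Genome ``N`` (assembly gap) satisfies only the pattern letter ``N``:
a motif is never asserted inside a gap run, which would otherwise plant
phantom cut sites.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

from .catalog import IUPAC_SETS, EnzymeSpec, IsoschizomerFamily
from .genome import GenomeSequence

__all__ = [
    "CutSiteIndex",
    "iupac_match",
    "iupac_reverse_complement",
    "is_palindromic",
    "scan_cut_sites",
    "digest_genome",
    "write_precomputed",
    "read_precomputed",
    "merge_cut_indices",
    "write_cut_sites_bed",
    "PrecomputedFormatError",
]

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class PrecomputedFormatError(ValueError):
    """Pre-computed cut-site file is malformed or belongs to another run."""


def iupac_reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC motif (degeneracy sets are preserved)."""
    try:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(motif.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in motif {motif!r}") from None


def is_palindromic(motif: str) -> bool:
    """True if the motif equals its IUPAC reverse complement set-wise.

    Each IUPAC letter denotes a unique base set, so string equality with
    the reverse complement is exactly set-wise identity.
    """
    motif = motif.upper()
    return motif == iupac_reverse_complement(motif)


def iupac_match(pattern: str, window: str) -> bool:
    """Does ``window`` (over A/C/G/T/N) satisfy the IUPAC ``pattern``?

    A window base matches iff it belongs to the degeneracy set of the
    corresponding pattern letter; a genome ``N`` matches only the pattern
    letter ``N``.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    for p, w in zip(pattern.upper(), window.upper()):
        if w not in "ACGTN":
            raise ValueError(f"window base {w!r} is not one of A/C/G/T/N")
        if p == "N":
            continue
        if w == "N" or w not in IUPAC_SETS[p]:
            return False
    return True


def _motif_regex(motif: str) -> re.Pattern[str]:
    # Lookahead so overlapping matches are all reported.
    classes = []
    for letter in motif.upper():
        bases = "".join(sorted(IUPAC_SETS[letter]))
        if letter == "N":
            bases += "N"
        classes.append(f"[{bases}]" if len(bases) > 1 else bases)
    return re.compile("(?=" + "".join(classes) + ")")


def scan_cut_sites(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """All top-strand cut coordinates of ``enzyme`` in ``seq``.

    Every motif match starting at ``m`` yields a cut at ``m + cut_offset``;
    for non-palindromic motifs the reverse-complement motif is also
    scanned, a match at ``m`` yielding ``m + (len(motif) - cut_offset)``.
    The result is sorted and deduplicated; overlapping matches all count.
    """
    seq = seq.upper()
    motif = enzyme.recognition_motif
    cuts = {
        m.start() + enzyme.cut_offset for m in _motif_regex(motif).finditer(seq)
    }
    if not is_palindromic(motif):
        rc = iupac_reverse_complement(motif)
        mirror = len(motif) - enzyme.cut_offset
        cuts.update(
            m.start() + mirror for m in _motif_regex(rc).finditer(seq)
        )
    return sorted(cuts)


@dataclass
class CutSiteIndex:
    """Per-chromosome sorted cut coordinates for one enzyme family.

    ``cuts`` maps chromosome name to a strictly increasing list of 0-based
    coordinates.  ``genome_id`` records the assembly digested, so indices
    from different genomes are never merged.
    """

    genome_id: str
    family_id: str
    cuts: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, coords in self.cuts.items():
            coords = sorted(set(int(c) for c in coords))
            if coords and coords[0] < 0:
                raise ValueError(f"{chrom}: negative cut coordinate {coords[0]}")
            self.cuts[chrom] = coords

    @property
    def n_cuts(self) -> int:
        return sum(len(v) for v in self.cuts.values())


def digest_genome(genome: GenomeSequence, family: IsoschizomerFamily) -> CutSiteIndex:
    """Digest every chromosome with the family representative.

    Any family member would produce the same index (shared motif and
    offset); only the representative is scanned to avoid redundant work.
    """
    enzyme = family.representative
    cuts = {
        chrom: scan_cut_sites(genome.sequence(chrom), enzyme)
        for chrom in genome.chrom_names
    }
    return CutSiteIndex(genome_id=genome.genome_id, family_id=family.family_id, cuts=cuts)


def write_precomputed(index: CutSiteIndex, path: str | Path, motif: str = "",
                      cut_offset: int | None = None) -> None:
    """Write a cut-site index as a gzip-compressed text file.

    Header lines start with ``#`` and record genome_id, family_id and (if
    given) motif and offset; records are ``chrom<TAB>coordinate`` sorted
    by chromosome then coordinate.
    """
    path = Path(path)
    with gzip.open(path, "wt") as fh:
        fh.write(f"#genome_id={index.genome_id}\n")
        fh.write(f"#family_id={index.family_id}\n")
        if motif:
            fh.write(f"#motif={motif}\n")
        if cut_offset is not None:
            fh.write(f"#cut_offset={cut_offset}\n")
        for chrom in sorted(index.cuts):
            for coord in index.cuts[chrom]:
                fh.write(f"{chrom}\t{coord}\n")


def read_precomputed(path: str | Path, expect_genome_id: str | None = None) -> CutSiteIndex:
    """Read a pre-computed cut-site file, validating header and sortedness.

    If ``expect_genome_id`` is given and does not match the file header,
    loading is refused — mixing digests of different assemblies silently
    corrupts every downstream quantity.
    """
    path = Path(path)
    header: dict[str, str] = {}
    cuts: dict[str, list[int]] = {}
    with gzip.open(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PrecomputedFormatError(
                    f"{path} line {line_no}: expected 'chrom<TAB>coordinate'"
                )
            chrom, coord_s = parts
            try:
                coord = int(coord_s)
            except ValueError:
                raise PrecomputedFormatError(
                    f"{path} line {line_no}: non-integer coordinate {coord_s!r}"
                ) from None
            lst = cuts.setdefault(chrom, [])
            if lst and coord <= lst[-1]:
                raise PrecomputedFormatError(
                    f"{path} line {line_no}: coordinates not strictly increasing "
                    f"for {chrom}"
                )
            lst.append(coord)
    for key in ("genome_id", "family_id"):
        if key not in header:
            raise PrecomputedFormatError(f"{path}: missing #{key}= header line")
    if expect_genome_id is not None and header["genome_id"] != expect_genome_id:
        raise PrecomputedFormatError(
            f"{path}: pre-computed for genome {header['genome_id']!r}, "
            f"refusing to load into a run for {expect_genome_id!r}"
        )
    return CutSiteIndex(genome_id=header["genome_id"],
                        family_id=header["family_id"], cuts=cuts)


def merge_cut_indices(a: CutSiteIndex, b: CutSiteIndex) -> CutSiteIndex:
    """Sorted, deduplicated union of two indices over the same genome.

    Models a double digestion: the fragment set of an enzyme pair is
    defined by the union of both enzymes' cut sites.
    """
    if a.genome_id != b.genome_id:
        raise ValueError(
            f"cannot merge cut indices from different genomes "
            f"({a.genome_id!r} vs {b.genome_id!r})"
        )
    chroms = set(a.cuts) | set(b.cuts)
    merged = {
        chrom: sorted(set(a.cuts.get(chrom, [])) | set(b.cuts.get(chrom, [])))
        for chrom in chroms
    }
    return CutSiteIndex(
        genome_id=a.genome_id,
        family_id=f"{a.family_id}+{b.family_id}",
        cuts=merged,
    )


def write_cut_sites_bed(index: CutSiteIndex, path: str | Path) -> None:
    """Export cut sites as 1-bp BED intervals (0-based half-open) for inspection."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(index.cuts):
            for coord in index.cuts[chrom]:
                fh.write(f"{chrom}\t{coord}\t{coord + 1}\t{index.family_id}\n")
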