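"""Seeded synthetic genomes, enzyme catalogs and site sets with ground truth.

The generator builds toy genomes in which the planted recognition motifs
are the *only* occurrences of those motifs: the random background is
rejection-cleaned of every planted motif (and its reverse complement)
before the motifs are written in at recorded positions.  Digesting such
a genome must therefore return exactly the planted cut coordinates,
which makes every downstream quantity (fragments, NF, recovered sites)
analytically known.

All generation is driven by a single integer seed; the same seed yields
byte-identical FASTA output.  These genomes have uniform base
composition and no CpG islands, repeats or assembly gaps — they exercise
the machinery, not the biology of real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import EnzymeSpec, IsoschizomerFamily
from .digestion import _motif_regex, is_palindromic, iupac_reverse_complement
from .fragmentation import SiteOfInterest, SizeRange
from .genome import GenomeSequence

__all__ = [
    "FixtureSpec",
    "StandardFixture",
    "generate_genome",
    "generate_sites",
    "standard_fixture",
    "mini_catalog",
    "FIXTURE_VERSION",
]

#: Bumped whenever the generation algorithm changes, so that regenerated
#: fixtures remain comparable across package versions.
FIXTURE_VERSION = "1"

_BASES = np.array(list("ACGT"))

#: Placement classes for generated sites and the recovery indicator each
#: implies for the declared (size range, read length) pair.
PLACEMENTS = (
    "in-fragment-near-end",   # in an in-range fragment, within r of an end -> 1
    "in-fragment-center",     # in an in-range fragment, > r from both ends -> 0
    "terminal-fragment",      # before the first / after the last cut      -> 0
    "outside",                # in an internal fragment outside the range  -> 0
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic genome with planted motifs.

    ``planted_motifs`` maps each IUPAC motif to the top-strand start
    positions where it is written, per chromosome.  Chromosomes are
    named ``chr1 .. chrN`` and all have ``genome_length`` bp.
    """

    seed: int
    genome_length: int
    n_chroms: int = 1
    planted_motifs: Mapping[str, Mapping[str, Sequence[int]]] = field(
        default_factory=dict
    )
    genome_id: str = "synthetic"

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


class FixtureError(ValueError):
    """The requested fixture cannot be constructed (e.g. motif overlap)."""


def _clean_background(seq: np.ndarray, motifs: Sequence[str],
                      rng: np.random.Generator, max_rounds: int = 200) -> None:
    """Re-randomise every spontaneous motif occurrence until none remain."""
    patterns = []
    for motif in motifs:
        patterns.append((_motif_regex(motif), len(motif)))
        if not is_palindromic(motif):
            rc = iupac_reverse_complement(motif)
            patterns.append((_motif_regex(rc), len(rc)))
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for pattern, width in patterns:
            for m in pattern.finditer(text):
                seq[m.start() : m.start() + width] = rng.choice(
                    _BASES, size=width
                )
                dirty = True
        if not dirty:
            return
    raise FixtureError(
        "could not clean the background of planted motifs; motif density too high"
    )


def _concretise(motif: str, rng: np.random.Generator) -> str:
    """Pick one concrete A/C/G/T realisation of an IUPAC motif."""
    from .catalog import IUPAC_SETS

    return "".join(
        b if b in "ACGT" else rng.choice(sorted(IUPAC_SETS[b]))
        for b in motif.upper()
    )


def generate_genome(spec: FixtureSpec) -> tuple[GenomeSequence, dict[str, dict[str, list[int]]]]:
    """Build the genome and return it with the ground-truth match starts.

    The returned truth maps ``motif -> chrom -> sorted top-strand match
    start positions``; for an enzyme with that motif and cut offset
    ``o``, the expected cut coordinates are exactly ``start + o``.

    Raises :class:`FixtureError` if planted motifs overlap, run off a
    chromosome end, or if planting creates additional matches at the
    junctions (the spec is then unrealisable as stated).
    """
    rng = np.random.default_rng(spec.seed)
    motifs = sorted(spec.planted_motifs)
    sequences: dict[str, str] = {}
    occupied_by_chrom: dict[str, list[tuple[int, int]]] = {}

    for chrom in spec.chrom_names():
        seq = rng.choice(_BASES, size=spec.genome_length)
        if motifs:
            _clean_background(seq, motifs, rng)
        occupied: list[tuple[int, int]] = []
        for motif in motifs:
            for pos in sorted(spec.planted_motifs[motif].get(chrom, [])):
                end = pos + len(motif)
                if pos < 0 or end > spec.genome_length:
                    raise FixtureError(
                        f"motif {motif} at {chrom}:{pos} runs off the chromosome"
                    )
                for s, e in occupied:
                    if pos < e and s < end:
                        raise FixtureError(
                            f"planted motifs overlap at {chrom}:{pos}"
                        )
                occupied.append((pos, end))
                seq[pos:end] = list(_concretise(motif, rng))
        occupied_by_chrom[chrom] = occupied
        sequences[chrom] = "".join(seq)

    genome = GenomeSequence.from_dict(spec.genome_id, sequences)

    # The ground truth is derived by scanning the finished sequence: one
    # planted motif may legitimately contain another (CCCGGG nests CCGG),
    # so a match is valid iff it overlaps a planted interval.  A match in
    # cleaned background, a planted position that failed to match, or any
    # bottom-strand match of a non-palindromic motif means the spec is
    # unrealisable and must fail loudly rather than shift the truth.
    truth: dict[str, dict[str, list[int]]] = {m: {} for m in motifs}
    for motif in motifs:
        top = _motif_regex(motif)
        bottom = None if is_palindromic(motif) else _motif_regex(
            iupac_reverse_complement(motif)
        )
        width = len(motif)
        for chrom in spec.chrom_names():
            occupied = occupied_by_chrom[chrom]
            found = sorted(m.start() for m in top.finditer(sequences[chrom]))
            stray = [
                p for p in found
                if not any(p < e and s < p + width for s, e in occupied)
            ]
            planted = set(spec.planted_motifs[motif].get(chrom, []))
            missing = planted - set(found)
            if bottom is not None:
                stray += [m.start() for m in bottom.finditer(sequences[chrom])]
            if stray or missing:
                raise FixtureError(
                    f"planting {motif} on {chrom} produced unexpected matches "
                    f"(stray {sorted(stray)[:5]}, missing {sorted(missing)[:5]})"
                )
            truth[motif][chrom] = found
    return genome, truth


def generate_sites(
    cuts_by_chrom: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    size_range: SizeRange,
    read_length: int,
    counts: Mapping[str, int],
    seed: int,
    weight: float = 1.0,
) -> tuple[list[SiteOfInterest], pd.DataFrame]:
    """Place sites in the given placement classes with known recovery.

    ``cuts_by_chrom`` are the ground-truth cut coordinates of the
    digestion under test; fragments are the stretches between
    consecutive cuts.  ``counts`` maps placement class (see
    :data:`PLACEMENTS`) to the number of sites wanted.  Returns the
    sites and an expectation table with columns ``site_id, chrom, coord,
    placement, expected_gamma`` valid for exactly the declared
    ``(size_range, read_length)`` pair.
    """
    bad = set(counts) - set(PLACEMENTS)
    if bad:
        raise ValueError(f"unknown placement classes: {sorted(bad)}")
    rng = np.random.default_rng(seed)

    in_range: list[tuple[str, int, int]] = []
    out_of_range: list[tuple[str, int, int]] = []
    terminal: list[tuple[str, int, int]] = []
    for chrom in sorted(cuts_by_chrom):
        cuts = sorted(cuts_by_chrom[chrom])
        length = chrom_lengths[chrom]
        if cuts:
            if cuts[0] > 0:
                terminal.append((chrom, 0, cuts[0]))
            if cuts[-1] < length:
                terminal.append((chrom, cuts[-1], length))
        else:
            terminal.append((chrom, 0, length))
        for s, e in zip(cuts, cuts[1:]):
            (in_range if size_range.contains(e - s) else out_of_range).append(
                (chrom, s, e)
            )

    def pick(pool: list[tuple[str, int, int]], k: int, where: str,
             cls: str) -> list[tuple[str, int]]:
        coords: list[tuple[str, int]] = []
        candidates = []
        for chrom, s, e in pool:
            if where == "near-end":
                span = min(read_length, e - s)
                candidates.extend((chrom, c) for c in range(s, s + span))
            elif where == "center":
                lo, hi = s + read_length, e - read_length
                candidates.extend((chrom, c) for c in range(lo, hi))
            else:  # anywhere
                candidates.extend((chrom, c) for c in range(s, e))
        if len(candidates) < k:
            raise FixtureError(
                f"cannot place {k} sites of class {cls!r}: only "
                f"{len(candidates)} eligible positions"
            )
        idx = rng.choice(len(candidates), size=k, replace=False)
        coords.extend(candidates[i] for i in sorted(idx))
        return coords

    placed: list[tuple[str, int, str, int]] = []  # chrom, coord, class, gamma
    for cls in PLACEMENTS:
        k = counts.get(cls, 0)
        if k == 0:
            continue
        if cls == "in-fragment-near-end":
            coords = pick(in_range, k, "near-end", cls)
            gamma = 1
        elif cls == "in-fragment-center":
            pool = [(c, s, e) for c, s, e in in_range if e - s > 2 * read_length]
            coords = pick(pool, k, "center", cls)
            gamma = 0
        elif cls == "terminal-fragment":
            coords = pick(terminal, k, "anywhere", cls)
            gamma = 0
        else:  # outside
            coords = pick(out_of_range, k, "anywhere", cls)
            gamma = 0
        placed.extend((chrom, coord, cls, gamma) for chrom, coord in coords)

    seen: set[tuple[str, int]] = set()
    sites: list[SiteOfInterest] = []
    rows = []
    for chrom, coord, cls, gamma in placed:
        if (chrom, coord) in seen:
            continue  # collisions across classes are vanishingly rare; drop
        seen.add((chrom, coord))
        site_id = f"{chrom}:{coord + 1}"
        sites.append(SiteOfInterest(site_id, chrom, coord, weight))
        rows.append(
            {
                "site_id": site_id,
                "chrom": chrom,
                "coord": coord,
                "placement": cls,
                "expected_gamma": gamma,
            }
        )
    return sites, pd.DataFrame(rows)


def mini_catalog() -> list[IsoschizomerFamily]:
    """A three-family catalog: MspI/HpaII, TaqI and XmaI.

    MspI (C^CGG) and TaqI (T^CGA) are the classic frequent 4-cutters of
    reduced-representation protocols; XmaI (C^CCGGG) is a rarer
    6-cutter.  HpaII shares MspI's motif and offset but is CpG-sensitive,
    exercising the representative-selection rule.
    """
    mspi = EnzymeSpec("MspI", "CCGG", 1, sensitive_cpg=False)
    hpaii = EnzymeSpec("HpaII", "CCGG", 1, sensitive_cpg=True)
    taqi = EnzymeSpec("TaqI", "TCGA", 1, sensitive_cpg=False)
    xmai = EnzymeSpec("XmaI", "CCCGGG", 1, sensitive_cpg=False)
    return [
        IsoschizomerFamily("fam_MspI", (mspi, hpaii), representative=mspi),
        IsoschizomerFamily("fam_TaqI", (taqi,)),
        IsoschizomerFamily("fam_XmaI", (xmai,)),
    ]


@dataclass
class StandardFixture:
    """A complete seeded test scene: genome, catalog, sites and truth."""

    genome: GenomeSequence
    catalog: list[IsoschizomerFamily]
    sites: list[SiteOfInterest]
    truth: dict[str, dict[str, list[int]]]


def standard_fixture(
    seed: int,
    chrom_length: int = 75_000,
    n_chroms: int = 2,
    n_sites: int = 50,
) -> StandardFixture:
    """A ~150 kb two-chromosome scene with the mini catalog and 50 sites.

    Motifs are planted at gridded, non-overlapping positions; sites of
    interest are scattered close to planted MspI/TaqI cut sites, so that
    single digests and the pair all recover non-trivial site subsets.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]

    def plant(n_per_chrom: int, lane: int) -> dict[str, list[int]]:
        # Lanes keep different motifs on disjoint position grids (step 16
        # exceeds every motif length), so planted motifs never overlap.
        out = {}
        for chrom in chroms:
            grid = np.arange(200 + 16 * lane, chrom_length - 200, 48)
            out[chrom] = sorted(
                int(p) for p in rng.choice(grid, size=n_per_chrom, replace=False)
            )
        return out

    planted = {
        "CCGG": plant(60, 0),
        "TCGA": plant(45, 1),
        "CCCGGG": plant(12, 2),
    }
    spec = FixtureSpec(
        seed=seed,
        genome_length=chrom_length,
        n_chroms=n_chroms,
        planted_motifs=planted,
        genome_id=f"synthfix{seed}",
    )
    genome, truth = generate_genome(spec)

    # Sites near MspI or TaqI cut coordinates (cut = match start + 1).
    anchors = []
    for motif in ("CCGG", "TCGA"):
        for chrom in chroms:
            anchors.extend((chrom, p + 1) for p in truth[motif][chrom])
    idx = rng.choice(len(anchors), size=n_sites, replace=False)
    sites = []
    seen: set[tuple[str, int]] = set()
    for i in sorted(idx):
        chrom, cut = anchors[i]
        coord = cut + int(rng.integers(1, 40))
        while (chrom, coord) in seen:
            coord += 1
        seen.add((chrom, coord))
        sites.append(SiteOfInterest(f"{chrom}:{coord + 1}", chrom, coord, 1.0))
    return StandardFixture(genome=genome, catalog=mini_catalog(),
                           sites=sites, truth=truth)
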