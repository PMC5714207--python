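"""Fragments, size selection and the site-recovery indicator.

A digestion with cuts ``[c1 .. ck]`` on a chromosome yields the internal
fragments ``[c1, c2), [c2, c3), ...``.  Chromosome-terminal stretches are
excluded: an RRBS library fragment needs two enzyme-generated ends for
adapter ligation, so a stretch bounded by a chromosome end is never
sequenced.

Size selection keeps fragments whose length lies in the inclusive window
``[a, a + b]`` (``a``: lower limit, ``b``: breadth), mimicking gel
excision.  A site of interest is *recovered* (indicator gamma = 1) when
it sits inside a selected fragment within one read length of either
fragment end — single-end reads of length ``r`` from both fragment ends
cover the first and last ``r`` bases only.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .digestion import CutSiteIndex
from .genome import GenomeSequence

__all__ = [
    "Fragment",
    "SizeRange",
    "SiteOfInterest",
    "build_fragments",
    "select_by_size",
    "recovered_sites",
    "read_site_annotation",
    "write_fragments_bed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment ``[start, end)`` in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeRange:
    """A size-selection window: fragment lengths in ``[lower, lower + breadth]``."""

    lower: int
    breadth: int

    def __post_init__(self) -> None:
        if self.lower < 1:
            raise ValueError(f"size-range lower limit {self.lower} must be >= 1")
        if self.breadth < 1:
            raise ValueError(f"size-range breadth {self.breadth} must be >= 1")

    @property
    def upper(self) -> int:
        return self.lower + self.breadth

    def contains(self, length: int) -> bool:
        return self.lower <= length <= self.upper

    def __str__(self) -> str:
        return f"{self.lower}-{self.upper}"


@dataclass(frozen=True)
class SiteOfInterest:
    """One weighted genomic position to recover (e.g. the C of a CpG).

    ``coord`` is 0-based; annotation files on disk use 1-based positions
    and are converted on read.
    """

    site_id: str
    chrom: str
    coord: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.coord < 0:
            raise ValueError(f"site {self.site_id!r}: negative coordinate")
        if self.weight < 0:
            raise ValueError(f"site {self.site_id!r}: negative weight {self.weight}")


def build_fragments(index: CutSiteIndex, genome: GenomeSequence) -> list[Fragment]:
    """Fragments between consecutive cut sites, per chromosome.

    Chromosomes with fewer than two cuts contribute nothing; terminal
    stretches (before the first and after the last cut) are excluded.
    """
    if index.genome_id != genome.genome_id:
        raise ValueError(
            f"cut-site index is for genome {index.genome_id!r}, "
            f"not {genome.genome_id!r}"
        )
    lengths = genome.chrom_lengths
    fragments: list[Fragment] = []
    for chrom in genome.chrom_names:
        cuts = index.cuts.get(chrom, [])
        if cuts and cuts[-1] > lengths[chrom]:
            raise ValueError(
                f"cut coordinate {cuts[-1]} beyond end of {chrom} "
                f"(length {lengths[chrom]})"
            )
        fragments.extend(
            Fragment(chrom, cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)
        )
    return fragments


def select_by_size(
    fragments: Iterable[Fragment], size_range: SizeRange
) -> tuple[list[Fragment], int]:
    """Fragments whose length falls in the window, and their count NF."""
    selected = [f for f in fragments if size_range.contains(f.length)]
    return selected, len(selected)


def recovered_sites(
    selected: Sequence[Fragment],
    sites: Sequence[SiteOfInterest],
    read_length: int,
) -> tuple[np.ndarray, list[str]]:
    """Per-site recovery indicator gamma and the recovered site IDs.

    ``gamma[i] = 1`` iff some selected fragment ``[s, e)`` contains the
    site (``s <= coord < e``) and the site lies in the first or last
    ``read_length`` bases of the fragment (``coord - s < r`` or
    ``e - coord <= r``).  Sites on chromosomes absent from the fragment
    set get gamma 0 with a logged warning.
    """
    if read_length < 1:
        raise ValueError(f"read length must be >= 1, got {read_length}")
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for frag in sorted(selected, key=lambda f: (f.chrom, f.start)):
        starts, ends = by_chrom.setdefault(frag.chrom, ([], []))
        starts.append(frag.start)
        ends.append(frag.end)

    gamma = np.zeros(len(sites), dtype=np.int8)
    recovered: list[str] = []
    warned: set[str] = set()
    for i, site in enumerate(sites):
        if site.chrom not in by_chrom:
            if site.chrom not in warned:
                logger.warning(
                    "site %s on chromosome %r with no selected fragments",
                    site.site_id, site.chrom,
                )
                warned.add(site.chrom)
            continue
        starts, ends = by_chrom[site.chrom]
        j = bisect_right(starts, site.coord) - 1
        if j < 0:
            continue
        s, e = starts[j], ends[j]
        if not (s <= site.coord < e):
            continue
        if (site.coord - s < read_length) or (e - site.coord <= read_length):
            gamma[i] = 1
            recovered.append(site.site_id)
    return gamma, recovered


def read_site_annotation(path: str | Path) -> list[SiteOfInterest]:
    """Read a tab-separated site annotation file.

    Columns: ``site_id, chrom, coordinate(1-based), weight``; lines
    starting with ``#`` are comments.  Coordinates are converted to
    0-based.  Site IDs must be unique.
    """
    path = Path(path)
    sites: list[SiteOfInterest] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{path} line {line_no}: expected 4 tab-separated fields "
                    f"(site_id, chrom, coordinate, weight), got {len(fields)}"
                )
            site_id, chrom, coord_s, weight_s = (f.strip() for f in fields)
            if site_id in seen:
                raise ValueError(f"{path} line {line_no}: duplicate site ID {site_id!r}")
            seen.add(site_id)
            try:
                coord_1based = int(coord_s)
                weight = float(weight_s)
            except ValueError:
                raise ValueError(
                    f"{path} line {line_no}: bad coordinate or weight"
                ) from None
            if coord_1based < 1:
                raise ValueError(
                    f"{path} line {line_no}: 1-based coordinate must be >= 1"
                )
            sites.append(SiteOfInterest(site_id, chrom, coord_1based - 1, weight))
    return sites


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Export fragments as BED (0-based half-open) for inspection."""
    with open(Path(path), "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")
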