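"""Restriction-enzyme catalog: isoschizomer families and methylation sensitivity.

Restriction enzymes that recognise the same motif and cut at the same
offset produce identical fragment length distributions and are therefore
interchangeable for digestion prediction.  Such enzymes are grouped into
*isoschizomer families*; only one member per family (the representative)
is ever digested with.

Each enzyme carries three methylation-sensitivity flags, one per cytosine
context (CpG, CHG, CHH).  A bisulfite protocol must use an enzyme whose
cutting does not depend on the methylation state being measured, so
families are filtered to those containing at least one member that is
insensitive in every context relevant to the experiment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EnzymeSpec",
    "IsoschizomerFamily",
    "CatalogError",
    "parse_enzyme_annotation",
    "filter_families",
    "IUPAC_SETS",
]

#: Degeneracy sets of the 15-letter IUPAC nucleotide alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Methylation contexts recognised by the sensitivity filter.
CONTEXTS = ("CpG", "CHG", "CHH")

_BOOL_WORDS = {
    "yes": True,
    "no": False,
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "sensitive": True,
    "insensitive": False,
}


class CatalogError(ValueError):
    """Malformed or inconsistent enzyme annotation."""


@dataclass(frozen=True)
class EnzymeSpec:
    """One restriction enzyme: IUPAC recognition motif and top-strand cut offset.

    ``cut_offset`` counts the bases 5' of the top-strand cut within the
    motif, so MspI (C^CGG) has motif ``CCGG`` and offset 1.  Only Type
    IIP-style enzymes making a single double-strand cut inside the motif
    are supported (1 <= offset <= motif length); enzymes cleaving at two
    positions per recognition event cannot be expressed and are rejected
    at parse time.
    """

    name: str
    recognition_motif: str
    cut_offset: int
    sensitive_cpg: bool = False
    sensitive_chg: bool = False
    sensitive_chh: bool = False

    def __post_init__(self) -> None:
        motif = self.recognition_motif.upper()
        object.__setattr__(self, "recognition_motif", motif)
        if not motif:
            raise CatalogError(f"enzyme {self.name!r}: empty recognition motif")
        bad = set(motif) - set(IUPAC_SETS)
        if bad:
            raise CatalogError(
                f"enzyme {self.name!r}: motif {motif!r} contains non-IUPAC "
                f"characters {sorted(bad)}"
            )
        if not (1 <= self.cut_offset <= len(motif)):
            raise CatalogError(
                f"enzyme {self.name!r}: cut offset {self.cut_offset} outside "
                f"[1, {len(motif)}]"
            )

    def insensitive_in(self, contexts: Iterable[str]) -> bool:
        """True if this enzyme is methylation-insensitive in every given context."""
        flags = {
            "CpG": self.sensitive_cpg,
            "CHG": self.sensitive_chg,
            "CHH": self.sensitive_chh,
        }
        for ctx in contexts:
            if ctx not in flags:
                raise ValueError(f"unknown methylation context {ctx!r}")
            if flags[ctx]:
                return False
        return True


@dataclass
class IsoschizomerFamily:
    """A group of enzymes sharing one recognition motif and cut offset.

    ``members`` are kept in lexicographic name order; ``representative``
    defaults to the first member and is the enzyme actually used for
    digestion.  Any member would give the identical cut-site index.
    """

    family_id: str
    members: tuple[EnzymeSpec, ...]
    representative: EnzymeSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.members:
            raise CatalogError(f"family {self.family_id!r} has no members")
        members = tuple(sorted(self.members, key=lambda e: e.name))
        object.__setattr__(self, "members", members)
        motifs = {e.recognition_motif for e in members}
        offsets = {e.cut_offset for e in members}
        if len(motifs) > 1:
            raise CatalogError(
                f"family {self.family_id!r}: members disagree on motif "
                f"({sorted(motifs)})"
            )
        if len(offsets) > 1:
            raise CatalogError(
                f"family {self.family_id!r}: members disagree on cut offset "
                f"({sorted(offsets)})"
            )
        if self.representative is None:
            self.representative = members[0]
        elif self.representative not in members:
            raise CatalogError(
                f"family {self.family_id!r}: representative "
                f"{self.representative.name!r} is not a member"
            )

    @property
    def recognition_motif(self) -> str:
        return self.representative.recognition_motif

    @property
    def cut_offset(self) -> int:
        return self.representative.cut_offset


def _parse_bool(token: str, line_no: int) -> bool:
    try:
        return _BOOL_WORDS[token.strip().lower()]
    except KeyError:
        raise CatalogError(
            f"line {line_no}: cannot parse {token!r} as a sensitivity flag "
            f"(expected one of {sorted(_BOOL_WORDS)})"
        ) from None


_COLUMNS = (
    "enzyme_name",
    "motif",
    "cut_offset",
    "cpg_sensitive",
    "chg_sensitive",
    "chh_sensitive",
    "family_id",
)


def parse_enzyme_annotation(path: str | Path) -> list[IsoschizomerFamily]:
    """Load an enzyme annotation file into isoschizomer families.

    The file is comma- or tab-separated text with a header line naming the
    columns ``enzyme_name, motif, cut_offset, cpg_sensitive, chg_sensitive,
    chh_sensitive, family_id``.  Lines starting with ``#`` are comments.
    Families are returned sorted by ``family_id``; within a family the
    motif and cut offset must agree.

    Raises
    ------
    CatalogError
        On a malformed line (named by line number), an out-of-bounds cut
        offset, or motif/offset disagreement within a family.
    """
    path = Path(path)
    text = path.read_text()
    return _parse_annotation_text(text, source=str(path))


def _parse_annotation_text(text: str, source: str = "<string>") -> list[IsoschizomerFamily]:
    lines = io.StringIO(text).readlines()
    data_lines: list[tuple[int, str]] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        data_lines.append((i, line))
    if not data_lines:
        raise CatalogError(f"{source}: no records found")

    header_no, header = data_lines[0]
    sep = "\t" if "\t" in header else ","
    cols = [c.strip().lower() for c in header.split(sep)]
    if cols != list(_COLUMNS):
        raise CatalogError(
            f"{source} line {header_no}: header must be "
            f"{','.join(_COLUMNS)} (comma- or tab-separated), got {cols}"
        )

    by_family: dict[str, list[EnzymeSpec]] = {}
    seen_names: set[str] = set()
    for line_no, line in data_lines[1:]:
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != len(_COLUMNS):
            raise CatalogError(
                f"{source} line {line_no}: expected {len(_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        name, motif, offset_s, cpg_s, chg_s, chh_s, family_id = fields
        try:
            offset = int(offset_s)
        except ValueError:
            raise CatalogError(
                f"{source} line {line_no}: cut offset {offset_s!r} is not an integer"
            ) from None
        try:
            enzyme = EnzymeSpec(
                name=name,
                recognition_motif=motif,
                cut_offset=offset,
                sensitive_cpg=_parse_bool(cpg_s, line_no),
                sensitive_chg=_parse_bool(chg_s, line_no),
                sensitive_chh=_parse_bool(chh_s, line_no),
            )
        except CatalogError as exc:
            raise CatalogError(f"{source} line {line_no}: {exc}") from None
        if name in seen_names:
            raise CatalogError(f"{source} line {line_no}: duplicate enzyme name {name!r}")
        seen_names.add(name)
        by_family.setdefault(family_id, []).append(enzyme)

    families = [
        IsoschizomerFamily(family_id=fid, members=tuple(members))
        for fid, members in sorted(by_family.items())
    ]
    return families


def filter_families(
    families: Sequence[IsoschizomerFamily],
    contexts: Iterable[str],
) -> list[IsoschizomerFamily]:
    """Keep families with at least one enzyme insensitive in every context.

    The representative of each retained family is recomputed as the
    lexicographically first member that qualifies, so downstream digestion
    never uses a methylation-sensitive member.  Returns a (possibly empty)
    list; an empty result is the caller's problem, not an error.
    """
    contexts = tuple(contexts)
    if not contexts:
        raise ValueError("at least one methylation context is required")
    kept: list[IsoschizomerFamily] = []
    for fam in families:
        qualifying = [e for e in fam.members if e.insensitive_in(contexts)]
        if not qualifying:
            continue
        kept.append(
            IsoschizomerFamily(
                family_id=fam.family_id,
                members=fam.members,
                representative=qualifying[0],
            )
        )
    return kept
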