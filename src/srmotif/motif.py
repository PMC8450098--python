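"""Data model of the sarcin/ricin motif and isostericity classification.

The motif is represented on a fixed 13-position template: positions 1-7
are the left strand 5'->3', positions 8-13 the right strand 5'->3'.  The
basepair slots and their Leontis-Westhof families are invariant across
variants; only the sequence changes:

    cWW(1,13)  flanking Watson-Crick pair
    tSH(2,12)  "lower" trans Sugar/Hoogsteen pair
    tHH(3,11)  trans Hoogsteen/Hoogsteen pair
    cSH(4,5)   bulged base to triple-U pair
    tWH(5,10)  trans Watson-Crick/Hoogsteen pair (triple)
    tHS(6,9)   "upper" trans Hoogsteen/Sugar (sheared) pair
    cWW(7,8)   flanking Watson-Crick pair

Substitutions at non-Watson-Crick slots are classified against bundled
isostericity matrices: isosteric substitutions preserve the 3D geometry
of the motif, non-isosteric ones distort it, and combinations that never
form the family at all ("forbidden") are predicted to disrupt the motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

__all__ = [
    "BasePairFamily",
    "IsoCell",
    "Slot",
    "SLOTS",
    "SRMotifVariant",
    "PROTOTYPE",
    "classify_pair",
    "classify_substitution",
    "variant_name",
    "parse_variant_name",
    "motif_report",
]

_BASES = "ACGU"
_EDGES = {"W", "H", "S"}


@dataclass(frozen=True)
class BasePairFamily:
    """A Leontis-Westhof basepair family: two edges plus an orientation.

    ``tHS(x, y)`` denotes x pairing through its Hoogsteen edge with the
    Sugar edge of y; reversing the member order swaps the edge labels,
    so tHS(x, y) is the same physical family as tSH(y, x).
    """

    edges: tuple
    orientation: str  # "cis" | "trans"

    def __post_init__(self):
        if len(self.edges) != 2 or not set(self.edges) <= _EDGES:
            raise ValueError("edges must be an ordered pair from {W,H,S}; "
                             "got %r" % (self.edges,))
        if self.orientation not in ("cis", "trans"):
            raise ValueError("orientation must be 'cis' or 'trans'; got %r"
                             % self.orientation)

    @classmethod
    def from_tag(cls, tag: str) -> "BasePairFamily":
        m = re.fullmatch(r"([ct])([WHS])([WHS])", tag)
        if not m:
            raise ValueError("malformed family tag %r (expected e.g. "
                             "'cWW', 'tHS')" % tag)
        orient = "cis" if m.group(1) == "c" else "trans"
        return cls(edges=(m.group(2), m.group(3)), orientation=orient)

    @property
    def tag(self) -> str:
        return self.orientation[0] + self.edges[0] + self.edges[1]

    def reversed(self) -> "BasePairFamily":
        return BasePairFamily(edges=(self.edges[1], self.edges[0]),
                              orientation=self.orientation)

    @property
    def symmetric(self) -> bool:
        return self.edges[0] == self.edges[1]


@dataclass(frozen=True)
class IsoCell:
    """One isostericity-matrix cell: the pair's group and annotations."""

    groups: frozenset          # e.g. {"i1"} or {"i1", "i2"} for combined
    near: bool = False         # near-isosteric to the stated group
    modeled: bool = False      # modeled interaction, not yet observed

    @property
    def label(self) -> str:
        core = "/".join(sorted(self.groups))
        if self.near:
            return "near:" + core
        if self.modeled:
            return "modeled:" + core
        return core


def _parse_cell(text: str) -> Optional[IsoCell]:
    if text == "-":
        return None
    near = modeled = False
    if text.startswith("near:"):
        near, text = True, text[5:]
    elif text.startswith("modeled:"):
        modeled, text = True, text[8:]
    groups = frozenset(text.split("/"))
    if not all(re.fullmatch(r"i[1-6]", g) for g in groups):
        raise ValueError("malformed isostericity cell %r" % text)
    return IsoCell(groups=groups, near=near, modeled=modeled)


def parse_isostericity_matrices(text: str) -> dict:
    """Parse the plain-text matrix file into {family tag: 4x4 dict}."""
    matrices: dict = {}
    current = None
    rows_seen = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = re.fullmatch(r"\[([ct][WHS][WHS])\]", line)
        if m:
            current = m.group(1)
            matrices[current] = {}
            rows_seen = 0
            continue
        if current is None:
            raise ValueError("cell data before any [family] header")
        cells = line.split("\t")
        if cells[0] == ".":
            if cells[1:] != list(_BASES):
                raise ValueError("column header must be A C G U")
            continue
        row_base, values = cells[0], cells[1:]
        if row_base not in _BASES or len(values) != 4:
            raise ValueError("malformed matrix row %r" % raw)
        for col_base, value in zip(_BASES, values):
            matrices[current][(row_base, col_base)] = _parse_cell(value)
        rows_seen += 1
    for tag, table in matrices.items():
        if len(table) != 16:
            raise ValueError("family %s has %d cells, expected 16"
                             % (tag, len(table)))
        fam = BasePairFamily.from_tag(tag)
        if fam.symmetric:
            for (b1, b2), cell in table.items():
                if cell != table[(b2, b1)]:
                    raise ValueError("symmetric family %s has asymmetric "
                                     "cells at %s-%s" % (tag, b1, b2))
    return matrices


def _load_bundled_matrices() -> dict:
    text = (resources.files("srmotif.data") / "isostericity_sr.txt"
            ).read_text()
    return parse_isostericity_matrices(text)


_MATRICES = _load_bundled_matrices()


def _as_family(family) -> BasePairFamily:
    if isinstance(family, BasePairFamily):
        return family
    return BasePairFamily.from_tag(str(family))


def classify_pair(family, b1: str, b2: str,
                  matrices: Optional[dict] = None) -> Optional[IsoCell]:
    """Look up the isostericity cell for (b1, b2) in the given family.

    Returns ``None`` when the combination does not form the family
    ("not a pair").  Member order is respected: a family stored under its
    reversed tag is looked up through the transposed table, so
    ``classify_pair(tHS, x, y) == classify_pair(tSH, y, x)``.
    """
    fam = _as_family(family)
    if b1 not in _BASES or b2 not in _BASES:
        raise ValueError("bases must be A/C/G/U; got %r, %r" % (b1, b2))
    tables = _MATRICES if matrices is None else matrices
    if fam.tag in tables:
        return tables[fam.tag][(b1, b2)]
    rev = fam.reversed().tag
    if rev in tables:
        return tables[rev][(b2, b1)]
    raise KeyError("unsupported family %s: no bundled isostericity matrix"
                   % fam.tag)


def classify_substitution(family, pair_from, pair_to,
                          matrices: Optional[dict] = None) -> str:
    """Classify replacing ``pair_from`` by ``pair_to`` within a family.

    Returns one of ``"isosteric"``, ``"near_isosteric"``,
    ``"non_isosteric"`` or ``"forbidden"`` (the target combination cannot
    form the family at all).  ``pair_from`` must itself be a valid pair.
    """
    cell_from = classify_pair(family, *pair_from, matrices=matrices)
    if cell_from is None:
        raise ValueError(
            "pair_from %s-%s does not form a %s pair; cannot classify a "
            "substitution relative to a non-pair"
            % (pair_from[0], pair_from[1], _as_family(family).tag))
    cell_to = classify_pair(family, *pair_to, matrices=matrices)
    if cell_to is None:
        return "forbidden"
    if tuple(pair_from) == tuple(pair_to):
        return "isosteric"
    if cell_from.groups & cell_to.groups:
        if cell_from.near or cell_to.near:
            return "near_isosteric"
        return "isosteric"
    return "non_isosteric"


# ---------------------------------------------------------------------------
# motif template


@dataclass(frozen=True)
class Slot:
    """A fixed basepair slot of the 13-position motif template."""

    name: str
    family: BasePairFamily
    pos1: int  # 1-based template position of the first member
    pos2: int


SLOTS = (
    Slot("cWW(1,13)", BasePairFamily.from_tag("cWW"), 1, 13),
    Slot("tSH(2,12)", BasePairFamily.from_tag("tSH"), 2, 12),
    Slot("tHH(3,11)", BasePairFamily.from_tag("tHH"), 3, 11),
    Slot("cSH(4,5)", BasePairFamily.from_tag("cSH"), 4, 5),
    Slot("tWH(5,10)", BasePairFamily.from_tag("tWH"), 5, 10),
    Slot("tHS(6,9)", BasePairFamily.from_tag("tHS"), 6, 9),
    Slot("cWW(7,8)", BasePairFamily.from_tag("cWW"), 7, 8),
)


@dataclass(frozen=True)
class SRMotifVariant:
    """One 13-position motif sequence variant.

    ``sequence`` runs 5'->3' starting with the left strand: positions
    1-7 are the left strand, 8-13 the right strand.  ``slot_mask``
    restricts which slots are considered formed, for S/R-like motifs
    that lack a pair of the standard architecture; ``None`` means all.
    """

    sequence: str
    id: str = ""
    slot_mask: Optional[frozenset] = None

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 13 or not set(seq) <= set(_BASES):
            raise ValueError("motif sequence must be 13 positions over "
                             "A/C/G/U; got %r" % self.sequence)
        if self.slot_mask is not None:
            names = {s.name for s in SLOTS}
            if not set(self.slot_mask) <= names:
                raise ValueError("unknown slot names in mask: %r"
                                 % (set(self.slot_mask) - names,))

    def base(self, position: int) -> str:
        """Base at a 1-based template position."""
        if not 1 <= position <= 13:
            raise ValueError("position must be 1..13; got %d" % position)
        return self.sequence[position - 1]

    def slot_bases(self, slot: Slot) -> tuple:
        return self.base(slot.pos1), self.base(slot.pos2)

    @property
    def active_slots(self) -> tuple:
        if self.slot_mask is None:
            return SLOTS
        return tuple(s for s in SLOTS if s.name in self.slot_mask)

    @property
    def left_strand(self) -> str:
        return self.sequence[:7]

    @property
    def right_strand(self) -> str:
        return self.sequence[7:]


#: The reference motif: H95 large-subunit prototype sequence on the
#: duplex template with C1-G13 and G7-C8 flanking pairs.
PROTOTYPE = SRMotifVariant(sequence="CUAGUAGCGAACG", id="prototype")

_TOKEN_RE = re.compile(r"^([ACGU])(1[0-3]|[1-9])([ACGU])$")


def variant_name(variant: SRMotifVariant,
                 prototype: SRMotifVariant = PROTOTYPE) -> str:
    """Mutation-style name of a variant relative to a prototype.

    Tokens ``<fromBase><position><toBase>`` joined by "/" in ascending
    position order, e.g. ``"U2G/C12A"``; identical sequences give
    ``"prototype"``.
    """
    if len(variant.sequence) != len(prototype.sequence):
        raise ValueError("variant and prototype lengths differ")
    tokens = ["%s%d%s" % (p, i, v)
              for i, (p, v) in enumerate(zip(prototype.sequence,
                                             variant.sequence), start=1)
              if p != v]
    return "/".join(tokens) if tokens else "prototype"


def parse_variant_name(name: str,
                       prototype: SRMotifVariant = PROTOTYPE
                       ) -> SRMotifVariant:
    """Inverse of :func:`variant_name`.

    Each token's from-base must match the prototype at that position;
    a mismatch or malformed token raises with the offending position.
    """
    if name.strip() == "prototype":
        return SRMotifVariant(sequence=prototype.sequence, id="prototype")
    seq = list(prototype.sequence)
    for token in name.strip().split("/"):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError("malformed mutation token %r in %r"
                             % (token, name))
        from_base, pos, to_base = m.group(1), int(m.group(2)), m.group(3)
        if prototype.sequence[pos - 1] != from_base:
            raise ValueError(
                "token %r: prototype has %s at position %d, not %s"
                % (token, prototype.sequence[pos - 1], pos, from_base))
        seq[pos - 1] = to_base
    return SRMotifVariant(sequence="".join(seq), id=name.strip())


def motif_report(variant: SRMotifVariant,
                 prototype: SRMotifVariant = PROTOTYPE) -> list:
    """Per-slot classification of a variant against a prototype.

    Returns one dict per active slot with the slot name and family, the
    variant's bases, the pair's isostericity cell (or not-a-pair), the
    substitution class relative to the prototype's pair, and a
    ``disrupting`` flag for slots whose combination cannot form the
    family (predicted to abolish the motif).
    """
    rows = []
    for slot in variant.active_slots:
        b_from = prototype.slot_bases(slot)
        b_to = variant.slot_bases(slot)
        cell = classify_pair(slot.family, *b_to)
        substitution = classify_substitution(slot.family, b_from, b_to)
        rows.append({
            "slot": slot.name,
            "family": slot.family.tag,
            "bases": "%s%s" % b_to,
            "pair_class": cell.label if cell is not None else "not-a-pair",
            "substitution": substitution,
            "disrupting": cell is None,
        })
    return rows


def read_variants_tsv(text: str) -> list:
    """Parse variant definitions: ``id<TAB>left_strand<TAB>right_strand``."""
    variants = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        # duplex ids conventionally start with '#', so only tab-free
        # '#' lines are comments
        if not line or line.lower().startswith("id\t") or \
                (line.startswith("#") and "\t" not in line):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError("line %d: expected 3 tab-separated fields"
                             % lineno)
        vid, left, right = (p.strip() for p in parts)
        variants.append(SRMotifVariant(sequence=left + right, id=vid))
    return variants
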