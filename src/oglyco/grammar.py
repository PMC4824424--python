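"""Structure identifiers for mucin-type O-glycans.

A GalNAc-linked glycan is written as a compact bracketed string over a
one-letter residue alphabet, read right to left from the reducing end:

* ``T`` is the protein attachment site (Ser/Thr),
* ``V`` immediately before the final ``T`` is the protein-linked GalNAc,
* every other residue carries the linkage position on its parent
  (``2``, ``3``, ``4``, ``6`` or ``8``), optionally preceded by an anomeric
  letter (``a``/``b`` for alpha/beta), e.g. ``Lb3`` is Gal beta1-3,
* branches are enclosed in brackets; every substituent of the root GalNAc
  is written as a branch, so core 1 is ``[L3]VT`` and the disialylated
  T antigen is ``[S6][S3L3]VT``.

Residue codes: ``f`` Fuc, ``K`` Kdn, ``L`` Gal, ``N`` Neu5Gc, ``S`` Neu5Ac,
``V`` GalNAc, ``Y`` GlcNAc, ``s`` sulfate.

This module parses identifiers into residue trees, serializes trees back to
the canonical (anomeric-free) form, reports chemistry conflicts (two
substituents on one position), and translates to/from the IUPAC condensed
one-line notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "GrammarError",
    "ResidueNode",
    "ParsedGlycan",
    "parse",
    "serialize",
    "canonicalize",
    "is_valid",
    "validate_chemistry",
    "to_iupac",
    "from_iupac",
    "residue_count",
    "glcnac_count",
    "iter_identifiers",
    "RESIDUE_CODES",
    "MODIFIER_CODES",
    "STRUCTURAL_CODES",
    "LINKAGE_POSITIONS",
]

#: codes a residue node may carry
RESIDUE_CODES = frozenset("fKLNSVYs")
#: branch decorations that do not extend the oligosaccharide backbone
MODIFIER_CODES = frozenset("fs")
#: monosaccharides that build the backbone
STRUCTURAL_CODES = RESIDUE_CODES - MODIFIER_CODES
LINKAGE_POSITIONS = frozenset((2, 3, 4, 6, 8))

_UNIT_RE = re.compile(r"([fKLNSVYs])([ab]?)([23468])")


class GrammarError(ValueError):
    """Raised for strings that are not words of the identifier language.

    ``position`` is the 0-based character offset of the offending symbol.
    """

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class ResidueNode:
    """One residue of a glycan tree.

    ``linkage`` is the position on the parent residue; it is ``None`` only
    for the root GalNAc, which attaches to the protein rather than to a
    sugar.  ``anomeric`` is ``'a'``, ``'b'`` or ``None`` (unspecified).
    Children are kept sorted (descending linkage, then code) so that equal
    trees compare equal.
    """

    code: str
    linkage: Optional[int] = None
    anomeric: Optional[str] = None
    children: tuple["ResidueNode", ...] = ()

    def __post_init__(self):
        ordered = tuple(
            sorted(self.children, key=lambda c: (-(c.linkage or 0), c.code))
        )
        object.__setattr__(self, "children", ordered)

    # -- convenience ------------------------------------------------------
    def child_at(self, position: int) -> Optional["ResidueNode"]:
        for child in self.children:
            if child.linkage == position:
                return child
        return None

    def occupied_positions(self) -> set[int]:
        return {c.linkage for c in self.children if c.linkage is not None}

    def structural_children(self) -> tuple["ResidueNode", ...]:
        return tuple(c for c in self.children if c.code in STRUCTURAL_CODES)

    def modifier_children(self) -> tuple["ResidueNode", ...]:
        return tuple(c for c in self.children if c.code in MODIFIER_CODES)

    def walk(self) -> Iterator["ResidueNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass(frozen=True)
class ParsedGlycan:
    """A parsed identifier: the protein site plus an optional residue tree.

    ``root`` is the protein-linked GalNAc or ``None`` for the bare site
    ``"T"``.  ``source`` records the text the tree was parsed from.
    """

    root: Optional[ResidueNode] = None
    source: str = "T"

    def walk(self) -> Iterator[ResidueNode]:
        if self.root is not None:
            yield from self.root.walk()

    def __str__(self) -> str:  # canonical form
        return serialize(self)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_branch(text: str, start: int, end: int) -> ResidueNode:
    """Parse ``text[start:end]``, the interior of a branch or a chain.

    The rightmost residue unit is the head; bracket groups immediately to
    its left are its bracketed children and any remaining prefix is its
    linear chain child.
    """
    if start >= end:
        raise GrammarError("empty branch", start)
    m = _UNIT_RE.fullmatch(text, end - 3, end) or _UNIT_RE.fullmatch(
        text, end - 2, end
    )
    if m is None:
        raise GrammarError(
            f"expected residue unit before position {end}", max(end - 1, start)
        )
    code, anomer, digit = m.group(1), m.group(2) or None, int(m.group(3))
    pos = m.start()
    children: list[ResidueNode] = []
    # bracket groups abutting the head, right to left
    while pos > start and text[pos - 1] == "]":
        depth = 0
        i = pos - 1
        while i >= start:
            if text[i] == "]":
                depth += 1
            elif text[i] == "[":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if i < start or depth != 0:
            raise GrammarError("unbalanced brackets", pos - 1)
        children.append(_parse_branch(text, i + 1, pos - 1))
        pos = i
    if pos > start:  # linear chain child
        children.append(_parse_branch(text, start, pos))
    return ResidueNode(code, digit, anomer, tuple(children))


def parse(identifier: str) -> ParsedGlycan:
    """Parse a structure identifier into its unique residue tree.

    Raises :class:`GrammarError` (with a character offset) for unbalanced
    brackets, illegal symbols, or a missing trailing ``T``.
    """
    if not identifier:
        raise GrammarError("empty identifier", 0)
    for i, ch in enumerate(identifier):
        if ch not in "23468abfsKLNSVYT[]":
            raise GrammarError(f"illegal symbol {ch!r}", i)
    if identifier[-1] != "T":
        raise GrammarError("identifier must end in 'T'", len(identifier) - 1)
    body = identifier[:-1]
    if body == "":
        return ParsedGlycan(None, identifier)
    if body[-1] != "V":
        raise GrammarError(
            "protein-linked residue must be GalNAc ('V')", len(body) - 1
        )
    # root branches: a sequence of balanced bracket groups before the V
    pos = len(body) - 1
    children: list[ResidueNode] = []
    while pos > 0:
        if body[pos - 1] != "]":
            raise GrammarError(
                "substituents of the root GalNAc must be bracketed", pos - 1
            )
        depth = 0
        i = pos - 1
        while i >= 0:
            if body[i] == "]":
                depth += 1
            elif body[i] == "[":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if i < 0 or depth != 0:
            raise GrammarError("unbalanced brackets", pos - 1)
        children.append(_parse_branch(body, i + 1, pos - 1))
        pos = i
    root = ResidueNode("V", None, None, tuple(children))
    return ParsedGlycan(root, identifier)


# ---------------------------------------------------------------------------
# serialization (canonical form)
# ---------------------------------------------------------------------------

def _serialize_node(node: ResidueNode) -> str:
    """Serialize the subtree at ``node`` (code + linkage digit included)."""
    structural = sorted(
        node.structural_children(), key=lambda c: -(c.linkage or 0)
    )
    fucose = [c for c in node.modifier_children() if c.code == "f"]
    sulfate = [c for c in node.modifier_children() if c.code == "s"]

    linear = ""
    bracketed = structural
    if structural:
        # A 6-linked branch with structural siblings forces the fully
        # bracketed form (the I-branch convention [[Y6][Y3]L...); otherwise
        # the lowest-position child continues the chain (e.g. S3[V4]L).
        if len(structural) == 1 or all(
            (c.linkage or 0) != 6 for c in structural
        ):
            linear = _serialize_node(structural[-1])
            bracketed = structural[:-1]
    parts = [linear]
    parts += [f"[{_serialize_node(c)}]" for c in bracketed]
    parts += [f"[{c.code}{c.linkage}]" for c in fucose]
    parts += [f"[{c.code}{c.linkage}]" for c in sulfate]
    parts.append(node.code)
    if node.linkage is not None:
        parts.append(str(node.linkage))
    return "".join(parts)


def serialize(glycan: ParsedGlycan) -> str:
    """Write a residue tree in the canonical (anomeric-free) form."""
    if glycan.root is None:
        return "T"
    root = glycan.root
    arms = sorted(root.children, key=lambda c: -(c.linkage or 0))
    return "".join(f"[{_serialize_node(c)}]" for c in arms) + "VT"


def canonicalize(identifier: str) -> str:
    """Normal form of an identifier: parsed and re-serialized.

    Anomeric letters are dropped, sibling branches are ordered by
    descending linkage position left to right (so right to left reads
    ascending), and modifier branches sit innermost, adjacent to the
    residue they decorate.  Idempotent.
    """
    return serialize(parse(identifier))


def is_valid(identifier: str) -> bool:
    """True when the identifier parses and carries no chemistry conflict."""
    try:
        glycan = parse(identifier)
    except GrammarError:
        return False
    return not validate_chemistry(glycan)


# ---------------------------------------------------------------------------
# chemistry
# ---------------------------------------------------------------------------

def validate_chemistry(glycan: ParsedGlycan) -> list[str]:
    """Report conflicts: distinct substituents sharing one linkage position.

    Strings such as ``[S3][L3]VT`` are grammatical but chemically
    impossible (two residues 3-linked to one GalNAc).  A sulfate sharing a
    position label with one glycosidic substituent is not a conflict —
    the model treats sulfation as non-blocking — but two glycosidic
    substituents, or two sulfates, on one position are.  Returns a list of
    human-readable conflict descriptions; empty means feasible.  Sulfate
    leaves are also checked (a sulfate cannot itself be substituted).
    """
    conflicts: list[str] = []
    for node in glycan.walk():
        seen: dict[tuple, str] = {}
        for child in node.children:
            key = (child.linkage, child.code == "s")
            if key in seen:
                conflicts.append(
                    f"position {child.linkage} of {node.code} carries both "
                    f"{seen[key]} and {child.code}"
                )
            else:
                seen[key] = child.code
        if node.code == "s" and node.children:
            conflicts.append("sulfate must be a leaf")
    return conflicts


def residue_count(glycan: ParsedGlycan) -> int:
    """Number of residue nodes (sulfate included; the site is not counted)."""
    return sum(1 for _ in glycan.walk())


def glcnac_count(glycan: ParsedGlycan) -> int:
    """Number of GlcNAc (``Y``) residues, for the GlcNAc-limit option."""
    return sum(1 for n in glycan.walk() if n.code == "Y")


# ---------------------------------------------------------------------------
# IUPAC condensed one-line notation
# ---------------------------------------------------------------------------

_IUPAC_NAMES = {
    "f": "Fuc",
    "K": "Kdn",
    "L": "Gal",
    "N": "Neu5Gc",
    "S": "Neu5Ac",
    "V": "GalNAc",
    "Y": "GlcNAc",
}
_IUPAC_CODES = {v: k for k, v in _IUPAC_NAMES.items()}
#: anomeric carbon of the glycosidic bond
_FIRST_CARBON = {"S": 2, "K": 2, "N": 2}
_ANOMER_SYMBOL = {"a": "α", "b": "β"}
_SYMBOL_ANOMER = {v: k for k, v in _ANOMER_SYMBOL.items()}


def default_anomer(code: str, linkage: Optional[int], parent_code: str) -> str:
    """Anomeric configuration implied by the enzyme panel.

    Fucosyl- and sialyltransferases make alpha links; Gal and GlcNAc are
    beta; GalNAc is alpha except for the beta1-4 GalNAc of the Sd(a)
    synthase; the alpha3-Gal of the B antigen is the one alpha-Gal.
    """
    if code in ("f", "S", "K", "N"):
        return "a"
    if code == "Y":
        return "b"
    if code == "L":
        return "a" if (parent_code == "L" and linkage == 3) else "b"
    if code == "V":
        return "b" if linkage == 4 else "a"
    raise ValueError(f"no anomeric configuration for {code!r}")


def _iupac_node(node: ResidueNode, parent_code: str) -> str:
    if node.code == "s":
        return f"({node.linkage}S)"
    structural = sorted(
        node.structural_children(), key=lambda c: -(c.linkage or 0)
    )
    modifiers = node.modifier_children()
    linear = ""
    bracketed = list(structural)
    if structural:
        # IUPAC condensed: the lowest-position child is the main chain,
        # every other branch is parenthesized before the parent residue.
        linear = _iupac_node(structural[-1], node.code)
        bracketed = structural[:-1]
    parts = [linear]
    parts += [f"({_iupac_node(c, node.code)})" for c in bracketed]
    parts += [
        _iupac_node(c, node.code)
        for c in modifiers
        if c.code == "s"
    ]
    parts += [
        f"({_iupac_node(c, node.code)})" for c in modifiers if c.code == "f"
    ]
    anomer = node.anomeric or default_anomer(node.code, node.linkage, parent_code)
    carbon = _FIRST_CARBON.get(node.code, 1)
    parts.append(
        f"{_IUPAC_NAMES[node.code]}{_ANOMER_SYMBOL[anomer]}{carbon}-{node.linkage}"
    )
    return "".join(parts)


def to_iupac(identifier: str) -> str:
    """Translate an identifier to IUPAC condensed one-line notation.

    Sulfation is written as a parenthesized ``(3S)``/``(6S)`` prefix on the
    sulfated residue.  Anomeric configurations absent from the identifier
    are filled in from the enzyme defaults (:func:`default_anomer`).
    """
    glycan = parse(identifier)
    if glycan.root is None:
        return "Ser/Thr"
    arms = sorted(glycan.root.children, key=lambda c: -(c.linkage or 0))
    if not arms:
        return "GalNAc-Ser/Thr"
    inner = _iupac_node(arms[-1], "V") + "".join(
        f"({_iupac_node(c, 'V')})" for c in arms[:-1]
    )
    return f"{inner}GalNAc-Ser/Thr"


_IUPAC_UNIT_RE = re.compile(
    r"(Fuc|Kdn|GalNAc|GlcNAc|Gal|Neu5Gc|Neu5Ac)([αβ])([12])-([23468])"
)
_IUPAC_SULF_RE = re.compile(r"\(([2346])S\)")


def _from_iupac_chain(text: str) -> ResidueNode:
    """Parse one IUPAC chain (innermost residue last) into a subtree."""
    pos = len(text)
    m = None
    for m in _IUPAC_UNIT_RE.finditer(text):
        pass  # last match is the innermost residue
    matches = list(_IUPAC_UNIT_RE.finditer(text))
    if not matches:
        raise GrammarError(f"unknown monosaccharide token in {text!r}", 0)
    head = matches[-1]
    if head.end() != len(text):
        raise GrammarError(f"trailing text after residue: {text!r}", head.end())
    code = _IUPAC_CODES[head.group(1)]
    anomer = _SYMBOL_ANOMER[head.group(2)]
    linkage = int(head.group(4))
    children: list[ResidueNode] = []
    pos = head.start()
    # leading sulfate markers directly before the head
    while True:
        sm = _IUPAC_SULF_RE.search(text, 0, pos)
        if sm and sm.end() == pos:
            children.append(ResidueNode("s", int(sm.group(1))))
            pos = sm.start()
            continue
        break
    # parenthesized branches
    while pos > 0 and text[pos - 1] == ")":
        depth = 0
        i = pos - 1
        while i >= 0:
            if text[i] == ")":
                depth += 1
            elif text[i] == "(":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if i < 0:
            raise GrammarError("unbalanced parentheses", pos - 1)
        inner = text[i + 1 : pos - 1]
        sm = _IUPAC_SULF_RE.fullmatch(text, i, pos)
        if sm:
            children.append(ResidueNode("s", int(sm.group(1))))
        else:
            children.append(_from_iupac_chain(inner))
        pos = i
    if pos > 0:
        children.append(_from_iupac_chain(text[:pos]))
    return ResidueNode(code, linkage, anomer, tuple(children))


def from_iupac(name: str) -> str:
    """Translate an IUPAC condensed one-line name to a canonical identifier."""
    name = name.strip()
    if name in ("Ser/Thr", ""):
        return "T"
    if not name.endswith("GalNAc-Ser/Thr"):
        raise GrammarError("name must end in GalNAc-Ser/Thr", max(len(name) - 1, 0))
    body = name[: -len("GalNAc-Ser/Thr")]
    children: list[ResidueNode] = []
    pos = len(body)
    while pos > 0 and body[pos - 1] == ")":
        depth = 0
        i = pos - 1
        while i >= 0:
            if body[i] == ")":
                depth += 1
            elif body[i] == "(":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if i < 0:
            raise GrammarError("unbalanced parentheses", pos - 1)
        children.append(_from_iupac_chain(body[i + 1 : pos - 1]))
        pos = i
    if pos > 0:
        children.append(_from_iupac_chain(body[:pos]))
    root = ResidueNode("V", None, None, tuple(children))
    return serialize(ParsedGlycan(root, name))


# ---------------------------------------------------------------------------
# identifier list files
# ---------------------------------------------------------------------------

def iter_identifiers(lines) -> Iterator[str]:
    """Yield identifiers from text lines; '#' comments and blanks ignored."""
    for line in lines:
        text = line.split("#", 1)[0].strip()
        if text:
            yield text
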