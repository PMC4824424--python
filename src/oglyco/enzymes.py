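"""The 25 enzyme activities of mucin-type O-glycosylation as rewrite rules.

Each glycosyltransferase (or sulfotransferase) is a pattern-based rule: an
acceptor template bound against the glycan residue tree, plus a single
residue added at a fixed position of one matched residue.  Reversal removes
exactly that residue, so every rule is invertible and a reaction network is
a DAG in which each edge adds one residue.

Template semantics
------------------
Templates are written in the identifier shorthand (e.g. ``*[Lb4Y*T`` for a
terminal type-2 LacNAc).  Compiled to trees:

* a leading ``[`` anchors a *branch-initial* residue: all of its
  substituents must belong to the rule's tolerated-modifier set
  (by default sulfate only — sulfation never blocks the transferases),
* inner residues of a template chain may carry extra branches only from
  their tolerance set (fucose is tolerated where the sialyltransferase and
  2-fucosyltransferase chemistry demands it, e.g. sialyl-Lewis X),
* ``*`` wildcards leave the context toward the reducing end unconstrained,
* templates without wildcards are anchored at the protein-linked GalNAc.

Matching never inspects the identifier string; it binds subtree patterns on
the parsed tree, and a site only yields a product when the target position
is chemically free, so no rule can create a position conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

from .grammar import (
    MODIFIER_CODES,
    ParsedGlycan,
    ResidueNode,
    parse,
    serialize,
)

__all__ = [
    "Pattern",
    "Acceptor",
    "EnzymeRule",
    "PanelConfig",
    "default_panel",
    "panel_by_id",
    "match_sites",
    "apply_forward",
    "apply_reverse",
    "has_i_branch",
    "DONOR_BY_CODE",
]

#: nucleotide/cofactor donor for each transferred residue
DONOR_BY_CODE = {
    "V": "UDP-V",
    "L": "UDP-L",
    "Y": "UDP-Y",
    "f": "GDP-f",
    "S": "CMP-S",
    "s": "PAP-s",
}

_TOL_S = frozenset("s")
_TOL_FS = frozenset("fs")
_TOL_NONE = frozenset()


@dataclass(frozen=True)
class Pattern:
    """Constraint on one residue of an acceptor template.

    ``linkage`` of ``None`` matches any position.  ``children`` are
    required substituents (matched by position); when ``closed`` is true,
    any further substituent must carry a code in ``tol``.
    """

    code: str
    linkage: Optional[int] = None
    children: tuple["Pattern", ...] = ()
    closed: bool = True
    tol: frozenset = _TOL_S


@dataclass(frozen=True)
class Acceptor:
    """One acceptor form of a rule.

    ``anchor`` is ``"root"`` (pattern base is the protein-linked GalNAc),
    ``"any"`` (base may bind anywhere) or ``"site"`` (the bare,
    unglycosylated site).  ``target_path`` walks required-children indices
    from the base to the residue that receives the transfer; ``add`` is the
    (code, position, anomeric) of the transferred residue.
    """

    pattern: Optional[Pattern]
    add: tuple[str, int, str]
    anchor: str = "any"
    target_path: tuple[int, ...] = ()
    #: codes the matched base's parent may have (None = unconstrained);
    #: the protein-linked GalNAc counts as parent code "V"
    parent_codes: Optional[frozenset[str]] = None


@dataclass(frozen=True)
class EnzymeRule:
    """One row of the enzyme panel."""

    id: int
    short_name: str
    ec: str
    acceptors: tuple[Acceptor, ...]
    enabled: bool = True
    #: suppression by the I-branching product: "off", "global" (any
    #: I-branch in the glycan blocks the rule) or "local" (only sites on
    #: the branch below an I-branched Gal are blocked)
    i_branch_scope: str = "off"

    @property
    def donor(self) -> str:
        return DONOR_BY_CODE[self.acceptors[0].add[0]]


@dataclass(frozen=True)
class PanelConfig:
    """Switches for the documented open interpretation points.

    ``rule4_type2``: let the 2-fucosyltransferases act on type-2 chains
    (required for Lewis Y / type-2 A and B antigens).
    ``gcnt2_inhibition``: scope over which the I-branching product shuts
    down poly-LacNAc extension by rule 10 — ``"branch6"`` (default: the
    6-branch the I-branching enzyme created is a poor elongation
    substrate, so extension is blocked below it), ``"global"`` (any
    I-branch in the glycan blocks the rule), ``"local"`` (both branches
    of an I-branched Gal are blocked) or ``"off"``.
    """

    rule4_type2: bool = True
    gcnt2_inhibition: str = "branch6"


# ---------------------------------------------------------------------------
# the panel
# ---------------------------------------------------------------------------

def default_panel(config: PanelConfig | None = None) -> list[EnzymeRule]:
    """The 25 enzyme activities, ids 1-25.

    Initiation (2); core formation (5, 6, 8, 9); branching and extension
    (1, 7, 10, 12, 19); sulfation (20-22); termination (3, 4, 11, 13-18,
    23-25).
    """
    cfg = config or PanelConfig()
    P = Pattern
    rules: list[EnzymeRule] = []

    def rule(id, name, ec, *acceptors, inhibited="off"):
        rules.append(EnzymeRule(id, name, ec, tuple(acceptors), True, inhibited))

    # -- branching / extension -------------------------------------------
    rule(1, "β4Gal-T4", "2.4.1.38",
         Acceptor(P("Y"), ("L", 4, "b")))
    rule(2, "ppGalNAc-Ts", "2.4.1.41",
         Acceptor(None, ("V", 0, "a"), anchor="site"))
    rule(3, "α4Fuc-T", "2.4.1.65",
         Acceptor(P("Y", children=(P("L", 3),)), ("f", 4, "a")))
    r4_forms = [
        Acceptor(P("Y", children=(P("L", 3),), tol=_TOL_FS),
                 ("f", 2, "a"), target_path=(0,)),
        Acceptor(P("V", children=(P("L", 3),), closed=False),
                 ("f", 2, "a"), anchor="root", target_path=(0,)),
    ]
    if cfg.rule4_type2:
        r4_forms.append(
            Acceptor(P("Y", children=(P("L", 4),), tol=_TOL_FS),
                     ("f", 2, "a"), target_path=(0,)))
    rule(4, "α2Fuc-Ts", "2.4.1.69", *r4_forms)
    rule(5, "C2Gn-T", "2.4.1.102",
         Acceptor(P("V", children=(P("L", 3),), closed=False),
                  ("Y", 6, "b"), anchor="root"))
    rule(6, "C1Gal-T1", "2.4.1.122",
         Acceptor(P("V", tol=_TOL_NONE), ("L", 3, "b"), anchor="root"))
    # The equation of record shows the core-2 context, but the enzyme
    # elongates the core-1 Gal itself (extended core-1 chains are well
    # documented), so the 6-arm is left unconstrained.
    rule(7, "β3Gn-T3", "2.4.1.146",
         Acceptor(P("V", children=(P("L", 3),), closed=False),
                  ("Y", 3, "b"), anchor="root", target_path=(0,)))
    rule(8, "β3Gn-T6", "2.4.1.147",
         Acceptor(P("V", tol=_TOL_NONE), ("Y", 3, "b"), anchor="root"))
    rule(9, "C2/4Gn-T", "2.4.1.148",
         Acceptor(P("V", children=(P("Y", 3),), closed=False),
                  ("Y", 6, "b"), anchor="root"))
    rule(10, "β3Gn-T2/3/4/5/7", "2.4.1.149",
         Acceptor(P("Y", children=(P("L", 4),)), ("Y", 3, "b"),
                  target_path=(0,)),
         inhibited=cfg.gcnt2_inhibition)
    rule(11, "α3Fuc-T", "2.4.1.152",
         Acceptor(P("Y", children=(P("L", 4),)), ("f", 3, "a")))
    rule(12, "β3Gal-T5", "2.4.1.-",
         Acceptor(P("Y"), ("L", 3, "b")))

    # -- sialylation ------------------------------------------------------
    rule(13, "ST6Gal-I", "2.4.99.1",
         Acceptor(P("Y", children=(P("L", 4),)), ("S", 6, "a"),
                  target_path=(0,)))
    # Acts on the root GalNAc whatever the state of the 3-arm; the narrow
    # printed acceptors (Tn, core 1) cannot account for the sialyl-6
    # core-3 structures that the reversed simulator must deconstruct.
    rule(14, "ST6GalNAc-I", "2.4.99.3",
         Acceptor(P("V", closed=False), ("S", 6, "a"), anchor="root"))
    rule(15, "ST3Gal-I", "2.4.99.4",
         Acceptor(P("V", children=(P("L", 3),), closed=False),
                  ("S", 3, "a"), anchor="root", target_path=(0,)))
    rule(16, "ST3Gal-III/IV", "2.4.99.6",
         Acceptor(P("Y", children=(P("L", 4),), tol=_TOL_FS),
                  ("S", 3, "a"), target_path=(0,)),
         # the ST3Gal-III isoform also caps type-1 chains
         Acceptor(P("Y", children=(P("L", 3),), tol=_TOL_FS),
                  ("S", 3, "a"), target_path=(0,)))
    rule(17, "ST6GalNAc-III/IV", "2.4.99.7",
         Acceptor(P("V", children=(P("L", 3, (P("S", 3),)),), closed=False),
                  ("S", 6, "a"), anchor="root"))
    rule(18, "ST6GlcNAc-I", "2.4.99.-",
         Acceptor(P("V", children=(P("L", 3, (P("Y", 3),)),), closed=False),
                  ("S", 6, "a"), anchor="root", target_path=(0, 0)))

    # -- I-branching ------------------------------------------------------
    rule(19, "Gcnt2", "2.4.1.-",
         Acceptor(P("L", children=(P("Y", 3, (P("L", 4),)),)),
                  ("Y", 6, "b")))

    # -- sulfation --------------------------------------------------------
    rule(20, "CHST4/6", "2.8.2.-",
         Acceptor(P("Y"), ("s", 6, "")))
    # β1,3-linked Gal only: the α3-Gal of the B antigen (L on L) is not
    # a substrate of this sulfotransferase.
    rule(21, "GAL3ST2", "2.8.2.-",
         Acceptor(P("L", 3), ("s", 3, ""), parent_codes=frozenset("Y")))
    rule(22, "GAL4ST4", "2.8.2.-",
         Acceptor(P("L", 4), ("s", 3, "")))

    # -- blood-group / Sd(a) termination ---------------------------------
    rule(23, "α3Gal-T", "2.4.1.37",
         Acceptor(P("L", children=(P("f", 2),)), ("L", 3, "a")))
    rule(24, "α3GalNAc-T", "2.4.1.40",
         Acceptor(P("L", children=(P("f", 2),)), ("V", 3, "a")))
    rule(25, "β4GalNAc-T", "2.4.1.-",
         Acceptor(P("L", 4, (P("S", 3),)), ("V", 4, "b")))

    assert [r.id for r in rules] == list(range(1, 26))
    return rules


def panel_by_id(config: PanelConfig | None = None) -> dict[int, EnzymeRule]:
    return {r.id: r for r in default_panel(config)}


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def has_i_branch(glycan: ParsedGlycan) -> bool:
    """True when some Gal carries both a 3- and a 6-linked GlcNAc."""
    for node in glycan.walk():
        if node.code == "L":
            three, six = node.child_at(3), node.child_at(6)
            if three is not None and six is not None \
                    and three.code == "Y" and six.code == "Y":
                return True
    return False


def _bind(node: ResidueNode, pat: Pattern) -> bool:
    if node.code != pat.code:
        return False
    if pat.linkage is not None and node.linkage != pat.linkage:
        return False
    required_positions = set()
    for child_pat in pat.children:
        child = node.child_at(child_pat.linkage)
        if child is None or not _bind(child, child_pat):
            return False
        required_positions.add(child_pat.linkage)
    if pat.closed:
        for child in node.children:
            if child.linkage in required_positions:
                continue
            if child.code not in pat.tol:
                return False
    return True


def _walk_paths(node: ResidueNode, path=()) -> Iterator[tuple[tuple, ResidueNode]]:
    yield path, node
    for i, child in enumerate(node.children):
        yield from _walk_paths(child, path + (i,))


def _walk_paths_with_parent(node: ResidueNode, path=(), parent=None):
    yield path, node, parent
    for i, child in enumerate(node.children):
        yield from _walk_paths_with_parent(child, path + (i,), node)


def _descend(path: tuple, node: ResidueNode, pattern: Pattern,
             target_path: tuple) -> tuple[tuple, ResidueNode]:
    """Translate a pattern target path into a tree path from the root."""
    for idx in target_path:
        child_pat = pattern.children[idx]
        for i, child in enumerate(node.children):
            if child.linkage == child_pat.linkage and child.code == child_pat.code:
                path, node, pattern = path + (i,), child, child_pat
                break
    return path, node


def match_sites(rule: EnzymeRule, glycan: ParsedGlycan,
                ) -> list[tuple[tuple, Acceptor]]:
    """All (tree-path, acceptor-form) sites where the rule can act.

    The path addresses the residue receiving the transfer; a site is only
    reported when the target position is free (chemical feasibility) and,
    for an I-branch-inhibited rule, when the glycan carries no I-branch.
    """
    sites: list[tuple[tuple, Acceptor]] = []
    if rule.i_branch_scope == "global" and has_i_branch(glycan):
        return sites
    for acceptor in rule.acceptors:
        if acceptor.anchor == "site":
            if glycan.root is None:
                sites.append(((), acceptor))
            continue
        if glycan.root is None:
            continue
        if acceptor.anchor == "root":
            candidates = [((), glycan.root, None)]
        else:
            candidates = list(_walk_paths_with_parent(glycan.root))
        for path, node, parent in candidates:
            if acceptor.parent_codes is not None and (
                    parent is None
                    or parent.code not in acceptor.parent_codes):
                continue
            if not _bind(node, acceptor.pattern):
                continue
            tpath, tnode = _descend(path, node, acceptor.pattern,
                                    acceptor.target_path)
            code, position, _ = acceptor.add
            if _position_blocked(tnode, code, position):
                continue
            if rule.i_branch_scope in ("local", "branch6") and \
                    _below_i_branch(glycan.root, tpath,
                                    rule.i_branch_scope == "branch6"):
                continue
            sites.append(((tpath), acceptor))
    return sites


def _position_blocked(node: ResidueNode, code: str, position: int) -> bool:
    """Whether adding ``code`` at ``position`` would collide.

    Any substituent blocks its position: sulfation does not block the
    other transferases at *other* positions of the residue, but two
    substituents can never share one carbon.
    """
    return any(child.linkage == position for child in node.children)


def _below_i_branch(root: ResidueNode, path: tuple,
                    six_branch_only: bool = False) -> bool:
    node = root
    for i in path:
        if node.code == "L":
            three, six = node.child_at(3), node.child_at(6)
            if three is not None and six is not None \
                    and three.code == "Y" and six.code == "Y":
                if not six_branch_only or node.children[i] is six:
                    return True
        node = node.children[i]
    return False


def _add_at(node: ResidueNode, path: tuple, new: ResidueNode) -> ResidueNode:
    if not path:
        return replace(node, children=node.children + (new,))
    i = path[0]
    children = list(node.children)
    children[i] = _add_at(children[i], path[1:], new)
    return replace(node, children=tuple(children))


def _remove_at(node: ResidueNode, path: tuple) -> ResidueNode:
    if len(path) == 1:
        children = node.children[: path[0]] + node.children[path[0] + 1 :]
        return replace(node, children=children)
    i = path[0]
    children = list(node.children)
    children[i] = _remove_at(children[i], path[1:])
    return replace(node, children=tuple(children))


def _add_many(node: ResidueNode, additions: dict[tuple, tuple[str, int]],
              path: tuple = ()) -> ResidueNode:
    """Rebuild the tree with a new leaf under every addressed residue.

    All paths address the *original* tree, so the edits are made in one
    recursive pass (children re-sort on construction, which would
    invalidate index paths if the additions were applied one at a time).
    """
    children = tuple(
        _add_many(child, additions, path + (i,))
        for i, child in enumerate(node.children)
    )
    if path in additions:
        code, position = additions[path]
        children = children + (ResidueNode(code, position),)
    return replace(node, children=children)


def apply_forward(rule: EnzymeRule, glycan: ParsedGlycan,
                  multi_site: str = "per_site") -> set[str]:
    """Canonical identifiers of the products of one rule application.

    ``multi_site`` selects the policy for templates matching at several
    positions: ``"simultaneous"`` substitutes every site of an acceptor
    form at once, yielding one product per form (the split-substitute-
    reassemble behaviour of the original string-rewriting system);
    ``"per_site"`` yields one product per site.
    """
    sites = match_sites(rule, glycan)
    products: set[str] = set()
    if multi_site == "union":
        return apply_forward(rule, glycan, "per_site") | \
            apply_forward(rule, glycan, "simultaneous")
    if multi_site == "per_site":
        for path, acceptor in sites:
            if acceptor.anchor == "site":
                root = ResidueNode("V")
            else:
                root = _add_many(glycan.root, {path: acceptor.add[:2]})
            products.add(serialize(ParsedGlycan(root)))
        return products
    by_form: dict[int, list[tuple]] = {}
    forms: dict[int, Acceptor] = {}
    for path, acceptor in sites:
        by_form.setdefault(id(acceptor), []).append(path)
        forms[id(acceptor)] = acceptor
    for form_id, paths in by_form.items():
        acceptor = forms[form_id]
        if acceptor.anchor == "site":
            products.add(serialize(ParsedGlycan(ResidueNode("V"))))
            continue
        root = _add_many(glycan.root,
                         {p: acceptor.add[:2] for p in paths})
        products.add(serialize(ParsedGlycan(root)))
    return products


def apply_reverse(rule: EnzymeRule, glycan: ParsedGlycan) -> set[str]:
    """Canonical identifiers of all single-step precursors.

    A single residue is removed per reverse step, whatever the forward
    multi-site policy.  Exact inversion of per-site application:
    ``g in apply_reverse(rule, g2)`` iff
    ``g2 in apply_forward(rule, g, "per_site")``.  Only the residue the
    rule itself added can be removed, so it must be a leaf and the
    remainder must still present a valid acceptor at that site.
    """
    precursors: set[str] = set()
    if glycan.root is None:
        return precursors
    target = serialize(glycan)
    adds = {acc.add[:2] for acc in rule.acceptors}
    if ("V", 0) in adds and not glycan.root.children:
        return {"T"}
    for path, node in _walk_paths(glycan.root):
        if not path or node.children:
            continue
        if (node.code, node.linkage) not in adds:
            continue
        candidate = ParsedGlycan(_remove_at(glycan.root, path))
        if target in apply_forward(rule, candidate, "per_site"):
            precursors.add(serialize(candidate))
    return precursors
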