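"""Exports: DOT reaction graphs, SBML models and SVG glycan drawings.

DOT files are emitted as plain text (layout is left to external tools and
skipped entirely for very large networks).  SBML is written as Level 2
version 4: every glycan is a species, every reaction consumes its
nucleotide-sugar donor species.  Glycan structures are drawn in the manner
of turtle graphics, reading the identifier right to left with a stack of
saved positions for branches, using CFG-style symbols.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .enzymes import DONOR_BY_CODE, panel_by_id
from .grammar import ParsedGlycan, ResidueNode, parse
from .simulator import ReactionNetwork

__all__ = [
    "EDGE_COLORS",
    "write_dot",
    "dot_source",
    "write_sbml",
    "sbml_document",
    "render_svg",
    "svg_source",
    "DrawState",
]

#: edge colour per transferred residue
EDGE_COLORS = {
    "V": "brown",
    "L": "yellow",
    "f": "red",
    "S": "magenta",
    "Y": "blue",
    "s": "orange",
}

#: networks larger than this get no layout hints in the DOT output
_LAYOUT_LIMIT = 5000


def _transferred(rule_id: int, panel) -> str:
    return panel[rule_id].acceptors[0].add[0]


def dot_source(network: ReactionNetwork) -> str:
    """DOT text for a reaction network.

    Nodes are glycan identifiers; edges are enzyme-catalysed reactions
    colour-coded by the monosaccharide (or sulfate) being transferred.
    """
    panel = panel_by_id()
    lines = ["digraph glycans {"]
    if network.node_count <= _LAYOUT_LIMIT:
        lines.append('  rankdir="LR";')
        lines.append('  node [shape=box, fontsize=9];')
    for node in network.nodes:
        lines.append(f'  "{node}";')
    for r in network.edges:
        color = EDGE_COLORS.get(_transferred(r.enzyme_id, panel), "black")
        name = network.enzyme_names.get(r.enzyme_id, str(r.enzyme_id))
        lines.append(
            f'  "{r.substrate}" -> "{r.product}" '
            f'[color={color}, label="{name}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_dot(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write(dot_source(network))


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level2/version4"
_COFACTOR = {"UDP-V": "UDP", "UDP-L": "UDP", "UDP-Y": "UDP",
             "GDP-f": "GDP", "CMP-S": "CMP", "PAP-s": "ABP"}


def _species_id(identifier: str, ids: dict[str, str]) -> str:
    if identifier not in ids:
        ids[identifier] = f"g{len(ids) + 1}"
    return ids[identifier]


def sbml_document(network: ReactionNetwork) -> ET.ElementTree:
    """SBML Level 2 version 4 document for a reaction network."""
    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", level="2", version="4")
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", id="oglycosylation")
    lc = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{_SBML_NS}}}compartment", id="golgi", size="1")
    ls = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    ids: dict[str, str] = {}
    panel = panel_by_id()
    donors = sorted({panel[r.enzyme_id].donor for r in network.edges})
    for glycan in network.nodes:
        ET.SubElement(ls, f"{{{_SBML_NS}}}species",
                      id=_species_id(glycan, ids), name=glycan,
                      compartment="golgi", initialAmount="0")
    for donor in donors:
        for name in (donor, _COFACTOR[donor]):
            if name not in ids:
                ids[name] = f"m{len(ids) + 1}"
                ET.SubElement(ls, f"{{{_SBML_NS}}}species", id=ids[name],
                              name=name, compartment="golgi",
                              initialAmount="0",
                              boundaryCondition="true")
    lr = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for i, r in enumerate(network.edges, 1):
        donor = panel[r.enzyme_id].donor
        rx = ET.SubElement(lr, f"{{{_SBML_NS}}}reaction", id=f"r{i}",
                           name=network.enzyme_names.get(
                               r.enzyme_id, str(r.enzyme_id)),
                           reversible="false")
        lre = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        ET.SubElement(lre, f"{{{_SBML_NS}}}speciesReference",
                      species=ids[r.substrate])
        ET.SubElement(lre, f"{{{_SBML_NS}}}speciesReference",
                      species=ids[donor])
        lpr = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
        ET.SubElement(lpr, f"{{{_SBML_NS}}}speciesReference",
                      species=ids[r.product])
        ET.SubElement(lpr, f"{{{_SBML_NS}}}speciesReference",
                      species=ids[_COFACTOR[donor]])
    ET.indent(sbml)
    return ET.ElementTree(sbml)


def write_sbml(network: ReactionNetwork, path) -> None:
    sbml_document(network).write(path, xml_declaration=True,
                                 encoding="UTF-8")


# ---------------------------------------------------------------------------
# SVG drawing
# ---------------------------------------------------------------------------

@dataclass
class DrawState:
    """Turtle state while scanning an identifier right to left.

    Brackets push and pop (position, orientation) pairs; the stack is
    empty again at the end of a well-formed identifier.
    """

    x: float = 0.0
    y: float = 0.0
    angle: float = 180.0  # drawing right-to-left toward the non-reducing end
    stack: list[tuple[float, float, float]] = field(default_factory=list)

    def push(self):
        self.stack.append((self.x, self.y, self.angle))

    def pop(self):
        self.x, self.y, self.angle = self.stack.pop()


#: CFG symbol style: (shape, fill) per residue code
_GLYPHS = {
    "V": ("square", "#FFD400"),     # GalNAc: yellow square
    "L": ("circle", "#FFD400"),     # Gal: yellow circle
    "Y": ("square", "#0072BC"),     # GlcNAc: blue square
    "f": ("triangle", "#ED1C24"),   # Fuc: red triangle
    "S": ("diamond", "#A54399"),    # Neu5Ac: purple diamond
    "N": ("diamond", "#8FCCE9"),    # Neu5Gc: light blue diamond
    "K": ("diamond", "#46D1A1"),    # Kdn: green diamond
}
_STEP = 40.0
#: branch fan-out angle by linkage position
_ANGLES = {2: -50.0, 3: -35.0, 4: 0.0, 6: 35.0, 8: 50.0}


def _layout(node: ResidueNode, x: float, y: float, angle: float,
            bonds: list, glyphs: list) -> None:
    glyphs.append((node.code, node.linkage, x, y))
    children = [c for c in node.children if c.code != "s"]
    sulfates = [c for c in node.children if c.code == "s"]
    for s in sulfates:
        # small star offset: upper-left for 6-sulfation, lower-left for 3-
        dy = -14 if s.linkage == 6 else 14
        glyphs.append(("s", s.linkage, x - 14, y + dy))
    for child in children:
        a = angle + _ANGLES.get(child.linkage or 4, 0.0)
        rad = math.radians(a)
        nx, ny = x + _STEP * math.cos(rad), y + _STEP * math.sin(rad)
        bonds.append((x, y, nx, ny))
        _layout(child, nx, ny, a, bonds, glyphs)


def _glyph_svg(code: str, linkage, x: float, y: float) -> str:
    if code == "s":
        pts = []
        for i in range(10):
            r = 7 if i % 2 == 0 else 3
            a = math.pi / 2 + i * math.pi / 5
            pts.append(f"{x + r * math.cos(a):.1f},{y - r * math.sin(a):.1f}")
        return f'<polygon points="{" ".join(pts)}" fill="orange"/>'
    shape, fill = _GLYPHS[code]
    if shape == "square":
        return (f'<rect x="{x - 9:.1f}" y="{y - 9:.1f}" width="18" '
                f'height="18" fill="{fill}" stroke="black"/>')
    if shape == "circle":
        return (f'<circle cx="{x:.1f}" cy="{y:.1f}" r="9" fill="{fill}" '
                'stroke="black"/>')
    if shape == "triangle":
        return (f'<polygon points="{x:.1f},{y - 9:.1f} {x - 9:.1f},'
                f'{y + 9:.1f} {x + 9:.1f},{y + 9:.1f}" fill="{fill}" '
                'stroke="black"/>')
    return (f'<polygon points="{x:.1f},{y - 10:.1f} {x + 10:.1f},{y:.1f} '
            f'{x:.1f},{y + 10:.1f} {x - 10:.1f},{y:.1f}" fill="{fill}" '
            'stroke="black"/>')


def svg_source(identifier: str, style: str = "CFG") -> str:
    """SVG drawing of one glycan (CFG symbol style).

    Two passes: the bond framework first, then the sugar symbols, so the
    glyphs sit on top of the lines.
    """
    if style != "CFG":
        raise NotImplementedError("only the CFG symbol style is implemented")
    glycan = parse(identifier)
    bonds: list = []
    glyphs: list = []
    glyphs.append(("site", None, 0.0, 0.0))
    if glycan.root is not None:
        bonds.append((0.0, 0.0, -_STEP, 0.0))
        _layout(glycan.root, -_STEP, 0.0, 180.0, bonds, glyphs)
    xs = [g[2] for g in glyphs] + [b[0] for b in bonds] + [b[2] for b in bonds]
    ys = [g[3] for g in glyphs] + [b[1] for b in bonds] + [b[3] for b in bonds]
    pad = 24
    x0, x1 = min(xs) - pad, max(xs) + pad
    y0, y1 = min(ys) - pad, max(ys) + pad
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{x0:.0f} {y0:.0f} {x1 - x0:.0f} {y1 - y0:.0f}" '
        f'width="{x1 - x0:.0f}" height="{y1 - y0:.0f}">'
    ]
    for bx, by, ex, ey in bonds:  # first pass: bonds
        parts.append(f'<line x1="{bx:.1f}" y1="{by:.1f}" x2="{ex:.1f}" '
                     f'y2="{ey:.1f}" stroke="black"/>')
    for code, linkage, x, y in glyphs:  # second pass: symbols
        if code == "site":
            parts.append(f'<text x="{x + 6:.1f}" y="{y + 5:.1f}" '
                         'font-size="14">Ser/Thr</text>')
        else:
            parts.append(_glyph_svg(code, linkage, x, y))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_svg(identifier: str, path, style: str = "CFG") -> None:
    with open(path, "w") as fh:
        fh.write(svg_source(identifier, style))
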