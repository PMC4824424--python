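"""Iterative generation of O-glycosylation reaction networks.

Forward simulation grows a rooted DAG of glycans from a starting structure
(by default the bare protein site): at iteration *n*+1 every enabled enzyme
acts on every product first seen at iteration *n*, and each match site
contributes one product.  The run stops after a prescribed number of
iterations or at the first iteration that adds no new structure (network
closure).  The system is fully deterministic — no randomness anywhere.

Reverse ("prediction") runs use the inverted rules, removing one residue
per reaction, and declare a glycan biosynthetically predictable when the
bare site is reached, i.e. when the final step is the removal of the
protein-linked GalNAc by ppGalNAc-T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .enzymes import (
    EnzymeRule,
    PanelConfig,
    apply_forward,
    apply_reverse,
    default_panel,
)
from .grammar import ParsedGlycan, canonicalize, glcnac_count, parse

__all__ = [
    "SimulationConfig",
    "Reaction",
    "ReactionNetwork",
    "PredictionResult",
    "simulate",
    "predict",
    "forward_from_prediction",
    "format_log",
    "NetworkSizeError",
]


class NetworkSizeError(RuntimeError):
    """Raised when a run exceeds the configured node ceiling."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a forward run.

    ``glcnac_limit`` caps the number of GlcNAc residues per glycan (the
    knob that closes otherwise exponentially growing networks); ``None``
    means unlimited.  ``enabled_enzymes`` of ``None`` enables the whole
    panel.  ``max_nodes`` is a resource guard, not a model parameter.
    """

    start: str = "T"
    max_iterations: int = 8
    glcnac_limit: Optional[int] = None
    enabled_enzymes: Optional[frozenset[int]] = None
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    #: "per_site" (default) yields one product per matched site;
    #: "simultaneous" substitutes all sites of one acceptor form at once;
    #: "union" yields both
    multi_site: str = "per_site"
    max_nodes: int = 20_000_000

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a configuration from a plain mapping (e.g. parsed JSON).

        Recognised keys: start, max_iterations, glcnac_limit,
        enabled_enzymes (list of ids), multi_site, max_nodes, and the
        panel switches rule4_type2 / gcnt2_inhibition.
        """
        panel_keys = {"rule4_type2", "gcnt2_inhibition"}
        panel = PanelConfig(**{k: v for k, v in data.items() if k in panel_keys})
        kwargs = {k: v for k, v in data.items()
                  if k in ("start", "max_iterations", "glcnac_limit",
                           "multi_site", "max_nodes")}
        enabled = data.get("enabled_enzymes")
        if enabled is not None:
            kwargs["enabled_enzymes"] = frozenset(int(x) for x in enabled)
        return cls(panel_config=panel, **kwargs)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def active_rules(self) -> list[EnzymeRule]:
        panel = default_panel(self.panel_config)
        if self.enabled_enzymes is None:
            return panel
        bad = set(self.enabled_enzymes) - {r.id for r in panel}
        if bad:
            raise ValueError(f"unknown enzyme ids: {sorted(bad)}")
        return [r for r in panel if r.id in self.enabled_enzymes]


@dataclass(frozen=True)
class Reaction:
    substrate: str
    enzyme_id: int
    product: str
    iteration: int


@dataclass
class ReactionNetwork:
    """A reaction DAG: canonical identifiers with discovery serials.

    ``nodes`` maps each identifier to its serial number (1, 2, ... in
    discovery order; the starting structure has serial 0).  ``first_seen``
    records the iteration at which each node appeared.  ``closed_at`` is
    the first iteration that produced no new structure, or ``None`` if the
    run stopped at the iteration cap while still growing.
    """

    start: str
    nodes: dict[str, int] = field(default_factory=dict)
    edges: list[Reaction] = field(default_factory=list)
    first_seen: dict[str, int] = field(default_factory=dict)
    closed_at: Optional[int] = None
    enzyme_names: dict[int, str] = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def closure_iteration(self) -> Optional[int]:
        """Last iteration that produced a new structure, for closed runs.

        ``closed_at`` records the iteration at which closure was detected
        (the first to add nothing); a network reported "closed after N
        iterations" closed with ``closure_iteration == N``.
        """
        return None if self.closed_at is None else self.closed_at - 1

    @property
    def glycan_count(self) -> int:
        """Distinct glycans, not counting the bare site."""
        return len(self.nodes) - (1 if "T" in self.nodes else 0)

    def glycans(self) -> list[str]:
        return [g for g in self.nodes if g != "T"]

    def enzymes_used(self) -> frozenset[int]:
        return frozenset(r.enzyme_id for r in self.edges)

    def to_networkx(self):
        """The same DAG as a :class:`networkx.MultiDiGraph`."""
        import networkx as nx

        graph = nx.MultiDiGraph()
        for node, serial in self.nodes.items():
            graph.add_node(node, serial=serial,
                           iteration=self.first_seen[node])
        for r in self.edges:
            graph.add_edge(r.substrate, r.product, enzyme=r.enzyme_id,
                           iteration=r.iteration)
        return graph


def _run(start: str, rules: Sequence[EnzymeRule], max_iterations: int,
         step, glcnac_limit: Optional[int], max_nodes: int,
         stop_node: Optional[str] = None) -> ReactionNetwork:
    start = canonicalize(start)
    net = ReactionNetwork(start)
    net.enzyme_names = {r.id: r.short_name for r in rules}
    net.nodes[start] = 0
    net.first_seen[start] = 0
    serial = 0
    frontier = [start]
    iteration = 0
    while frontier and iteration < max_iterations:
        iteration += 1
        new_frontier: list[str] = []
        for substrate in frontier:
            tree = parse(substrate)
            for rule in rules:
                for product in sorted(step(rule, tree)):
                    if glcnac_limit is not None and \
                            glcnac_count(parse(product)) > glcnac_limit:
                        continue
                    if product not in net.nodes:
                        serial += 1
                        net.nodes[product] = serial
                        net.first_seen[product] = iteration
                        new_frontier.append(product)
                        if len(net.nodes) > max_nodes:
                            raise NetworkSizeError(
                                f"network exceeded {max_nodes} nodes at "
                                f"iteration {iteration}")
                    net.edges.append(
                        Reaction(substrate, rule.id, product, iteration))
        if not new_frontier:
            net.closed_at = iteration
            break
        frontier = new_frontier
        if stop_node is not None and stop_node in net.nodes:
            break
    return net


def simulate(config: SimulationConfig) -> ReactionNetwork:
    """Forward network generation under ``config``."""

    def step(rule, tree):
        return apply_forward(rule, tree, config.multi_site)

    return _run(config.start, config.active_rules(), config.max_iterations,
                step, config.glcnac_limit, config.max_nodes)


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of a reverse (biosynthetic-route) run.

    ``predictable`` is true iff the bare site was reached, which happens
    exactly when the last removal is GalNAc taken off the protein.
    ``iterations_used`` is the iteration at which the bare site appeared
    (or the total iterations run when not predictable); ``enzymes_used``
    collects every enzyme appearing in the reverse network.
    """

    glycan: str
    predictable: bool
    iterations_used: int
    enzymes_used: frozenset[int]
    network: ReactionNetwork

    @property
    def steps(self) -> list[Reaction]:
        return self.network.edges


def predict(glycan: str, enabled_enzymes: Optional[Iterable[int]] = None,
            max_iterations: int = 100,
            panel_config: PanelConfig | None = None) -> PredictionResult:
    """Deconstruct ``glycan`` with the reversed enzyme panel.

    Runs until the bare site is produced or an iteration adds nothing new.
    """
    rules = default_panel(panel_config)
    if enabled_enzymes is not None:
        enabled = set(enabled_enzymes)
        rules = [r for r in rules if r.id in enabled]
    net = _run(glycan, rules, max_iterations, apply_reverse, None,
               20_000_000, stop_node="T")
    predictable = "T" in net.nodes
    iterations = net.first_seen["T"] if predictable else (
        net.closed_at or max_iterations)
    return PredictionResult(canonicalize(glycan), predictable, iterations,
                            net.enzymes_used(), net)


def forward_from_prediction(prediction: PredictionResult,
                            config: SimulationConfig | None = None,
                            ) -> ReactionNetwork:
    """Forward network restricted to the enzymes a prediction used.

    The predicted glycan necessarily reappears as a node.
    """
    if not prediction.predictable:
        raise ValueError(
            f"{prediction.glycan} is not predictable; no biosynthetic "
            "route to run forward")
    base = config or SimulationConfig(
        max_iterations=prediction.iterations_used + 1)
    cfg = SimulationConfig(
        start="T",
        max_iterations=base.max_iterations,
        glcnac_limit=base.glcnac_limit,
        enabled_enzymes=prediction.enzymes_used,
        panel_config=base.panel_config,
        max_nodes=base.max_nodes,
    )
    return simulate(cfg)


def format_log(network: ReactionNetwork) -> list[str]:
    """Reaction log lines in discovery order.

    One line per reaction:
    ``<iteration no.>: <substrate> -- <enzyme> --> <product> (<serial no.>)``
    where the serial is assigned at the first appearance of the product.
    """
    names = network.enzyme_names
    lines = []
    for r in network.edges:
        name = names.get(r.enzyme_id, str(r.enzyme_id))
        lines.append(
            f"{r.iteration}: {r.substrate} -- {name} --> {r.product} "
            f"({network.nodes[r.product]})")
    return lines
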