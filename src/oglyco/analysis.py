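"""Analytics over O-glycosylation reaction networks.

Connectivity indices of the reaction DAG, local clustering, degree
statistics, classification of glycans by core type, terminal-epitope
detection from identifier substrings, and per-iteration growth series.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .grammar import ParsedGlycan, parse
from .simulator import ReactionNetwork

__all__ = [
    "NetworkIndices",
    "GrowthSeries",
    "EPITOPE_CATALOG",
    "indices",
    "clustering",
    "avg_clustering",
    "degree_stats",
    "classify_core",
    "core_counts",
    "detect_epitopes",
    "epitope_distribution",
    "epitope_combinations",
    "growth_series",
    "epitope_table",
]

#: terminal epitopes recognised as substrings of canonical identifiers
#: (anomeric-free forms)
EPITOPE_CATALOG = {
    "Lewis A": "[L3[f4]Y",
    "Lewis X": "[L4[f3]Y",
    "sialyl-Lewis A": "[S3L3[f4]Y",
    "sialyl-Lewis X": "[S3L4[f3]Y",
    "Lewis B": "[[f2]L3[f4]Y",
    "Lewis Y": "[[f2]L4[f3]Y",
    "H": "[[f2]L3Y",
    "A": "[V3[f2]L3[f4]Y",
    "B": "[L3[f2]L",
    "Sda/Cad": "[S3[V4]L",
}


# ---------------------------------------------------------------------------
# connectivity indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkIndices:
    """Connectivity measures of a reaction network.

    ``beta`` is edges per node, e/v.  ``alpha`` is the non-planar cyclomatic
    ratio: actual cycles (e - v + 1, for a connected graph) over the
    maximum possible, v(v-1)/2 - (v-1); zero for trees, one for the
    complete graph, undefined (NaN) for v < 3.  ``gamma`` is
    the edge density 2e / (v(v-1)).  ``avg_degree`` is the mean total
    degree 2e/v and ``avg_clustering`` the network mean of the local
    clustering coefficients.
    """

    v: int
    e: int
    beta: float
    alpha: float
    gamma: float
    avg_degree: float
    avg_clustering: float


def _distinct_edges(network: ReactionNetwork) -> set[tuple[str, str]]:
    return {(r.substrate, r.product) for r in network.edges}


def indices(network: ReactionNetwork) -> NetworkIndices:
    """Compute the alpha, beta and gamma indices and degree/clustering means.

    ``e`` counts distinct directed substrate->product edges (parallel
    reactions by different enzymes connect the same pair once), ``v``
    counts nodes.
    """
    v = network.node_count
    if v < 2:
        raise ValueError("indices need at least two nodes")
    edges = _distinct_edges(network)
    e = len(edges)
    beta = e / v
    max_cycles = v * (v - 1) / 2 - (v - 1)
    alpha = (e - v + 1) / max_cycles if v >= 3 and max_cycles > 0 else math.nan
    gamma = 2 * e / (v * (v - 1))
    return NetworkIndices(
        v=v, e=e, beta=beta, alpha=alpha, gamma=gamma,
        avg_degree=2 * e / v,
        avg_clustering=avg_clustering(network),
    )


def _neighbour_map(edges: set[tuple[str, str]]):
    nbrs: dict[str, set[str]] = {}
    for a, b in edges:
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)
    return nbrs


def clustering(network: ReactionNetwork, node: str) -> float:
    """Local clustering coefficient C_i = E_i / (k_i (k_i - 1)).

    k_i counts distinct neighbours (union of in- and out-neighbours) and
    E_i the directed edges among them, so the denominator is the directed
    maximum.  Nodes with fewer than two neighbours take C_i = 0.
    """
    edges = _distinct_edges(network)
    return _clustering_one(node, edges, _neighbour_map(edges))


def _clustering_one(node, edges, nbrs) -> float:
    neigh = nbrs.get(node, set())
    k = len(neigh)
    if k < 2:
        return 0.0
    e_i = sum(1 for a, b in edges if a in neigh and b in neigh)
    return e_i / (k * (k - 1))


def avg_clustering(network: ReactionNetwork) -> float:
    """Plain mean of C_i over all nodes of the network."""
    edges = _distinct_edges(network)
    nbrs = _neighbour_map(edges)
    nodes = list(network.nodes)
    if not nodes:
        return 0.0
    # local edge counting via adjacency sets keeps this O(sum k_i^2)
    out: dict[str, set[str]] = {}
    for a, b in edges:
        out.setdefault(a, set()).add(b)
    total = 0.0
    for node in nodes:
        neigh = nbrs.get(node, set())
        k = len(neigh)
        if k < 2:
            continue
        e_i = sum(1 for a in neigh for b in out.get(a, ()) if b in neigh)
        total += e_i / (k * (k - 1))
    return total / len(nodes)


def degree_stats(network: ReactionNetwork) -> dict:
    """Degree histograms and means of the reaction DAG.

    Returns in-/out-/total-degree histograms (degree -> node count) and
    the corresponding means; the mean in- and out-degrees each equal half
    the mean total degree.
    """
    edges = _distinct_edges(network)
    indeg = Counter()
    outdeg = Counter()
    for a, b in edges:
        outdeg[a] += 1
        indeg[b] += 1
    nodes = list(network.nodes)
    v = len(nodes)
    tot_hist = Counter(indeg[n] + outdeg[n] for n in nodes)
    in_hist = Counter(indeg[n] for n in nodes)
    out_hist = Counter(outdeg[n] for n in nodes)
    e = len(edges)
    return {
        "in": dict(in_hist),
        "out": dict(out_hist),
        "total": dict(tot_hist),
        "mean_in": e / v,
        "mean_out": e / v,
        "mean_total": 2 * e / v,
    }


# ---------------------------------------------------------------------------
# cores and epitopes
# ---------------------------------------------------------------------------

def classify_core(glycan: ParsedGlycan | str) -> str:
    """Core type from the root GalNAc's 3- and 6-substituents.

    Gal at 3 gives core 1 (or core 2 with a 6-linked GlcNAc); GlcNAc at 3
    gives core 3 (or core 4 with a 6-linked GlcNAc).  Everything else —
    the bare site, Tn and sialyl-Tn — is unclassified.
    """
    if isinstance(glycan, str):
        glycan = parse(glycan)
    if glycan.root is None:
        return "unclassified"
    three = glycan.root.child_at(3)
    six = glycan.root.child_at(6)
    six_is_y = six is not None and six.code == "Y"
    if three is not None and three.code == "L":
        return "core2" if six_is_y else "core1"
    if three is not None and three.code == "Y":
        return "core4" if six_is_y else "core3"
    return "unclassified"


def core_counts(network: ReactionNetwork) -> dict[str, int]:
    """Number of glycans of each core type (bare site excluded)."""
    counts = Counter(classify_core(g) for g in network.glycans())
    return {k: counts.get(k, 0)
            for k in ("core1", "core2", "core3", "core4", "unclassified")}


def detect_epitopes(identifier: str) -> set[str]:
    """Epitope labels whose patterns occur in the canonical identifier."""
    return {label for label, pattern in EPITOPE_CATALOG.items()
            if pattern in identifier}


def epitope_distribution(network: ReactionNetwork) -> dict[str, float]:
    """Percentage of glycans carrying each epitope, plus "other".

    A glycan may carry several epitopes, so rows need not sum to 100;
    "other" is the percentage carrying none.  Percentages are rounded
    half-up to one decimal.  The bare site is excluded from the
    denominator.
    """
    glycans = network.glycans()
    n = len(glycans)
    if n == 0:
        return {label: 0.0 for label in (*EPITOPE_CATALOG, "other")}
    counts = Counter()
    other = 0
    for g in glycans:
        hits = detect_epitopes(g)
        if not hits:
            other += 1
        counts.update(hits)

    def pct(x):  # round half-up to one decimal
        return math.floor(1000 * x / n + 0.5) / 10

    out = {label: pct(counts.get(label, 0)) for label in EPITOPE_CATALOG}
    out["other"] = pct(other)
    return out


def epitope_combinations(network: ReactionNetwork) -> int:
    """Number of distinct non-empty epitope-label sets across the network."""
    combos = {frozenset(detect_epitopes(g)) for g in network.glycans()}
    combos.discard(frozenset())
    return len(combos)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSeries:
    """Per-iteration counts of new and cumulative structures.

    ``growth_factor`` is b of the exponential fit nu(n) = a b^n to the
    new-structure counts (least squares on log counts, zero rows skipped);
    NaN when fewer than two positive counts exist.
    """

    iterations: tuple[int, ...]
    new_structures: tuple[int, ...]
    totals: tuple[int, ...]
    growth_factor: float


def growth_series(network: ReactionNetwork) -> GrowthSeries:
    """New-structure counts per discovery iteration and a log-linear fit."""
    per_iter = Counter(network.first_seen.values())
    per_iter.pop(0, None)  # the starting structure is not a product
    last = max(per_iter) if per_iter else 0
    its = tuple(range(1, last + 1))
    new = tuple(per_iter.get(i, 0) for i in its)
    totals = tuple(np.cumsum(new)) if new else ()
    pos = [(i, n) for i, n in zip(its, new) if n > 0]
    if len(pos) >= 2:
        x = np.array([p[0] for p in pos], float)
        y = np.log([p[1] for p in pos])
        slope, _ = np.polyfit(x, y, 1)
        b = float(np.exp(slope))
    else:
        b = math.nan
    return GrowthSeries(its, new, tuple(int(t) for t in totals), b)


# ---------------------------------------------------------------------------
# tabular emitters
# ---------------------------------------------------------------------------

def epitope_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Epitope-percentage rows (e.g. knockout name -> distribution)."""
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[*EPITOPE_CATALOG, "other"])


def core_table(network: ReactionNetwork) -> pd.DataFrame:
    counts = core_counts(network)
    return pd.DataFrame({"count": counts})


def degree_table(network: ReactionNetwork) -> pd.DataFrame:
    stats = degree_stats(network)
    degrees = sorted(set(stats["in"]) | set(stats["out"]) | set(stats["total"]))
    return pd.DataFrame(
        {kind: [stats[kind].get(d, 0) for d in degrees]
         for kind in ("in", "out", "total")},
        index=pd.Index(degrees, name="degree"))


def growth_table(network: ReactionNetwork) -> pd.DataFrame:
    gs = growth_series(network)
    return pd.DataFrame(
        {"new": gs.new_structures, "total": gs.totals},
        index=pd.Index(gs.iterations, name="iteration"))
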