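"""In-silico knockout screens and structure-prediction validation.

Single-enzyme knockouts compare a reaction network generated without one
activity against the wild-type network under the same configuration; the
validation experiment feeds experimentally determined structures to the
reversed simulator and reports the fraction it can deconstruct down to the
bare protein site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .analysis import (
    EPITOPE_CATALOG,
    NetworkIndices,
    epitope_distribution,
    indices,
)
from .grammar import GrammarError, iter_identifiers, parse
from .simulator import (
    PredictionResult,
    ReactionNetwork,
    SimulationConfig,
    predict,
    simulate,
)

__all__ = [
    "KnockoutResult",
    "ValidationReport",
    "knockout_run",
    "knockout_screen",
    "validate_structures",
    "load_validation_set",
    "TABLE3_CONFIG",
]

#: configuration of the reference single-knockout epitope screen:
#: 12 iterations with the sulfotransferases (20-22) omitted from the panel
TABLE3_CONFIG = SimulationConfig(
    max_iterations=12,
    enabled_enzymes=frozenset(range(1, 26)) - {20, 21, 22},
)


@dataclass
class KnockoutResult:
    """Comparison of a knockout network with its wild-type baseline."""

    disabled: frozenset[int]
    network: ReactionNetwork
    baseline: ReactionNetwork
    indices: Optional[NetworkIndices]
    baseline_indices: NetworkIndices
    epitopes: dict[str, float]
    missing: set[str]

    @property
    def index_deltas(self) -> dict[str, float]:
        """Wild-type minus knockout values of the connectivity indices.

        NaN when the knockout network degenerated below two nodes.
        """
        return {
            name: (getattr(self.baseline_indices, name)
                   - getattr(self.indices, name))
            if self.indices is not None else math.nan
            for name in ("beta", "alpha", "gamma", "avg_clustering")
        }

    @property
    def closure_iteration(self) -> Optional[int]:
        return self.network.closure_iteration


def _enabled(config: SimulationConfig) -> frozenset[int]:
    if config.enabled_enzymes is None:
        return frozenset(range(1, 26))
    return frozenset(config.enabled_enzymes)


def knockout_run(config: SimulationConfig, disabled: Iterable[int],
                 baseline: ReactionNetwork | None = None) -> KnockoutResult:
    """Run the simulation with ``disabled`` rules removed and compare.

    The baseline network (same configuration, nothing disabled) may be
    passed in to avoid recomputation across a screen.  Rule removal can
    only remove products, so the knockout's nodes are a subset of the
    baseline's; the difference is reported as the missing-structure set.
    """
    disabled = frozenset(disabled)
    enabled = _enabled(config)
    if not disabled <= enabled:
        raise ValueError(f"cannot disable inactive rules: {sorted(disabled - enabled)}")
    if baseline is None:
        baseline = simulate(config)
    net = simulate(
        SimulationConfig(
            start=config.start,
            max_iterations=config.max_iterations,
            glcnac_limit=config.glcnac_limit,
            enabled_enzymes=enabled - disabled,
            panel_config=config.panel_config,
            multi_site=config.multi_site,
            max_nodes=config.max_nodes,
        ))
    return KnockoutResult(
        disabled=disabled,
        network=net,
        baseline=baseline,
        indices=indices(net) if net.node_count >= 2 else None,
        baseline_indices=indices(baseline),
        epitopes=epitope_distribution(net),
        missing=set(baseline.nodes) - set(net.nodes),
    )


def knockout_screen(config: SimulationConfig = TABLE3_CONFIG,
                    rules: Sequence[int] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-knockout screen over ``rules`` (default: the enabled panel).

    Returns two frames indexed by knockout id (with a leading "wt" row in
    the epitope table): epitope percentages per knockout, and deltas of
    the connectivity indices relative to wild type.
    """
    enabled = _enabled(config)
    if rules is None:
        rules = sorted(enabled)
    baseline = simulate(config)
    epitope_rows = {"wt": epitope_distribution(baseline)}
    delta_rows = {}
    for rid in rules:
        result = knockout_run(config, {rid}, baseline=baseline)
        epitope_rows[rid] = result.epitopes
        delta_rows[rid] = result.index_deltas
    epitopes = pd.DataFrame.from_dict(
        epitope_rows, orient="index", columns=[*EPITOPE_CATALOG, "other"])
    deltas = pd.DataFrame.from_dict(delta_rows, orient="index")
    return epitopes, deltas


# ---------------------------------------------------------------------------
# structure validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of reverse-predicting a set of structure identifiers."""

    results: dict[str, PredictionResult]
    unparseable: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.results)

    @property
    def predictable(self) -> int:
        return sum(1 for r in self.results.values() if r.predictable)

    @property
    def coverage(self) -> float:
        """Percentage of parseable structures that were predicted."""
        if not self.results:
            return math.nan
        return 100.0 * self.predictable / self.total

    def not_predicted(self) -> list[str]:
        return [g for g, r in self.results.items() if not r.predictable]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictable": {g: r.predictable for g, r in self.results.items()},
                "iterations": {g: r.iterations_used for g, r in self.results.items()},
            }
        )


def validate_structures(identifiers: Iterable[str],
                        enabled_enzymes: Optional[Iterable[int]] = None,
                        panel_config=None) -> ValidationReport:
    """Reverse-predict every identifier; unparseable ones are set aside."""
    results: dict[str, PredictionResult] = {}
    bad: list[str] = []
    for ident in identifiers:
        try:
            parse(ident)
        except GrammarError:
            bad.append(ident)
            continue
        results[ident] = predict(ident, enabled_enzymes=enabled_enzymes,
                                 panel_config=panel_config)
    return ValidationReport(results, bad)


def load_validation_set() -> list[str]:
    """The packaged set of multiply-reported experimental O-glycans."""
    text = resources.files("oglyco.data").joinpath(
        "validation_glycans.txt").read_text()
    return list(iter_identifiers(text.splitlines()))
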