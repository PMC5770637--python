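"""Between-compartment tracer-flow inference by mass balance.

Given the change in % tracer recovery of each compartment over an interval,
and a directed flow topology (which compartment can pass tracer to which),
the per-edge flows are solved one node at a time: any internal node with a
single unknown incident edge determines that edge through its balance

    sum(inflows) - sum(outflows) = delta(node).

The designated residual edge (moss -> unattributed loss, interpreted as
gaseous loss) closes the system.  All flows are expressed in % of the tracer
applied; negative solved flows (e.g. upward soil transport) are reported with
a warning, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import PLANT_COMPARTMENTS

__all__ = [
    "FlowTopology",
    "FlowLedger",
    "IdentifiabilityError",
    "default_topology",
    "compartment_deltas",
    "aggregate_plant_delta",
    "infer_flows",
]

#: Nodes treated as external sources/sinks — they carry no balance equation.
EXTERNAL_NODES = ("atmosphere", "loss", "leachate")


class IdentifiabilityError(ValueError):
    """The topology cannot be solved node-by-node in a single pass."""


@dataclass(frozen=True)
class FlowTopology:
    """Directed edge list plus the designated residual-loss edge."""

    edges: tuple[tuple[str, str], ...]
    residual_edge: tuple[str, str]

    def __post_init__(self):
        if self.residual_edge not in self.edges:
            raise ValueError("residual edge must be part of the edge list")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in topology")

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a, b in self.edges:
            for n in (a, b):
                if n not in seen:
                    seen.append(n)
        return tuple(seen)

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in EXTERNAL_NODES)


def default_topology() -> FlowTopology:
    """The study's flow scheme.

    Pulse enters via the moss carpet; moss passes tracer to the O-horizon and
    to an unattributed (gaseous) loss; the soil chain O -> A -> B drains to
    leachate; plants take up N from the O-horizon and return it as litter.
    """
    return FlowTopology(
        edges=(
            ("atmosphere", "moss"),
            ("moss", "O_horizon"),
            ("moss", "loss"),
            ("O_horizon", "A_horizon"),
            ("A_horizon", "B_horizon"),
            ("B_horizon", "leachate"),
            ("O_horizon", "plants"),
            ("plants", "litter_current"),
            ("litter_current", "O_horizon"),
        ),
        residual_edge=("moss", "loss"),
    )


def compartment_deltas(
    table: pd.DataFrame,
    year_from: int,
    year_to: int,
    annualize: bool = False,
    value_column: str = "recovery_pct_mean",
) -> dict[str, float]:
    """Change in % recovery per compartment between two sampled years.

    Compartments missing either endpoint are excluded (with a warning), not
    imputed.  ``annualize`` divides by the interval length in years.
    """
    if year_to == year_from:
        span = 1.0
    else:
        span = float(year_to - year_from) if annualize else 1.0
    wide = table.pivot_table(index="compartment", columns="year", values=value_column)
    deltas: dict[str, float] = {}
    excluded = []
    for comp, row in wide.iterrows():
        if year_from not in row.index or year_to not in row.index:
            excluded.append(comp)
            continue
        a, b = row.get(year_from), row.get(year_to)
        if pd.isna(a) or pd.isna(b):
            excluded.append(comp)
            continue
        deltas[str(comp)] = float(b - a) / span
    if excluded:
        warnings.warn(
            f"compartments without both endpoint years, excluded: {sorted(excluded)}",
            stacklevel=2,
        )
    return deltas


def aggregate_plant_delta(deltas: dict[str, float]) -> dict[str, float]:
    """Collapse the vascular-plant compartments into a single ``plants`` node."""
    out = {k: v for k, v in deltas.items() if k not in PLANT_COMPARTMENTS}
    plant = [deltas[k] for k in PLANT_COMPARTMENTS if k in deltas]
    if plant:
        out["plants"] = float(np.sum(plant))
    return out


@dataclass
class FlowLedger:
    """Solved per-edge flows for one interval, all in % of tracer applied."""

    interval: tuple[int, int]
    deltas: dict[str, float]
    flows: dict[tuple[str, str], float]
    residual: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def closure_error(self) -> float:
        """Max absolute node-balance violation (should be ~0)."""
        worst = 0.0
        for node, delta in self.deltas.items():
            inflow = sum(v for (a, b), v in self.flows.items() if b == node)
            outflow = sum(v for (a, b), v in self.flows.items() if a == node)
            worst = max(worst, abs(inflow - outflow - delta))
        return worst

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "flow_pct_applied": v} for (a, b), v in self.flows.items()
        ]
        return pd.DataFrame(rows)

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the solved flows."""
        lines = ["digraph tracer_flows {", "  rankdir=TB;"]
        for node, delta in self.deltas.items():
            lines.append(f'  "{node}" [label="{node}\\nΔ {delta:+.2f}"];')
        for (a, b), v in self.flows.items():
            style = ' style=dashed' if (a, b) == ("moss", "loss") else ""
            lines.append(f'  "{a}" -> "{b}" [label="{v:.2f}"{style}];')
        lines.append("}")
        return "\n".join(lines)


def infer_flows(
    deltas: dict[str, float],
    topology: FlowTopology | None = None,
    litter_flux: float = 0.0,
    leachate_flux: float = 0.0,
    pulse_input: float = 0.0,
    interval: tuple[int, int] = (0, 0),
) -> FlowLedger:
    """Solve all edge flows from per-compartment recovery changes.

    ``litter_flux`` is the plant-to-litter transfer over the interval and
    ``leachate_flux`` the drainage export from the B-horizon (both % of dose,
    both observable); ``pulse_input`` is the atmosphere-to-moss input (the
    full dose in the application interval, zero afterwards).  Every internal
    node's balance closes exactly; the residual edge absorbs what the moss
    budget cannot attribute.
    """
    topology = topology or default_topology()
    deltas = dict(deltas)
    unknown_nodes = [n for n in topology.internal_nodes if n not in deltas]
    if unknown_nodes:
        raise ValueError(f"no recovery delta for internal nodes: {unknown_nodes}")

    flows: dict[tuple[str, str], float] = {}
    for a, b in topology.edges:
        if (a, b) == ("atmosphere", "moss"):
            flows[(a, b)] = pulse_input
        elif (a, b) == ("plants", "litter_current"):
            flows[(a, b)] = litter_flux
        elif b == "leachate":
            flows[(a, b)] = leachate_flux

    unknown = [e for e in topology.edges if e not in flows]
    # Single-pass elimination: a node with exactly one unknown incident edge
    # determines that edge from its balance.
    while unknown:
        progressed = False
        for node in topology.internal_nodes:
            incident = [e for e in unknown if node in e]
            if len(incident) != 1:
                continue
            edge = incident[0]
            inflow = sum(v for (a, b), v in flows.items() if b == node)
            outflow = sum(v for (a, b), v in flows.items() if a == node)
            need = deltas[node] - (inflow - outflow)
            # outgoing unknown edge: larger outflow makes delta smaller
            flows[edge] = -need if edge[0] == node else need
            unknown.remove(edge)
            progressed = True
            break
        if not progressed:
            raise IdentifiabilityError(
                f"cannot solve edges {unknown} in a single pass; "
                "some node has more than one unknown incident edge"
            )

    notes = []
    residual = flows[topology.residual_edge]
    if residual < 0:
        notes.append(
            f"negative residual loss ({residual:.3f}); apparent tracer creation, "
            "likely measurement noise"
        )
    for (a, b), v in flows.items():
        if v < 0 and (a, b) != topology.residual_edge:
            notes.append(f"negative flow {a}->{b} ({v:.3f}); upward/reverse transport")
    for note in notes:
        warnings.warn(note, stacklevel=2)

    return FlowLedger(
        interval=interval,
        deltas=deltas,
        flows=flows,
        residual=residual,
        warnings=tuple(notes),
    )
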