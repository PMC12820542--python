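"""Theory graphs: combine weight and meta-analysis results per adoption model.

Each adoption theory (TAM, UTAUT, HBM+PMT, TTF, PCT, TPB, DOI) is a set of
constructs and directed paths, packaged as editable JSON data. An edge of
the synthesized graph carries the path's weight W, pooled effect r, p-value
and examination count; the edge renders *thick* when W ≥ 0.700 (paths
supported by a high proportion of studies) and dashed when only the weight
analysis covers it (no pooled effect available).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from fractions import Fraction
from typing import Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError
from .pooling import PoolResult
from .weights import WeightResult

logger = logging.getLogger(__name__)

THICK_MIN_WEIGHT = 0.700  # inclusive
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class TheoryEdge:
    predictor: str
    outcome: str
    W: float
    E: int
    r: float | None
    p: float | None
    thick: bool
    significant: bool


@dataclass(frozen=True)
class TheoryGraph:
    name: str
    nodes: tuple[str, ...]
    edges: tuple[TheoryEdge, ...]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.predictor,
                e.outcome,
                W=e.W,
                E=e.E,
                r=e.r,
                p=e.p,
                thick=e.thick,
                significant=e.significant,
            )
        return g


def load_theory_vocabulary() -> dict[str, dict]:
    """Packaged theory vocabularies: theory name → {nodes, edges}."""
    text = (
        resources.files("metaweight.data").joinpath("theories.json").read_text()
    )
    return json.loads(text)


def build_theory_graph(
    name: str,
    theory_edges: Sequence[tuple[str, str]],
    weights: Sequence[WeightResult],
    pools: Mapping[tuple[str, str], PoolResult],
) -> TheoryGraph:
    """Synthesize one theory's graph from weight and pooling results.

    Theory paths absent from the weight results are omitted with a warning
    (the corpus never examined them often enough); paths with a weight but
    no pooled effect become dashed weight-only edges (r and p absent).
    """
    wmap = {(w.predictor, w.outcome): w for w in weights}
    nodes: list[str] = []
    for pred, outc in theory_edges:
        for node in (pred, outc):
            if node not in nodes:
                nodes.append(node)
    edges: list[TheoryEdge] = []
    for pred, outc in theory_edges:
        w = wmap.get((pred, outc))
        pool = pools.get((pred, outc))
        if w is None:
            logger.warning(
                "theory %s: path %s -> %s absent from results; edge omitted",
                name,
                pred,
                outc,
            )
            continue
        r = pool.r if pool is not None else None
        p = pool.p if pool is not None else None
        edges.append(
            TheoryEdge(
                predictor=pred,
                outcome=outc,
                W=w.W,
                E=w.E,
                r=r,
                p=p,
                thick=w.W_exact >= Fraction(7, 10),
                significant=(p is not None and p < SIGNIFICANCE_ALPHA),
            )
        )
    return TheoryGraph(name=name, nodes=tuple(nodes), edges=tuple(edges))


def _fmt(x: float | None, digits: int = 3) -> str:
    return "" if x is None else f"{x:.{digits}f}"


def export_graph(graph: TheoryGraph, format: str = "json") -> str:
    """Deterministic serialization of a theory graph.

    ``json`` round-trips through :func:`import_graph`; ``dot`` renders
    edge thickness via a penwidth proportional to W and dashes weight-only
    edges.
    """
    if format == "json":
        payload = {
            "name": graph.name,
            "nodes": list(graph.nodes),
            "edges": [
                {
                    "predictor": e.predictor,
                    "outcome": e.outcome,
                    "W": e.W,
                    "E": e.E,
                    "r": e.r,
                    "p": e.p,
                    "thick": e.thick,
                    "significant": e.significant,
                }
                for e in graph.edges
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "dot":
        lines = [f'digraph "{graph.name}" {{']
        for node in graph.nodes:
            lines.append(f'  "{node}";')
        for e in graph.edges:
            penwidth = 1.0 + 3.0 * e.W
            attrs = [f"penwidth={penwidth:.2f}"]
            if e.r is None:
                attrs.append('style="dashed"')
                label = f"W={e.W:.3f}"
            else:
                star = "" if not e.significant else "*"
                label = f"r={_fmt(e.r)}{star} W={e.W:.3f}"
            attrs.append(f'label="{label}"')
            lines.append(
                f'  "{e.predictor}" -> "{e.outcome}" [{", ".join(attrs)}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ConfigurationError(f"unknown export format {format!r}")


def import_graph(serialized: str) -> TheoryGraph:
    """Inverse of the JSON export."""
    payload = json.loads(serialized)
    edges = tuple(
        TheoryEdge(
            predictor=e["predictor"],
            outcome=e["outcome"],
            W=e["W"],
            E=e["E"],
            r=e["r"],
            p=e["p"],
            thick=e["thick"],
            significant=e["significant"],
        )
        for e in payload["edges"]
    )
    return TheoryGraph(
        name=payload["name"], nodes=tuple(payload["nodes"]), edges=edges
    )
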