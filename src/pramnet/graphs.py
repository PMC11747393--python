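"""Edge-weight transform, mean concept graphs, subgraphs and centrality.

A similarity rating ``s`` on ``[r_min, r_max]`` maps affinely to an edge
weight

    e = 1 - (s - r_min) / (r_max - r_min)

so ``e`` lies in [0, 1] with 0 for maximal relatedness (+7) and 1 for
maximal opposition (−7); the weight acts as a distance between concept
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    RATING_MAX,
    RATING_MIN,
    ConceptSet,
    PairIndex,
    RatingMatrix,
    ValidationError,
)


def rating_to_edge_weight(s, r_min: float = RATING_MIN, r_max: float = RATING_MAX):
    """Affine map from similarity rating to [0, 1] edge weight (distance)."""
    if r_min >= r_max:
        raise ValueError("r_min must be < r_max")
    s = np.asarray(s, dtype=float)
    if np.any(s < r_min) or np.any(s > r_max):
        raise ValueError(f"rating outside [{r_min}, {r_max}]")
    out = 1.0 - (s - r_min) / (r_max - r_min)
    return float(out) if out.ndim == 0 else out


def edge_weight_to_rating(e, r_min: float = RATING_MIN, r_max: float = RATING_MAX):
    """Inverse of :func:`rating_to_edge_weight` on [0, 1]."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0) or np.any(e > 1):
        raise ValueError("edge weight outside [0, 1]")
    out = r_min + (1.0 - e) * (r_max - r_min)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EdgeWeightMatrix:
    """Participants x pairs real edge weights in [0, 1]."""

    values: np.ndarray
    participant_ids: tuple[str, ...]
    pair_index: PairIndex

    @classmethod
    def from_ratings(cls, ratings: RatingMatrix) -> "EdgeWeightMatrix":
        return cls(
            rating_to_edge_weight(ratings.values),
            ratings.participant_ids,
            ratings.pair_index,
        )


@dataclass(frozen=True)
class WeightedConceptGraph:
    """Concept nodes with mean edge weights; optional per-edge annotations.

    ``direction`` maps a pair column to +1/-1: the sign of the fitted group
    coefficient on the edge weight, i.e. -1 when group 1 shows the stronger
    association (shorter distance).
    """

    concepts: ConceptSet
    pair_index: PairIndex
    weights: Mapping[int, float]
    direction: Mapping[int, int] = field(default_factory=dict)
    q_values: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"edge weight {w} outside [0, 1] on pair {k}")
            if not 0 <= k < len(self.pair_index):
                raise ValidationError(f"pair column {k} outside pair index")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def nodes_with_edges(self) -> list[str]:
        seen: set[str] = set()
        for k in self.weights:
            seen.update(self.pair_index.labels(k))
        return sorted(seen)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.concepts.labels)
        for k, w in self.weights.items():
            a, b = self.pair_index.labels(k)
            attrs = {"weight": float(w)}
            if k in self.direction:
                attrs["direction"] = int(self.direction[k])
            if k in self.q_values:
                attrs["q_value"] = float(self.q_values[k])
            g.add_edge(a, b, **attrs)
        return g

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.weights):
            a, b = self.pair_index.labels(k)
            rows.append(
                {
                    "concept_a": a,
                    "concept_b": b,
                    "weight": float(self.weights[k]),
                    "direction": int(self.direction.get(k, 0)),
                    "q_value": float(self.q_values.get(k, np.nan)),
                }
            )
        return pd.DataFrame(
            rows, columns=["concept_a", "concept_b", "weight", "direction", "q_value"]
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edge_list(self, path: str | Path) -> None:
        self.to_edge_list().to_csv(path, index=False)


def mean_graph(
    weights: EdgeWeightMatrix, participant_subset: Sequence[int] | np.ndarray | None = None
) -> WeightedConceptGraph:
    """Per-edge arithmetic mean of edge weights over a participant subset."""
    v = weights.values
    if participant_subset is not None:
        idx = np.asarray(participant_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise ValidationError("empty participant subset")
        v = v[idx]
    elif v.shape[0] == 0:
        raise ValidationError("empty participant subset")
    means = v.mean(axis=0)
    return WeightedConceptGraph(
        weights.pair_index.concepts,
        weights.pair_index,
        {k: float(means[k]) for k in range(len(weights.pair_index))},
    )


def subgraph_from_flags(
    results: "pd.DataFrame | object",
    predictor: str,
    mean_weights: Mapping[int, float] | None = None,
) -> WeightedConceptGraph:
    """Subgraph of edges significant for ``predictor`` after FDR.

    ``results`` is an edge-wise inference table (see
    :mod:`pramnet.edgewise`). Each retained edge carries the sign of the
    fitted coefficient (negative = group 1 / higher predictor values show the
    stronger association) and its q-value. ``mean_weights`` optionally
    supplies the displayed edge weights; by default the subgraph stores the
    pooled mean weight column of the results table.
    """
    df = results.table if hasattr(results, "table") else results
    pi = results.pair_index if hasattr(results, "pair_index") else None
    if pi is None:
        raise ValueError("results must carry a pair_index")
    sub = df[(df["predictor"] == predictor) & df["significant"]]
    weights: dict[int, float] = {}
    direction: dict[int, int] = {}
    qvals: dict[int, float] = {}
    for row in sub.itertuples():
        k = int(row.pair)
        if mean_weights is not None:
            weights[k] = float(mean_weights[k])
        else:
            weights[k] = float(row.mean_weight)
        direction[k] = int(np.sign(row.beta)) or 1
        qvals[k] = float(row.q_value)
    concepts = pi.concepts
    return WeightedConceptGraph(concepts, pi, weights, direction, qvals)


def degree_centrality(
    graph: WeightedConceptGraph, denominator: str = "subgraph"
) -> dict[str, float]:
    """Degree of each non-isolated node over the maximum possible degree.

    ``denominator="subgraph"`` (default) divides by (number of nodes that
    carry at least one edge in the subgraph) − 1; ``"full"`` divides by
    (total number of concepts) − 1, i.e. the proportion of all pairs
    featuring the concept. Isolated concepts score 0 under both conventions.
    """
    degree: dict[str, int] = {c: 0 for c in graph.concepts.labels}
    for k in graph.weights:
        a, b = graph.pair_index.labels(k)
        degree[a] += 1
        degree[b] += 1
    if denominator == "subgraph":
        active = [c for c, d in degree.items() if d > 0]
        denom = max(len(active) - 1, 1)
    elif denominator == "full":
        denom = max(len(graph.concepts) - 1, 1)
    else:
        raise ValueError("denominator must be 'subgraph' or 'full'")
    return {c: d / denom for c, d in degree.items()}
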