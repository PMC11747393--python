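"""End-to-end orchestration: data -> reliability -> edge GLMs -> graphs ->
entropy -> mediation, with deterministic, fully seeded outputs.

Every stage draws its randomness from a named substream of one root seed,
so a pipeline run is a pure function of (inputs, config, seed) and two runs
with the same configuration produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import Cohort, load_cohort
from .edgewise import run_edgewise
from .entropy import entropy_effect_analysis
from .graphs import EdgeWeightMatrix, degree_centrality, mean_graph, subgraph_from_flags
from .mediation import run_mediation_screen
from .reliability import split_half_reliability
from .simulate import default_scenarios, simulate_cohort, write_simulated_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    scenario: str | None = None
    ratings_path: str | None = None
    demographics_path: str | None = None
    bias_path: str | None = None
    n_per_group: int | None = None
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    permutation_scheme: str = "simple"
    n_reliability_splits: int = 500
    out_dir: str | None = None
    run_reliability: bool = True
    run_entropy: bool = True
    run_mediation: bool = True

    def __post_init__(self) -> None:
        has_paths = all(
            p is not None
            for p in (self.ratings_path, self.demographics_path, self.bias_path)
        )
        if self.scenario is None and not has_paths:
            raise ValueError("provide either a scenario name or all three input paths")
        if self.scenario is not None and has_paths:
            raise ValueError("scenario and input paths are mutually exclusive")
        if self.scenario is not None and self.scenario not in default_scenarios():
            raise ValueError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(default_scenarios())}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def _stage_seed(root: int, stage: str) -> int:
    """Stable named substream below 2^31 for one pipeline stage."""
    ss = np.random.SeedSequence((root, sum(ord(c) for c in stage)))
    return int(ss.generate_state(1)[0] % (2**31))


def _get_cohort(config: PipelineConfig) -> Cohort:
    if config.scenario is not None:
        cfg = default_scenarios(n_per_group=config.n_per_group)[config.scenario]
        return simulate_cohort(cfg, seed=_stage_seed(config.seed, "simulate"))
    return load_cohort(config.ratings_path, config.demographics_path, config.bias_path)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and optionally write) the summary.

    Output bundle (when ``out_dir`` is set): the serialized config, the
    simulated cohort CSVs (scenario runs), a reliability JSON, the edge-wise
    results TSV, group-difference subgraph (CSV edge list + GraphML) with
    node centralities, the entropy/effect TSV and sigmoid-fit JSON, the
    mediation TSV, and a ``summary.json`` with the headline counts.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
        )
    stage = "simulate/load"
    try:
        cohort = _get_cohort(config)
        if out and config.scenario is not None:
            write_simulated_cohort(cohort, out)
        summary: dict = {
            "config": dataclasses.asdict(config),
            "n_participants": cohort.n_participants,
            "n_scored": cohort.n_scored(),
        }

        if config.run_reliability:
            stage = "reliability"
            rel = split_half_reliability(
                cohort.ratings,
                n_splits=config.n_reliability_splits,
                seed=_stage_seed(config.seed, "reliability"),
            )
            summary["reliability"] = {
                "r_raw": rel.r_raw,
                "r_corrected": rel.r_corrected,
                "n_splits": rel.n_splits,
            }
            if out:
                (out / "reliability.json").write_text(
                    json.dumps(summary["reliability"], indent=2, sort_keys=True) + "\n"
                )

        stage = "edgewise"
        edges = run_edgewise(
            cohort,
            predictors=("race", "news_bias"),
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=_stage_seed(config.seed, "edges"),
            scheme=config.permutation_scheme,
        )
        summary["edges"] = {
            "race_differing": edges.n_significant("race"),
            "news_differing": edges.n_significant("news_bias"),
            "n_pairs": len(cohort.pair_index),
        }
        if out:
            edges.table.to_csv(out / "edgewise.tsv", sep="\t", index=False)

        stage = "subgraph"
        pooled = mean_graph(EdgeWeightMatrix.from_ratings(cohort.ratings))
        race_sub = subgraph_from_flags(edges, "race", mean_weights=pooled.weights)
        centrality = degree_centrality(race_sub)
        hubs = sorted(
            ((c, v) for c, v in centrality.items() if v > 0),
            key=lambda cv: (-cv[1], cv[0]),
        )
        summary["race_subgraph"] = {
            "n_edges": race_sub.n_edges,
            "centrality": {c: round(v, 6) for c, v in hubs},
        }
        if out:
            race_sub.write_edge_list(out / "race_subgraph.csv")
            race_sub.write_graphml(out / "race_subgraph.graphml")
            pd.DataFrame(
                sorted(centrality.items()), columns=["concept", "centrality"]
            ).to_csv(out / "centrality.csv", index=False)

        if config.run_entropy:
            stage = "entropy"
            ent = entropy_effect_analysis(
                edges,
                cohort.ratings,
                predictor="news_bias",
                seed=_stage_seed(config.seed, "entropy"),
            )
            summary["entropy_sigmoid"] = {
                "a": ent.fit.a,
                "b": ent.fit.b,
                "c": ent.fit.c,
                "r_squared": ent.fit.r_squared,
                "converged": ent.fit.converged,
            }
            if out:
                ent.table.to_csv(out / "entropy.tsv", sep="\t", index=False)
                (out / "sigmoid.json").write_text(
                    json.dumps(summary["entropy_sigmoid"], indent=2, sort_keys=True) + "\n"
                )

        if config.run_mediation:
            stage = "mediation"
            med = run_mediation_screen(
                cohort,
                edges.significant_pairs("race"),
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=_stage_seed(config.seed, "mediation"),
            )
            summary["mediation"] = {
                "n_screened": len(med.table),
                "labels": med.label_counts(),
            }
            if out:
                med.table.to_csv(out / "mediation.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        (out / "run.log").write_text(
            f"pramnet {__version__}\npython {platform.python_version()}\n"
            f"numpy {np.__version__}\nroot_seed {config.seed}\n"
        )
    return summary
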