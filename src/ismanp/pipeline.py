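"""End-to-end pipeline: psychometrics → ISM → ANP with a reproducible manifest.

The pipeline is configuration-driven (:class:`PipelineConfig`, schema-checked
before any computation; unknown keys are rejected) and writes every stage
artifact plus a JSON manifest with versions, seeds and SHA-256 checksums.
Outputs are byte-reproducible from config + seed. Any stage failure aborts
with the stage name and the offending input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from . import __version__, anp, fixtures, io, ism, psychometrics, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ismanp.pipeline")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration. Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str
    seed: int = 42
    log_level: str = "WARNING"

    # psychometrics inputs (optional stage)
    responses: Optional[str] = None
    dimensions: Optional[str] = None  # JSON: item -> Haddon dimension
    retention: Literal["kaiser", "cumulative", "fixed"] = "kaiser"
    cumulative_threshold: float = 85.0
    n_factors: Optional[int] = None

    # ISM inputs: exactly one of relations / reachability_sets / use_example
    relations: Optional[str] = None
    reachability_sets: Optional[str] = None
    use_example: bool = False
    reclose: bool = False

    # ANP inputs
    clusters: Optional[str] = None  # JSON: factor -> cluster (example supplies its own)
    judgments: Optional[str] = None
    cluster_judgments: Optional[str] = None
    uniform_judgments: bool = False
    seeded_random_judgments: bool = False
    allow_inconsistent: bool = False
    orientation: Literal["influence", "dependence"] = "influence"
    limit_method: Literal["auto", "power", "cesaro"] = "auto"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager that re-raises any failure tagged with its stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, _StageError):
            raise _StageError(f"stage '{self.name}' failed: {exc}") from exc
        return False


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the manifest (also written).

    Artifacts, all under ``config.out_dir``: ``reliability.json`` and
    ``variance_table.csv`` (when responses are supplied), ``reachability.csv``,
    ``factor_sets.csv`` + ``factor_sets.json``, ``levels.csv``,
    ``hierarchy.dot``, ``supermatrix_unweighted.csv`` / ``_weighted.csv`` /
    ``_limit.csv``, ``weights.csv`` and ``manifest.json``.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        written.append(path)
        return path

    fx = fixtures.load_fixtures() if config.use_example else None

    # --- psychometrics ------------------------------------------------------
    if config.responses is not None:
        with _Stage("psychometrics"):
            import pandas as pd

            responses = pd.read_csv(config.responses)
            dims = (
                json.loads(Path(config.dimensions).read_text(encoding="utf-8"))
                if config.dimensions
                else None
            )
            corr = psychometrics.compute_correlation(responses)
            report = {
                "n_respondents": int(responses.shape[0]),
                "n_items": int(responses.shape[1]),
                "cronbach_alpha_overall": psychometrics.cronbach_alpha(responses),
                "kmo": psychometrics.kmo_statistic(corr),
            }
            stat, df_, p = psychometrics.bartlett_sphericity(corr, responses.shape[0])
            report["bartlett"] = {"statistic": stat, "df": df_, "pvalue": p}
            if dims:
                report["cronbach_alpha_by_dimension"] = {
                    d: psychometrics.cronbach_alpha(
                        responses, [i for i, dd in dims.items() if dd == d]
                    )
                    for d in sorted(set(dims.values()))
                    if sum(dd == d for dd in dims.values()) >= 2
                }
            result = psychometrics.efa(
                corr,
                retention=config.retention,
                cumulative_threshold=config.cumulative_threshold,
                n_factors=config.n_factors,
            )
            emit(
                "reliability.json",
                lambda payload, path: Path(path).write_text(
                    json.dumps(payload, indent=1) + "\n", encoding="utf-8"
                ),
                report,
            )
            emit(
                "variance_table.csv",
                lambda table, path: table.to_csv(path, index=False, float_format="%.6g"),
                result.variance_table(),
            )

    # --- ISM ----------------------------------------------------------------
    with _Stage("ism"):
        chosen = [
            name
            for name, given in [
                ("relations", config.relations is not None),
                ("reachability_sets", config.reachability_sets is not None),
                ("use_example", config.use_example),
            ]
            if given
        ]
        if len(chosen) != 1:
            raise ValueError(
                "configure exactly one of relations / reachability_sets / "
                f"use_example (got {chosen or 'none'})"
            )
        if config.relations is not None:
            relations = io.read_relations_csv(config.relations)
            ids = sorted(
                {f for r in relations for f in r[:2]}, key=io.factor_sort_key
            )
            M = ism.transitive_closure(ism.build_adjacency(relations, ids))
        elif config.reachability_sets is not None:
            sets = io.read_sets_json(config.reachability_sets)
            M = ism.reachability_from_sets(sets)
        else:
            M = ism.reachability_from_sets(fx.reachable_sets)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partition = ism.partition_levels(M, reclose=config.reclose)
        sets_table = ism.factor_sets(M)
        digraph = ism.hierarchy_digraph(M, partition)
        emit("reachability.csv", io.write_matrix_csv, M)
        emit("factor_sets.csv", io.write_factor_sets_csv, sets_table)
        emit(
            "factor_sets.json",
            io.write_sets_json,
            {f: sets_table.loc[f, "reachable"] for f in sets_table.index},
        )
        emit("levels.csv", io.write_levels_csv, partition.levels)
        labels = fx.factor_labels if fx else None
        emit(
            "hierarchy.dot",
            lambda dg, path: Path(path).write_text(dg.to_dot(labels), encoding="utf-8"),
            digraph,
        )

    # --- ANP ----------------------------------------------------------------
    with _Stage("anp"):
        if fx:
            cluster_of = fx.cluster_of
            cluster_order = fx.cluster_order
        elif config.clusters:
            cluster_of = json.loads(Path(config.clusters).read_text(encoding="utf-8"))
            cluster_order = None
        else:
            raise ValueError("ANP needs a clusters JSON (factor -> cluster label)")
        network = anp.build_network(M, cluster_of, cluster_order)
        if config.judgments is not None:
            judgments = io.read_judgments_json(config.judgments)
        elif config.uniform_judgments:
            judgments = "uniform"
        elif config.seeded_random_judgments:
            judgments = synthetic.random_consistent_judgments(
                network, seed=config.seed, orientation=config.orientation
            )
        else:
            raise ValueError(
                "no judgment matrices configured; supply 'judgments' or set "
                "'uniform_judgments' / 'seeded_random_judgments'"
            )
        cluster_judgments = (
            io.read_judgments_json(config.cluster_judgments)
            if config.cluster_judgments
            else None
        )
        result = anp.anp_pipeline(
            network,
            judgments,
            cluster_judgments=cluster_judgments,
            allow_inconsistent=config.allow_inconsistent,
            orientation=config.orientation,
            limit_method=config.limit_method,
        )
        full = lambda m, path: io.write_matrix_csv(m, path, float_format="%.12g")
        emit("supermatrix_unweighted.csv", full, result.unweighted)
        emit("supermatrix_weighted.csv", full, result.weighted)
        emit("supermatrix_limit.csv", full, result.limit.matrix)
        emit("weights.csv", io.write_weight_table_csv, result.weights)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "ismanp_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "limit_method": result.limit.method,
        "weights_full_precision": {
            f: float(w) for f, w in result.weights["weight"].items()
        },
        "checksums": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
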