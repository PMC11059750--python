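"""End-to-end orchestration: hypergraph -> factorize -> cluster -> evaluate -> markers.

``run_pipeline`` takes a flat key-value configuration (dict or YAML path),
executes the stages in order, and writes every artifact plus a run log with
all resolved parameters to the output directory.  Any stage failure raises
:class:`~chlnmf.errors.PipelineError` tagged with the stage name, and the run
log records which stages completed so partial output is never silent.
"""

from __future__ import annotations

import os
import warnings
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import evaluation, factorization, hypergraph, markers
from .errors import InvalidInputError, PipelineError
from .io import ExpressionMatrix, read_expression, read_labels, write_labels

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "input": None,          # path to expression matrix (tsv/csv/mtx)
    "truth_labels": None,   # optional path to truth label TSV
    "cells_in_rows": False,
    "log1p": False,
    "gene_filter_min_cells": 0,
    "k": None,              # factorization rank (required)
    "c": 0.5,
    "alpha": 10.0,
    "p": 5,
    "sigma": None,
    "n_clusters": None,     # defaults to k
    "knn": 5,
    "top_n": 10,
    "rank_direction": "ascending",
    "max_iter": 100,
    "tol": 1e-4,
    "n_restarts": 20,
    "seed": 0,
    "output_dir": ".",
}

_REQUIRED = ("input", "k")


def _load_config(config: Mapping[str, Any] | str) -> dict[str, Any]:
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    for key in _REQUIRED:
        if cfg[key] is None:
            raise InvalidInputError(f"config is missing required key {key!r}")
    if cfg["n_clusters"] is None:
        cfg["n_clusters"] = cfg["k"]
    return cfg


def _write_matrix(M: np.ndarray, rows: list[str], cols: list[str], path: str) -> None:
    pd.DataFrame(M, index=rows, columns=cols).to_csv(path, sep="\t")


def run_pipeline(
    config: Mapping[str, Any] | str,
    X: ExpressionMatrix | None = None,
) -> dict[str, Any]:
    """Run the full workflow; returns a dict of in-memory results.

    ``X`` may be passed directly (e.g. from the synthetic generator), in
    which case the ``input`` key is ignored but must still be present (use
    any placeholder).  Artifacts written to ``output_dir``: U.tsv, V.tsv,
    omega.tsv, objective_trace.tsv, labels.tsv, metrics.tsv (when truth
    labels are available), markers.tsv, run_log.yaml.
    """
    cfg = _load_config(config)
    out = cfg["output_dir"]
    os.makedirs(out, exist_ok=True)
    completed: list[str] = []
    results: dict[str, Any] = {}

    def stage(name: str):
        def deco(fn):
            try:
                fn()
            except PipelineError:
                raise
            except Exception as exc:
                _log(status=f"failed at stage {name!r}: {exc}")
                raise PipelineError(f"[{name}] {exc}") from exc
            completed.append(name)

        return deco

    def _log(status: str) -> None:
        with open(os.path.join(out, "run_log.yaml"), "w") as fh:
            yaml.safe_dump(
                {"parameters": cfg, "completed_stages": completed, "status": status},
                fh,
                sort_keys=False,
            )

    truth = None

    @stage("read")
    def _read():
        nonlocal X, truth
        if X is None:
            X = read_expression(
                cfg["input"],
                cells_in_rows=cfg["cells_in_rows"],
                log1p=cfg["log1p"],
                gene_filter_min_cells=cfg["gene_filter_min_cells"],
            )
        if cfg["truth_labels"]:
            cells, codes = read_labels(cfg["truth_labels"])
            if cells != X.cell_ids:
                raise InvalidInputError(
                    "truth-label cell ids do not match the expression matrix"
                )
            truth = codes
        results["X"] = X

    @stage("hypergraph")
    def _hyper():
        results["hypergraph"] = hypergraph.build_hypergraph(
            X, p=cfg["p"], sigma=cfg["sigma"]
        )

    @stage("factorize")
    def _factorize():
        fc = factorization.FactorizationConfig(
            rank=cfg["k"],
            cauchy_scale=cfg["c"],
            alpha=cfg["alpha"],
            neighborhood=cfg["p"],
            max_iter=cfg["max_iter"],
            tol=cfg["tol"],
            seed=cfg["seed"],
        )
        res = factorization.fit(X, results["hypergraph"], fc)
        results["factorization"] = res
        factors = [f"factor_{i}" for i in range(cfg["k"])]
        _write_matrix(res.U, X.gene_ids, factors, os.path.join(out, "U.tsv"))
        _write_matrix(res.V, factors, X.cell_ids, os.path.join(out, "V.tsv"))
        pd.DataFrame({"cell_id": X.cell_ids, "omega": res.omega}).to_csv(
            os.path.join(out, "omega.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {"iteration": np.arange(len(res.objective_trace)),
             "objective": res.objective_trace}
        ).to_csv(os.path.join(out, "objective_trace.tsv"), sep="\t", index=False)

    @stage("cluster")
    def _cluster():
        labels = evaluation.kmeans_cluster(
            results["factorization"].V,
            n_clusters=cfg["n_clusters"],
            seed=cfg["seed"],
            n_restarts=cfg["n_restarts"],
        )
        results["labels"] = labels
        write_labels(X.cell_ids, labels.labels, os.path.join(out, "labels.tsv"))

    @stage("evaluate")
    def _evaluate():
        if truth is None:
            return
        metrics = {
            "nmi": evaluation.nmi(truth, results["labels"].labels),
            "ari": evaluation.ari(truth, results["labels"].labels),
        }
        results["metrics"] = metrics
        pd.DataFrame(
            {"metric": list(metrics), "value": list(metrics.values())}
        ).to_csv(os.path.join(out, "metrics.tsv"), sep="\t", index=False)

    @stage("markers")
    def _markers():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = markers.pearson_similarity(results["factorization"].V)
            scores = markers.laplacian_score(X, S, knn=cfg["knn"])
        ranking = markers.top_markers(
            scores,
            X.gene_ids,
            top_n=cfg["top_n"],
            ascending=cfg["rank_direction"] == "ascending",
        )
        results["markers"] = ranking
        rank_of = {g: r for r, g in enumerate(
            (ranking.gene_ids[i] for i in ranking.order), start=1)}
        pd.DataFrame(
            {
                "gene_id": X.gene_ids,
                "laplacian_score": scores,
                "rank": [rank_of[g] for g in X.gene_ids],
            }
        ).to_csv(os.path.join(out, "markers.tsv"), sep="\t", index=False)

    _log(status="ok")
    return results
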