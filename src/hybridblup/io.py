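"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated text: wide lines x predictors matrices with a
``line`` id column (missing markers written as ``NA``), an expression
table with an optional ``replicate`` column, a hybrid phenotype table
(``female``, ``male``, trait columns), a per-se phenotype table, plain
gene lists, and a structured-text model file that round-trips a fitted
model exactly (predictions from a reloaded model are identical).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .model import FittedModel, VarianceComponents
from .simulate import PoolAssignment, SyntheticDataset

__all__ = [
    "write_marker_matrix", "read_marker_matrix",
    "write_expression", "read_expression",
    "write_hybrid_table", "read_hybrid_table",
    "write_per_se", "read_per_se",
    "write_gene_list", "read_gene_list",
    "write_pools", "read_pools",
    "write_model", "read_model",
    "write_dataset",
]


def write_marker_matrix(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index_label="line", na_rep="NA", lineterminator="\n")


def read_marker_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="line", na_values=["NA"])
    df.index.name = None
    return df.astype(float)


def write_expression(expression: pd.DataFrame, path) -> None:
    """Write a lines x genes table; a (line, replicate) MultiIndex is
    written as two leading columns."""
    if isinstance(expression.index, pd.MultiIndex):
        expression.to_csv(path, sep="\t", index_label=["line", "replicate"], lineterminator="\n")
    else:
        expression.to_csv(path, sep="\t", index_label="line", lineterminator="\n")


def read_expression(path) -> pd.DataFrame:
    head = pd.read_csv(path, sep="\t", nrows=0)
    if "replicate" in head.columns[:2]:
        df = pd.read_csv(path, sep="\t", index_col=["line", "replicate"])
    else:
        df = pd.read_csv(path, sep="\t", index_col="line")
        df.index.name = None
    return df.astype(float)


def write_hybrid_table(hybrids: pd.DataFrame, path) -> None:
    hybrids.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_hybrid_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("female", "male"):
        if col not in df.columns:
            raise DataError(f"hybrid table lacks required column {col!r}")
    return df


def write_per_se(per_se: pd.Series, path) -> None:
    per_se.rename("per_se").to_csv(path, sep="\t", index_label="line", lineterminator="\n")


def read_per_se(path) -> pd.Series:
    series = pd.read_csv(path, sep="\t", index_col="line")["per_se"].astype(float)
    series.index.name = None
    return series


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_pools(pools: PoolAssignment, path) -> None:
    payload = {"female_lines": list(pools.female_lines), "male_lines": list(pools.male_lines)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_pools(path) -> PoolAssignment:
    payload = yaml.safe_load(Path(path).read_text())
    return PoolAssignment(tuple(payload["female_lines"]), tuple(payload["male_lines"]))


def write_model(model: FittedModel, path) -> None:
    """Structured-text model file: a JSON header line with scalars, then a
    TSV body of per-predictor effects and normalization maxima."""
    header = {
        "beta0": model.beta0,
        "sigma2_f": model.vc.sigma2_f,
        "sigma2_m": model.vc.sigma2_m,
        "sigma2_e": model.vc.sigma2_e,
        "reml_loglik": model.vc.reml_loglik,
        "converged": model.vc.converged,
    }
    body = pd.DataFrame({
        "predictor": list(model.predictor_ids),
        "u_hat": model.u_hat,
        "v_hat": model.v_hat,
        "col_max_f": model.col_max_f,
        "col_max_m": model.col_max_m,
    })
    with open(path, "w") as fh:
        fh.write("#hybridblup-model\t" + json.dumps(header) + "\n")
        body.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_model(path) -> FittedModel:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#hybridblup-model\t"):
            raise DataError(f"{path} is not a model file")
        header = json.loads(first.split("\t", 1)[1])
        body = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    vc = VarianceComponents(
        sigma2_f=header["sigma2_f"], sigma2_m=header["sigma2_m"],
        sigma2_e=header["sigma2_e"], reml_loglik=header["reml_loglik"],
        converged=header["converged"],
    )
    return FittedModel(
        beta0=header["beta0"],
        u_hat=body["u_hat"].to_numpy(dtype=float),
        v_hat=body["v_hat"].to_numpy(dtype=float),
        vc=vc,
        predictor_ids=tuple(body["predictor"]),
        col_max_f=body["col_max_f"].to_numpy(dtype=float),
        col_max_m=body["col_max_m"].to_numpy(dtype=float),
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write every component of a synthetic dataset; returns name->path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pools": out / "pools.yaml",
        "markers": out / "markers.tsv",
        "expression": out / "expression.tsv",
        "expression_replicates": out / "expression_replicates.tsv",
        "hybrids": out / "hybrids.tsv",
        "per_se": out / "per_se.tsv",
    }
    write_pools(dataset.pools, paths["pools"])
    write_marker_matrix(dataset.markers, paths["markers"])
    write_expression(dataset.expression, paths["expression"])
    write_expression(dataset.expression_replicates, paths["expression_replicates"])
    write_hybrid_table(dataset.hybrids, paths["hybrids"])
    write_per_se(dataset.per_se, paths["per_se"])
    return {k: str(v) for k, v in paths.items()}
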