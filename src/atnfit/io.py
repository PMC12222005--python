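"""File formats: wide biomass/catch CSV, web YAML, parameter/result JSON.

The single dataset dialect is a wide CSV — first column ``year``, one
column per node, blank cells meaning *missing* (never zero: zero
records are data and are replaced upstream by the preparation rules,
not by the reader).  All numeric output keeps full double precision so
files round-trip bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FitResult
from .evaluation import EvaluationReport
from .foodweb import FoodWeb, Guild, RateParameters
from .noise import BiomassDataset

__all__ = [
    "read_biomass_csv",
    "write_biomass_csv",
    "read_catch_csv",
    "write_catch_csv",
    "read_web_yaml",
    "write_web_yaml",
    "params_to_dict",
    "params_from_dict",
    "write_fit_result",
    "read_fit_result",
    "compare_models",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Malformed input file, with row/column location where possible."""


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}"
            )


def _raw_header(path) -> list[str]:
    import csv as _csv

    with open(path, newline="") as fh:
        return next(_csv.reader(fh))


def read_biomass_csv(path) -> BiomassDataset:
    """Read a wide biomass CSV (rows = years, columns = nodes, blank = missing)."""
    header = _raw_header(path)
    nodes = header[1:]
    if len(set(nodes)) != len(nodes):
        dup = [n for n in nodes if nodes.count(n) > 1][0]
        raise FormatError(f"{path}: duplicate node column {dup!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "year":
        raise FormatError(f"{path}: first column must be 'year'")
    df = df.replace("", np.nan)
    _check_numeric(df, path)
    years = df.iloc[:, 0].astype(int).to_numpy()
    B = df.iloc[:, 1:].astype(float).to_numpy()
    return BiomassDataset(
        nodes=nodes, years=years, B_obs=B, observed_mask=~np.isnan(B)
    )


def write_biomass_csv(dataset: BiomassDataset, path) -> None:
    """Write the wide biomass CSV; masked cells become blanks (round-trip stable)."""
    B = np.where(dataset.observed_mask, dataset.B_obs, np.nan)
    df = pd.DataFrame(B, columns=dataset.nodes)
    df.insert(0, "year", dataset.years)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_catch_csv(path, dataset: BiomassDataset) -> np.ndarray:
    """Read a catch CSV (subset of node columns) into a full (T, n) matrix.

    Nodes without a column get zero catch; years must match the
    biomass series.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "year":
        raise FormatError(f"{path}: first column must be 'year'")
    df = df.replace("", np.nan)
    _check_numeric(df, path)
    years = df.iloc[:, 0].astype(int).to_numpy()
    if not np.array_equal(years, dataset.years):
        raise FormatError(f"{path}: catch years do not match the biomass series")
    out = np.zeros((dataset.n_years, dataset.n_nodes))
    for col in df.columns[1:]:
        if col not in dataset.nodes:
            raise FormatError(f"{path}: unknown catch column {col!r}")
        vals = df[col].astype(float).to_numpy()
        out[:, dataset.nodes.index(col)] = np.nan_to_num(vals, nan=0.0)
    return out


def write_catch_csv(dataset: BiomassDataset, web: FoodWeb, path) -> None:
    """Write catches of the has-catch guilds in the wide dialect."""
    cols = [g.name for g in web.guilds if g.has_catch]
    df = pd.DataFrame(
        {c: dataset.catches[:, dataset.nodes.index(c)] for c in cols}
    )
    df.insert(0, "year", dataset.years)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_web_yaml(web: FoodWeb, path) -> None:
    doc = {
        "guilds": [
            {
                "name": g.name,
                "role": g.role,
                **({"max_body_mass": g.max_body_mass} if g.max_body_mass else {}),
                **({"has_catch": True} if g.has_catch else {}),
            }
            for g in web.guilds
        ],
        "links": [
            {"consumer": c, "resource": r, "e": float(e)}
            for (c, r), e in zip(web.links, web.e)
        ],
        "exudation": {
            web.node_names[i]: float(web.s[i]) for i in web.producer_indices
        },
        "activity_respiration": {
            web.node_names[i]: float(web.ua[i]) for i in web.consumer_indices
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_web_yaml(path) -> FoodWeb:
    doc = yaml.safe_load(Path(path).read_text())
    guilds = [
        Guild(
            g["name"],
            g["role"],
            max_body_mass=g.get("max_body_mass"),
            has_catch=bool(g.get("has_catch", False)),
        )
        for g in doc["guilds"]
    ]
    links = [(l["consumer"], l["resource"]) for l in doc["links"]]
    e = {(l["consumer"], l["resource"]): float(l["e"]) for l in doc["links"]}
    return FoodWeb(
        guilds,
        links,
        e=e,
        s=doc.get("exudation", {}),
        ua=doc.get("activity_respiration", {}),
    )


def params_to_dict(
    params: RateParameters,
    web: FoodWeb,
    sigma: np.ndarray | None = None,
    B_init: np.ndarray | None = None,
) -> dict:
    link_keys = [f"{c}->{r}" for c, r in web.links]
    out = {
        "r": {web.node_names[i]: float(v) for i, v in zip(web.producer_indices, params.r)},
        "K": float(params.K),
        "um": {web.node_names[i]: float(v) for i, v in zip(web.consumer_indices, params.um)},
        "J": dict(zip(link_keys, map(float, params.J))),
        "B0": dict(zip(link_keys, map(float, params.B0))),
        "q": dict(zip(link_keys, map(float, params.q))),
    }
    if params.um_lower is not None:
        out["um_lower"] = {
            web.node_names[i]: float(v)
            for i, v in zip(web.consumer_indices, params.um_lower)
        }
    if sigma is not None:
        out["sigma"] = dict(zip(web.node_names, map(float, sigma)))
    if B_init is not None:
        out["B_init"] = dict(zip(web.node_names, map(float, B_init)))
    return out


def params_from_dict(doc: dict, web: FoodWeb):
    """Inverse of :func:`params_to_dict`; returns (params, sigma, B_init)."""
    link_keys = [f"{c}->{r}" for c, r in web.links]
    names = web.node_names
    params = RateParameters(
        r=np.array([doc["r"][names[i]] for i in web.producer_indices]),
        K=float(doc["K"]),
        um=np.array([doc["um"][names[i]] for i in web.consumer_indices]),
        J=np.array([doc["J"][k] for k in link_keys]),
        B0=np.array([doc["B0"][k] for k in link_keys]),
        q=np.array([doc["q"][k] for k in link_keys]),
        um_lower=(
            np.array([doc["um_lower"][names[i]] for i in web.consumer_indices])
            if "um_lower" in doc
            else None
        ),
    )
    sigma = (
        np.array([doc["sigma"][n] for n in names]) if "sigma" in doc else None
    )
    B_init = (
        np.array([doc["B_init"][n] for n in names]) if "B_init" in doc else None
    )
    return params, sigma, B_init


def write_fit_result(result: FitResult, web: FoodWeb, path, config: dict | None = None) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "parameters": params_to_dict(result.params, web, result.sigma, result.B_init),
        "loss": result.loss,
        "loglik": result.loglik,
        "aic": result.aic,
        "n_parameters": result.n_parameters,
        "n_nonpositive": {
            "all_nodes": result.n_nonpositive.all_nodes,
            "excluding_detritus": result.n_nonpositive.excluding_detritus,
        },
        "restart_trace": list(map(float, result.restart_trace)),
        "n_evals": result.n_evals,
    }
    if config is not None:
        doc["config"] = config
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit_result(path, web: FoodWeb) -> dict:
    doc = json.loads(Path(path).read_text())
    params, sigma, B_init = params_from_dict(doc["parameters"], web)
    doc["params"] = params
    doc["sigma"] = sigma
    doc["B_init"] = B_init
    return doc


def compare_models(
    reports: dict[str, EvaluationReport], reference: str
) -> pd.DataFrame:
    """Comparison table of evaluation reports, AIC differences vs a reference.

    Rows carry the model label, AIC difference to the reference model,
    non-positive prediction counts (all nodes and excluding detritus),
    Bray–Curtis dissimilarity and CPI coverage.
    """
    if reference not in reports:
        raise KeyError(f"reference model {reference!r} not among the results")
    ref_aic = reports[reference].aic
    rows = []
    for label, rep in reports.items():
        rows.append(
            {
                "model": label,
                "delta_aic": rep.aic - ref_aic,
                "aic": rep.aic,
                "n_nonpositive_excl_detritus": rep.n_nonpositive_excl_detritus,
                "n_nonpositive_all": rep.n_nonpositive_all,
                "bray_curtis": rep.bray_curtis_dissimilarity,
                "similarity": rep.similarity,
                "cpi_coverage": rep.cpi_coverage,
                "loglik": rep.loglik,
                "n_parameters": rep.n_parameters,
            }
        )
    return pd.DataFrame(rows)
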