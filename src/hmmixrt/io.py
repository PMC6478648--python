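"""Readers and writers for the wide CSV dialect and fit/truth JSON files.

The wide layout has one row per respondent with columns ``resp_1..resp_n``
and ``rt_1..rt_n``; an empty cell is a missing value.  Writers mirror the
readers so read-write-read round trips are value-identical, including
missingness.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset, FitResult, ModelSpec, ParameterSet, validate_dataset
from .simulate import ScenarioTruth


def _split_columns(df: pd.DataFrame):
    resp_cols = sorted([c for c in df.columns if c.startswith("resp_")],
                       key=lambda c: int(c.split("_")[1]))
    rt_cols = sorted([c for c in df.columns if c.startswith("rt_")],
                     key=lambda c: int(c.split("_")[1]))
    if not resp_cols or len(resp_cols) != len(rt_cols):
        raise ValueError("expected matching resp_1..resp_n and rt_1..rt_n columns")
    return resp_cols, rt_cols


def read_wide_csv(path):
    """Read a wide CSV into (responses, rts) float matrices with NaN missingness."""
    df = pd.read_csv(path)
    resp_cols, rt_cols = _split_columns(df)
    return df[resp_cols].to_numpy(dtype=float), df[rt_cols].to_numpy(dtype=float)


def write_wide_csv(path, responses: np.ndarray, rts: np.ndarray,
                   rt_decimals: int | None = None) -> None:
    """Write responses and response times (raw or categorized) as wide CSV."""
    responses = np.asarray(responses, dtype=float)
    rts = np.asarray(rts, dtype=float)
    n = responses.shape[1]
    df = pd.DataFrame({
        **{f"resp_{i + 1}": responses[:, i] for i in range(n)},
        **{f"rt_{i + 1}": rts[:, i] for i in range(n)},
    })
    float_format = f"%.{rt_decimals}f" if rt_decimals is not None else None
    df.to_csv(path, index=False, float_format=float_format)


def read_dataset_csv(path, T: int) -> Dataset:
    """Read a wide CSV of responses and categorized RTs into a Dataset."""
    responses, rts = read_wide_csv(path)
    return validate_dataset(responses, rts, T)


def _params_to_dict(params: ParameterSet) -> dict:
    out = {}
    for k in params.__dataclass_fields__:
        v = getattr(params, k)
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def _params_from_dict(d: dict) -> ParameterSet:
    kw = {}
    for k, v in d.items():
        kw[k] = np.asarray(v, dtype=float) if isinstance(v, list) else v
    return ParameterSet(**kw)


def write_fit_json(path, fit_result: FitResult) -> None:
    payload = {
        "spec": {"variant": fit_result.spec.variant, "n_items": fit_result.spec.n_items,
                 "n_categories": fit_result.spec.n_categories},
        "estimates": _params_to_dict(fit_result.estimates),
        "standard_errors": (_params_to_dict(fit_result.standard_errors)
                            if fit_result.standard_errors is not None else None),
        "loglik": fit_result.loglik,
        "npar": fit_result.npar,
        "converged": fit_result.converged,
        "degenerate": fit_result.degenerate,
        "n_em_iterations": fit_result.n_em_iterations,
        "trace": np.asarray(fit_result.trace).tolist(),
        "message": fit_result.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(**d["spec"])
    return FitResult(
        spec=spec, estimates=_params_from_dict(d["estimates"]),
        standard_errors=(_params_from_dict(d["standard_errors"])
                         if d.get("standard_errors") else None),
        loglik=d["loglik"], npar=d["npar"], converged=d["converged"],
        trace=np.asarray(d.get("trace", [])), degenerate=d.get("degenerate", False),
        n_em_iterations=d.get("n_em_iterations", 0), message=d.get("message", ""),
    )


def write_truth_json(path, truth: ScenarioTruth) -> None:
    d = asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    Path(path).write_text(json.dumps(d, indent=2))


def read_truth_json(path) -> ScenarioTruth:
    d = json.loads(Path(path).read_text())
    for k in ("alpha0", "alpha1", "beta0", "beta1", "nu"):
        if d.get(k) is not None:
            d[k] = np.asarray(d[k], dtype=float)
    return ScenarioTruth(**d)


__all__ = [
    "read_wide_csv", "write_wide_csv", "read_dataset_csv",
    "write_fit_json", "read_fit_json", "write_truth_json", "read_truth_json",
]
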