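"""File formats: response CSV, structure YAML/JSON, fit JSON.

Responses are person-by-item CSV with a header row of item ids and cells
in {0, 1, NA/empty}.  Structures are YAML or JSON with ``n_specific`` and
an ``items`` list of ``{id, specifics: [...]}`` records (1-based factor
indices, empty list for a construct item).  Fits round-trip losslessly as
JSON with full-precision floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimate import FitResult
from .model_core import ModelSpec, ResponseData, build_spec
from .structures import LoadingStructure

__all__ = [
    "read_responses",
    "write_responses",
    "read_structure",
    "write_structure",
    "structure_to_dict",
    "structure_from_dict",
    "write_fit",
    "read_fit",
    "write_eap",
]

FORMAT_VERSION = 1


def read_responses(path) -> ResponseData:
    """Read a person-by-item 0/1 CSV (header row of item ids; NA allowed)."""
    df = pd.read_csv(path)
    if df.shape[1] < 1:
        raise ValueError("response file has no item columns")
    item_ids = [str(c) for c in df.columns]
    X = df.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    bad = obs & ~np.isin(X, [0.0, 1.0])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary response {X[r, c]!r} at row {r + 1}, column {item_ids[c]!r}"
        )
    return ResponseData(X, item_ids=item_ids)


def write_responses(data: ResponseData, path) -> None:
    df = pd.DataFrame(data.X, columns=data.item_ids)
    df.to_csv(path, index=False, na_rep="NA")


def structure_to_dict(structure: LoadingStructure) -> dict:
    return {
        "n_specific": int(structure.n_specific),
        "items": [
            {
                "id": structure.item_labels[i],
                "specifics": structure.specifics_of_item(i),
            }
            for i in range(structure.n_items)
        ],
    }


def structure_from_dict(d: dict) -> LoadingStructure:
    S = int(d["n_specific"])
    items = d["items"]
    loads = np.zeros((len(items), S + 1), dtype=int)
    loads[:, 0] = 1
    labels = []
    for i, rec in enumerate(items):
        labels.append(str(rec.get("id", f"item{i + 1}")))
        for k in rec.get("specifics", []) or []:
            if not (1 <= int(k) <= S):
                raise ValueError(f"item {labels[-1]!r}: specific factor {k} out of range")
            loads[i, int(k)] = 1
    return LoadingStructure(len(items), S, loads, item_labels=labels)


def read_structure(path) -> LoadingStructure:
    """Read a structure file; YAML is a superset of JSON so one reader serves."""
    text = Path(path).read_text()
    return structure_from_dict(yaml.safe_load(text))


def write_structure(structure: LoadingStructure, path) -> None:
    d = structure_to_dict(structure)
    p = Path(path)
    if p.suffix.lower() == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


def fit_to_dict(res: FitResult) -> dict:
    spec = res.spec
    return {
        "format_version": FORMAT_VERSION,
        "family": spec.family,
        "gsm_excluded": spec.gsm_excluded,
        "B": spec.B.B.tolist(),
        "dimension_names": spec.B.dimension_names,
        "A": spec.A.A.tolist(),
        "dropped_items": list(spec.A.dropped_items),
        "pattern_free": spec.pattern.free.tolist(),
        "pattern_ties": None if spec.pattern.ties is None else spec.pattern.ties.tolist(),
        "beta_hat": res.beta_hat.tolist(),
        "beta_reduced": res.beta_reduced.tolist(),
        "mu_hat": res.mu_hat.tolist(),
        "Sigma_hat": res.Sigma_hat.tolist(),
        "loglik": res.loglik,
        "deviance": res.deviance,
        "aic": res.aic,
        "bic": res.bic,
        "n_free": res.n_free,
        "n_persons": res.n_persons,
        "converged": res.converged,
        "n_iter": res.n_iter,
        "history": res.history,
        "warnings": res.warnings_,
        "integration": res.integration,
    }


def write_fit(res: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(res), indent=1))


def read_fit(path) -> FitResult:
    import warnings as _warnings

    from .model_core import CovariancePattern
    from .structures import DesignMatrix, ScoringMatrix

    d = json.loads(Path(path).read_text())
    if d.get("format_version") != FORMAT_VERSION:
        _warnings.warn(
            f"fit file format version {d.get('format_version')} != {FORMAT_VERSION}",
            UserWarning,
            stacklevel=2,
        )
    B = ScoringMatrix(np.array(d["B"]), list(d["dimension_names"]))
    A = DesignMatrix(np.array(d["A"]), dropped_items=list(d["dropped_items"]))
    ties = None if d["pattern_ties"] is None else np.array(d["pattern_ties"])
    pattern = CovariancePattern(B.n_dims, np.array(d["pattern_free"], dtype=bool), ties)
    spec = ModelSpec(d["family"], B, A, pattern, gsm_excluded=d["gsm_excluded"])
    return FitResult(
        spec=spec,
        beta_hat=np.array(d["beta_hat"]),
        beta_reduced=np.array(d["beta_reduced"]),
        mu_hat=np.array(d["mu_hat"]),
        Sigma_hat=np.array(d["Sigma_hat"]),
        loglik=float(d["loglik"]),
        n_free=int(d["n_free"]),
        n_persons=int(d["n_persons"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        history=list(d["history"]),
        warnings_=list(d["warnings"]),
        integration=dict(d["integration"]),
    )


def write_eap(table, data: ResponseData, path) -> None:
    """Person-level EAP CSV: id, one EAP and one posterior-SD column per
    dimension."""
    cols = {"person": data.person_ids}
    for j, name in enumerate(table.dimension_names):
        cols[f"eap_{name}"] = table.eap[:, j]
    for j, name in enumerate(table.dimension_names):
        cols[f"psd_{name}"] = table.psd[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
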