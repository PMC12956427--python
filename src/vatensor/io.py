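"""File formats: dataset CSV, prediction/metric CSVs, truth YAML, manifest.

Dataset CSV layout: header ``id, domain, cause, <symptom columns...>``.
``domain`` is 1 for training rows and 0 for target rows; ``cause`` is a
string label (blank/NA for target rows); symptom cells are 0, 1 or NA
(NA becomes a masked entry).  Cause labels are stored as strings in
files and integer-coded internally; the code book travels with outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import SymptomDataset
from .simulate import SimulationTruth

__all__ = ["read_dataset", "write_dataset", "write_truth", "read_truth",
           "write_manifest"]


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files, naming the offending cell."""


def read_dataset(path: str | Path,
                 cause_names: list[str] | None = None) -> SymptomDataset:
    """Parse and validate a dataset CSV.

    The cause vocabulary is built from the training rows (sorted order)
    unless ``cause_names`` pins it explicitly — required when target
    scoring needs causes that never occur in training.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cause": "string"})
    required = ["id", "domain", "cause"]
    for col in required:
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing column {col!r}")
    symptom_names = [c for c in df.columns if c not in required]
    if not symptom_names:
        raise DatasetFormatError(f"{path}: no symptom columns found")

    D = df["domain"].to_numpy()
    if not np.isin(D, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(D, (0, 1)))[0])
        raise DatasetFormatError(
            f"{path}: row {bad + 2}: domain must be 0 or 1")

    raw = df[symptom_names].to_numpy(dtype=object)
    vals = pd.to_numeric(df[symptom_names].stack(future_stack=True),
                         errors="coerce").to_numpy().reshape(raw.shape)
    mask = ~np.isnan(vals)
    bad_cells = mask & ~np.isin(np.nan_to_num(vals, nan=0.0), (0.0, 1.0))
    # a non-numeric, non-NA token is also invalid
    nonnum = np.array([[isinstance(v, str) and v.strip().upper() not in
                        ("", "NA", "NAN") for v in row] for row in raw])
    bad_cells |= nonnum & ~mask
    if bad_cells.any():
        i, j = np.argwhere(bad_cells)[0]
        raise DatasetFormatError(
            f"{path}: row {i + 2}, column {symptom_names[j]!r}: "
            f"symptom value {raw[i, j]!r} is not 0, 1 or NA")
    X = np.nan_to_num(vals, nan=0.0).astype(np.int8)

    cause_str = df["cause"]
    is_blank = cause_str.isna() | (cause_str.str.strip() == "")
    blank_train = is_blank & (D == 1)
    if blank_train.any():
        bad = int(np.flatnonzero(blank_train)[0])
        raise DatasetFormatError(
            f"{path}: row {bad + 2}: training row has no cause label")
    if cause_names is None:
        cause_names = sorted(cause_str[(D == 1)].dropna().unique())
    code = {name: k for k, name in enumerate(cause_names)}
    Y = np.full(len(df), -1, dtype=np.int64)
    for i, (blank, label) in enumerate(zip(is_blank, cause_str)):
        if blank:
            continue
        if label not in code:
            raise DatasetFormatError(
                f"{path}: row {i + 2}: unknown cause {label!r}")
        Y[i] = code[label]

    return SymptomDataset(
        X=X, Y=Y, D=D, symptom_names=symptom_names,
        cause_names=list(cause_names),
        mask=mask if not mask.all() else None,
    )


def write_dataset(data: SymptomDataset, path: str | Path,
                  hidden_causes: np.ndarray | None = None) -> None:
    """Write a dataset CSV; round-trips through :func:`read_dataset`.

    ``hidden_causes`` optionally fills the cause column of target rows
    (used by truth files for scoring, never by ``fit``).
    """
    path = Path(path)
    n = data.n
    y_out = data.Y.copy()
    if hidden_causes is not None:
        y_out[data.target_index] = hidden_causes
    cause = [data.cause_names[y] if y >= 0 else "" for y in y_out]
    cols: dict[str, Any] = {
        "id": np.arange(1, n + 1),
        "domain": data.D,
        "cause": cause,
    }
    X = data.X.astype(object)
    if data.mask is not None:
        X = np.where(data.mask, X, "NA")
    for j, name in enumerate(data.symptom_names):
        cols[name] = X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Dump all generating parameters (YAML, lists; 1-based indices)."""
    cfg = truth.config
    doc = {
        "config": {
            "C": cfg.C, "p": cfg.p, "n_train": cfg.n_train,
            "n_target": cfg.n_target, "K": cfg.K, "r": cfg.r, "h": cfg.h,
            "scenario": cfg.scenario, "beta_range": list(cfg.beta_range),
            "informative_groups": list(cfg.informative_groups),
            "seed": cfg.seed,
        },
        "pi0": truth.pi0.tolist(),
        "pi1": truth.pi1.tolist(),
        "nu": truth.nu.tolist(),
        "phi": truth.phi.tolist(),
        "s": (truth.s + 1).tolist(),
        "Y": (truth.Y + 1).tolist(),
        "D": truth.D.tolist(),
    }
    if truth.psi_by_domain is not None:
        doc["psi_by_domain"] = truth.psi_by_domain.tolist()
    else:
        doc["psi"] = truth.psi.tolist()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth(path: str | Path) -> dict[str, Any]:
    doc = yaml.safe_load(Path(path).read_text())
    for key in ("pi0", "pi1", "nu", "phi", "psi", "psi_by_domain", "Y", "D", "s"):
        if key in doc:
            doc[key] = np.asarray(doc[key])
    if "s" in doc:
        doc["s"] = doc["s"] - 1
    if "Y" in doc:
        doc["Y"] = doc["Y"] - 1
    return doc


def write_manifest(path: str | Path, command: str,
                   config: dict[str, Any]) -> None:
    """JSON run manifest: command, configuration, library versions."""
    import vatensor

    doc = {
        "command": command,
        "config": config,
        "versions": {
            "vatensor": vatensor.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
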