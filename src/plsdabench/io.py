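"""CSV/JSON interchange: matrices, labels, manifests and fitted models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .synthetic import LabeledDataset

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_dataset",
    "model_to_json",
]


def read_matrix_csv(path, sep: str | None = None) -> pd.DataFrame:
    """Samples x features table: header row of feature ids, first column sample ids."""
    sep = sep or ("\t" if str(path).endswith((".tsv", ".tab")) else ",")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise InvalidInputError(f"{path}: matrix contains missing values")
    if df.columns.duplicated().any():
        raise InvalidInputError(f"{path}: duplicate feature identifiers")
    return df


def write_matrix_csv(path, X, sample_ids, feature_ids, sep: str = ","):
    pd.DataFrame(np.asarray(X), index=sample_ids, columns=feature_ids).to_csv(
        path, sep=sep, index_label="sample_id"
    )


def read_labels_csv(path) -> pd.Series:
    """Two-column CSV (sample_id, label) -> Series indexed by sample id."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise InvalidInputError(f"{path}: expected exactly one label column")
    return df.iloc[:, 0]


def write_labels_csv(path, y, sample_ids):
    pd.DataFrame({"label": np.asarray(y)}, index=sample_ids).to_csv(
        path, index_label="sample_id"
    )


def write_dataset(data: LabeledDataset, out_dir):
    """Write X.csv, y.csv and manifest.json for a generated dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(out / "X.csv", data.X, data.sample_ids, data.feature_ids)
    write_labels_csv(out / "y.csv", data.y, data.sample_ids)
    manifest = {
        "model": data.spec.model,
        "params": {
            "n": data.spec.n,
            "m": data.spec.m,
            "s": data.spec.s,
            "C": data.spec.C,
            "sep": data.spec.sep,
            "p": data.spec.p,
            "preset": data.spec.preset,
            "cluster_sd": data.spec.cluster_sd,
        },
        "seed": data.spec.seed,
        "signal_indices": np.asarray(data.truth.signal_indices).tolist(),
        "true_loading": np.asarray(data.truth.true_loading).tolist(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def model_to_json(model, path=None, seed: int | None = None):
    """Serialize a fitted model's weights, loadings, importances and means."""
    payload = {
        "method": model.method,
        "weights": model.weights_.tolist(),
        "loadings": model.loadings_.tolist(),
        "component_importance": model.component_importance_.tolist(),
        "centering_means": model.mean_.tolist(),
        "seed": seed,
    }
    if hasattr(model, "y_loadings_"):
        payload["y_loadings"] = model.y_loadings_.tolist()
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload
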