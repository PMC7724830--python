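"""Experiment grids: the four synthetic studies behind the benchmark surfaces.

Each study sweeps a parameter grid, regenerates a fresh ground-truthed
dataset per (cell, repeat) from a hashed seed (so any single cell is
reproducible in isolation), applies the requested methods, and tabulates
the mean and standard deviation of the metric over repeats in a
long-format :class:`pandas.DataFrame` ("surface table") with columns
``(axis1, axis2, method, metric, mean, sd, repeats)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import (
    CVConfig,
    apparent_separability,
    cosine_distance,
    make_estimator,
    repeated_cv_error,
    select_top_features,
    selection_confusion,
)
from .exceptions import InvalidInputError
from .methods import PLSDA
from .synthetic import GeneratorSpec, generate, true_loading_vector

__all__ = [
    "GridSpec",
    "grid_feature_selection",
    "loading_recovery",
    "classifier_study",
    "separability_study",
    "parse_ratio",
]

#: default grid axes spanning the regimes the studies describe
DEFAULT_N_AXIS = (50, 100, 200, 500, 1000)
DEFAULT_M_AXIS = (20, 50, 100, 500, 2000)
DEFAULT_S_AXIS = (1, 2, 5, 10, 20)


@dataclass
class GridSpec:
    """A two-axis experiment grid over one synthetic model."""

    model: str
    methods: Sequence[str] = ("pca", "plsda")
    axes: dict = field(default_factory=dict)  # e.g. {"n": [...], "m": [...]}
    fixed: dict = field(default_factory=dict)  # e.g. {"s": 10, "n": 200}
    repeats: int = 20
    base_seed: int = 0

    def __post_init__(self):
        if not self.axes or len(self.axes) > 2:
            raise InvalidInputError("axes must name one or two swept parameters")
        if self.repeats < 1:
            raise InvalidInputError("repeats must be >= 1")

    def cells(self):
        names = list(self.axes)
        if len(names) == 1:
            names = names + [None]
            values = [(v, None) for v in self.axes[names[0]]]
        else:
            values = list(product(self.axes[names[0]], self.axes[names[1]]))
        return names, values


def _cell_seed(base_seed: int, i: int, j: int, r: int) -> int:
    """Stable per-(cell, repeat) seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), i, j, r])
    return int(ss.generate_state(1)[0] % (2**31))


def _cell_spec(grid: GridSpec, names, cell) -> dict:
    params = dict(grid.fixed)
    params["model"] = grid.model
    for name, value in zip(names, cell):
        if name is not None:
            params[name] = value
    params.pop("n_components", None)
    return params


def _surface_rows(records: dict, names, repeats: int) -> pd.DataFrame:
    rows = []
    for (cell, method, metric), vals in records.items():
        vals = np.asarray(vals, dtype=float)
        rows.append(
            {
                "axis1": names[0],
                "axis1_value": cell[0],
                "axis2": names[1],
                "axis2_value": cell[1],
                "method": method,
                "metric": metric,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                "repeats": vals.size,
            }
        )
    return pd.DataFrame(rows)


def grid_feature_selection(grid: GridSpec) -> pd.DataFrame:
    """Per cell: select top-s features with each method, score precision.

    The selection size always equals the cell's signal count s, so the
    precision = recall identity holds on every record and only precision
    is tabulated.
    """
    names, cells = grid.cells()
    records: dict = {}
    ncomp = int(grid.fixed.get("n_components", 1))
    for (i, j), cell in zip(product_indices(cells), cells):
        for r in range(grid.repeats):
            seed = _cell_seed(grid.base_seed, i, j, r)
            params = _cell_spec(grid, names, cell)
            params["seed"] = seed
            spec = GeneratorSpec(**params)
            data = generate(spec)
            for method in grid.methods:
                est = make_estimator(
                    method, n_components=ncomp, keep=spec.s, seed=seed
                )
                est.fit(data.X, data.y)
                selected = select_top_features(est, spec.s)
                conf = selection_confusion(selected, data.truth, spec.m)
                records.setdefault((cell, method, "precision"), []).append(
                    conf.precision
                )
    return _surface_rows(records, names, grid.repeats)


def loading_recovery(grid: GridSpec) -> pd.DataFrame:
    """Per cell: cosine distance between the first fitted weight vector and
    the manifest's (unit-norm) true loading, averaged over repeats."""
    if grid.model != "linear":
        raise InvalidInputError("loading recovery is defined for the linear model")
    names, cells = grid.cells()
    records: dict = {}
    for (i, j), cell in zip(product_indices(cells), cells):
        for r in range(grid.repeats):
            seed = _cell_seed(grid.base_seed, i, j, r)
            params = _cell_spec(grid, names, cell)
            params["seed"] = seed
            spec = GeneratorSpec(**params)
            data = generate(spec)
            truth_vec = true_loading_vector(data.truth)
            for method in grid.methods:
                est = make_estimator(method, n_components=1, keep=spec.s, seed=seed)
                est.fit(data.X, data.y)
                dist = cosine_distance(est.weights_[:, 0], truth_vec)
                records.setdefault((cell, method, "cosine_distance"), []).append(dist)
    return _surface_rows(records, names, grid.repeats)


def classifier_study(grid: GridSpec, cfg: CVConfig | None = None) -> pd.DataFrame:
    """Per cell: repeated cross-validated classification error per method."""
    cfg = cfg or CVConfig()
    names, cells = grid.cells()
    records: dict = {}
    for (i, j), cell in zip(product_indices(cells), cells):
        for r in range(grid.repeats):
            seed = _cell_seed(grid.base_seed, i, j, r)
            params = _cell_spec(grid, names, cell)
            params["seed"] = seed
            spec = GeneratorSpec(**params)
            data = generate(spec)
            for method in grid.methods:
                est = make_estimator(
                    method, n_components=cfg.ncomp, keep=spec.s, seed=seed
                )
                rep_cfg = CVConfig(
                    folds=cfg.folds,
                    repetitions=cfg.repetitions,
                    ncomp=cfg.ncomp,
                    stratified=cfg.stratified,
                    seed=seed,
                )
                mean_err, _ = repeated_cv_error(est, data.X, data.y, rep_cfg)
                records.setdefault((cell, method, "cv_error"), []).append(mean_err)
    return _surface_rows(records, names, grid.repeats)


def parse_ratio(ratio) -> tuple[int, int]:
    """Accept '1:20' strings or (1, 20) tuples."""
    if isinstance(ratio, str):
        a, b = ratio.split(":")
        return int(a), int(b)
    a, b = ratio
    return int(a), int(b)


def separability_study(
    ratios: Sequence,
    cfg: CVConfig | None = None,
    n: int = 100,
    n_seeds: int = 1,
    base_seed: int = 0,
    include_cv: bool = True,
) -> pd.DataFrame:
    """Randomly labeled uniform data at a sweep of n:m ratios.

    For each ratio the feature count is ``m = n * b / a`` and, per seed,
    a one-component PLS-DA is fitted to report the apparent separability
    of its first component; optionally the repeated-CV error of the same
    model is measured (``cfg.repetitions`` repetitions of
    ``cfg.folds``-fold CV).  Returns a long-format table with one row
    per (ratio, metric).
    """
    cfg = cfg or CVConfig()
    rows = []
    for k, ratio in enumerate(ratios):
        a, b = parse_ratio(ratio)
        m = int(round(n * b / a))
        seps, cvs = [], []
        for s_idx in range(n_seeds):
            seed = _cell_seed(base_seed, k, 0, s_idx)
            spec = GeneratorSpec(model="random_labels", n=n, m=m, s=0, seed=seed)
            data = generate(spec)
            model = PLSDA(n_components=1).fit(data.X, data.y)
            seps.append(apparent_separability(model, data.y))
            if include_cv:
                rep_cfg = CVConfig(
                    folds=cfg.folds,
                    repetitions=cfg.repetitions,
                    ncomp=1,
                    stratified=cfg.stratified,
                    seed=seed,
                )
                mean_err, _ = repeated_cv_error("plsda", data.X, data.y, rep_cfg)
                cvs.append(mean_err)
        metrics = {"apparent_separability": seps}
        if include_cv:
            metrics["cv_error"] = cvs
        for metric, vals in metrics.items():
            vals = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "ratio": f"{a}:{b}",
                    "n": n,
                    "m": m,
                    "method": "plsda",
                    "metric": metric,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "repeats": vals.size,
                }
            )
    return pd.DataFrame(rows)


def product_indices(cells):
    """Stable (i, j) indices for the cell list produced by GridSpec.cells()."""
    seen1: dict = {}
    seen2: dict = {}
    out = []
    for c1, c2 in cells:
        i = seen1.setdefault(c1, len(seen1))
        j = seen2.setdefault(c2, len(seen2))
        out.append((i, j))
    return out
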