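"""Climate-space reduction and δ18O-covariate hindcasting.

The paleodistribution engine reduces correlated climate layers to a few
principal-component axes fitted on the present-day climate, projects the
anchor paleoclimates onto the same axes (standardized with present-day
means and scales), regresses each cell's axis values on the δ18O forcing
across anchor times (ordinary least squares, 2 parameters), and evaluates
the fitted lines along the forcing curve to hindcast climate on a dense
time grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import ClimateStack, ForcingCurve

__all__ = [
    "PcaLoadings",
    "ForcingFit",
    "climate_pca",
    "project_anchor",
    "fit_forcing_interpolation",
    "hindcast_axes",
    "default_time_grid",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaLoadings:
    """PCA fitted on present-day climate cells (z-scored per variable)."""

    variables: list[str]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (n_axes, n_vars)
    explained_variance_ratio: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project raw climate vectors (n, n_vars) onto the axes."""
        Z = (X - self.mean) / self.scale
        return Z @ self.components.T


def climate_pca(
    current: ClimateStack, n_axes: int = 5
) -> tuple[PcaLoadings, ClimateStack]:
    """PCA of the present-day climate; returns loadings and the axis stack.

    Cells are standardized (z-score over valid cells) before the
    decomposition; constant layers are dropped with a warning.  Axis signs
    follow the largest-|loading|-positive convention.
    """
    variables = current.variables
    X = current.to_table()
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        logger.warning("dropping constant layers: %s", dropped)
        variables = [v for v, k in zip(variables, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    if n_axes > len(variables):
        raise ValueError("more axes requested than (non-constant) variables")
    mean = X.mean(axis=0)
    Z = (X - mean) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for j in range(n_axes):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    var = s**2
    loadings = PcaLoadings(
        variables=variables,
        mean=mean,
        scale=sd,
        components=Vt[:n_axes],
        explained_variance_ratio=var[:n_axes] / var.sum(),
    )
    return loadings, project_anchor(current, loadings)


def project_anchor(anchor: ClimateStack, loadings: PcaLoadings) -> ClimateStack:
    """Axis stack at an anchor time, standardized with present-day stats."""
    missing = [v for v in loadings.variables if v not in anchor.layers]
    if missing:
        raise ValueError(f"anchor is missing layers: {missing}")
    X = np.column_stack([anchor.layers[v][anchor.mask] for v in loadings.variables])
    scores = loadings.transform(X)
    layers: dict[str, np.ndarray] = {}
    for j in range(loadings.n_axes):
        layer = np.full(anchor.shape, np.nan)
        layer[anchor.mask] = scores[:, j]
        layers[f"pc{j + 1}"] = layer
    return ClimateStack(
        grid=anchor.grid, layers=layers, time=anchor.time, mask=anchor.mask.copy()
    )


@dataclass
class ForcingFit:
    """Per-cell, per-axis OLS coefficients of axis value on δ18O."""

    template: ClimateStack          # grid/mask/axis-name template
    intercept: np.ndarray           # (n_axes, n_rows, n_cols)
    slope: np.ndarray               # (n_axes, n_rows, n_cols)
    axis_names: list[str]

    def predict(self, d18o: float, time: float) -> ClimateStack:
        layers = {
            name: self.intercept[j] + self.slope[j] * d18o
            for j, name in enumerate(self.axis_names)
        }
        return self.template.with_layers(layers, time=time)


def fit_forcing_interpolation(
    anchors: list[ClimateStack], forcing: ForcingCurve
) -> ForcingFit:
    """OLS of each cell's axis values on δ18O across anchor times."""
    if len(anchors) < 2:
        raise ValueError("need at least two anchor stacks")
    f = np.array([float(forcing.at(a.time)) for a in anchors])
    if np.unique(f).size < 2:
        raise ValueError("anchors must span at least two distinct forcing values")
    names = anchors[0].variables
    shape = anchors[0].shape
    for a in anchors[1:]:
        if a.variables != names or a.shape != shape:
            raise ValueError("anchor stacks must share axes and grid")

    A = np.column_stack([np.ones_like(f), f])          # (n_anchors, 2)
    n_axes = len(names)
    intercept = np.empty((n_axes,) + shape)
    slope = np.empty((n_axes,) + shape)
    for j, name in enumerate(names):
        Y = np.stack([a.layers[name] for a in anchors])  # (n_anchors, r, c)
        Yf = Y.reshape(len(anchors), -1)
        coef, *_ = np.linalg.lstsq(A, Yf, rcond=None)
        intercept[j] = coef[0].reshape(shape)
        slope[j] = coef[1].reshape(shape)
    return ForcingFit(
        template=anchors[0], intercept=intercept, slope=slope, axis_names=names
    )


def default_time_grid() -> np.ndarray:
    """1-ky steps from 0 to 600 plus 2-ky steps from 602 to 786 (694 slices)."""
    return np.concatenate([np.arange(0.0, 601.0, 1.0), np.arange(602.0, 787.0, 2.0)])


def hindcast_axes(
    fit: ForcingFit, forcing: ForcingCurve, time_grid: np.ndarray | None = None
) -> list[ClimateStack]:
    """Axis stacks along the time grid: axis(t) = intercept + slope·δ18O(t)."""
    if time_grid is None:
        time_grid = default_time_grid()
    stacks = []
    for t in np.asarray(time_grid, dtype=float):
        d18o = float(forcing.at(t))   # raises outside the forcing domain
        stacks.append(fit.predict(d18o, time=t))
    return stacks
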