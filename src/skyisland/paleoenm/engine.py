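"""End-to-end paleodistribution pipeline.

Chains the stages: PCA reduction of present-day climate → anchor
projection → per-cell δ18O regression → dense hindcast → presence/test
split → five presence-only models → max-SSS thresholds → committee
ensemble per time slice.  The result is an :class:`EnsembleSeries` ready
for Marine-Isotope-Stage compositing and range metrics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .climate import (
    climate_pca,
    default_time_grid,
    fit_forcing_interpolation,
    hindcast_axes,
    project_anchor,
)
from .evaluate import (
    EnsembleSeries,
    evaluate,
    max_sss_threshold,
    split_occurrences,
)
from .grids import ClimateStack, ForcingCurve, OccurrenceSet
from .models import ALGORITHMS, NicheModel, fit_model

__all__ = ["predict_stack", "sample_background", "run_paleo_ensemble"]

logger = logging.getLogger(__name__)


def predict_stack(model: NicheModel, stack: ClimateStack) -> np.ndarray:
    """Suitability map of a fitted model over a climate/axis stack."""
    out = np.full(stack.shape, np.nan)
    out[stack.mask] = model.predict(stack.to_table())
    return out


def sample_background(
    stack: ClimateStack, n: int = 10_000, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random non-masked cells (all cells when fewer than ``n``).

    Returns (rows, cols) of the sampled cells.
    """
    rows, cols = np.nonzero(stack.mask)
    if rows.size > n:
        rng = np.random.default_rng(seed)
        pick = rng.choice(rows.size, size=n, replace=False)
        rows, cols = rows[pick], cols[pick]
    return rows, cols


def loo_presence_scores(
    algorithm: str,
    train_X: np.ndarray,
    background_X: np.ndarray | None,
    train_cells: tuple[np.ndarray, np.ndarray] | None = None,
    buffer_cells: int = 3,
) -> np.ndarray:
    """Spatially buffered leave-one-out suitability of each training presence.

    Memorizing algorithms (domain's Gower similarity in particular) score
    their own training points — and, through spatial autocorrelation,
    their neighbors' — almost perfectly, which drives the max-SSS
    threshold to a cutoff no genuinely fresh suitable cell can reach.
    Scoring each presence with a model fitted on the presences OUTSIDE a
    ``buffer_cells`` Chebyshev radius (spatial block cross-validation in
    miniature) yields the transfer-honest score distribution.  Falls back
    to plain leave-one-out, then to in-sample scores, when too few
    presences remain.
    """
    n = train_X.shape[0]
    if n - 1 < 5:
        model = fit_model(algorithm, train_X, background_X)
        return model.predict(train_X)
    rows = cols = None
    if train_cells is not None:
        rows, cols = train_cells
    scores = np.empty(n)
    for i in range(n):
        if rows is not None:
            near = (np.abs(rows - rows[i]) <= buffer_cells) & (
                np.abs(cols - cols[i]) <= buffer_cells
            )
            keep = ~near
        else:
            keep = np.ones(n, dtype=bool)
            keep[i] = False
        if keep.sum() < 5:
            keep = np.ones(n, dtype=bool)
            keep[i] = False
        model = fit_model(algorithm, train_X[keep], background_X)
        scores[i] = model.predict(train_X[i][None, :])[0]
    return scores


def run_paleo_ensemble(
    anchors: list[ClimateStack],
    forcing: ForcingCurve,
    occurrences: OccurrenceSet,
    n_axes: int = 5,
    time_grid: np.ndarray | None = None,
    background_size: int = 10_000,
    votes_required: int | None = None,
    train_fraction: float = 0.7,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int | None = None,
) -> EnsembleSeries:
    """Hindcast ensemble distribution maps across the full time grid.

    ``anchors`` are raw-variable climate stacks at the anchor times (one
    of them must be the present, time 0); occurrences are grid-
    deduplicated, split 70/30, models are fitted on present-day PCA axes
    at the training cells, thresholded by max-SSS against a seeded
    background sample, and each hindcast slice is binarized and combined
    by committee vote.
    """
    try:
        present = next(a for a in anchors if a.time == 0.0)
    except StopIteration:
        raise ValueError("anchors must include the present (time 0)") from None

    rng = np.random.default_rng(seed)
    loadings, _ = climate_pca(present, n_axes=n_axes)
    anchor_axes = [project_anchor(a, loadings) for a in anchors]
    present_axes = next(a for a in anchor_axes if a.time == 0.0)
    fit = fit_forcing_interpolation(anchor_axes, forcing)
    if time_grid is None:
        time_grid = default_time_grid()
    slices = hindcast_axes(fit, forcing, time_grid)

    occ = occurrences if occurrences.deduplicated else occurrences.dedup_on_grid(
        present.grid
    )
    train, test = split_occurrences(
        occ, train_fraction=train_fraction, seed=int(rng.integers(2**31 - 1))
    )
    tr_rows, tr_cols = train.cells(present.grid)
    te_rows, te_cols = test.cells(present.grid)
    train_X = present_axes.values_at_cells(tr_rows, tr_cols)

    bg_rows, bg_cols = sample_background(
        present_axes, n=background_size, seed=int(rng.integers(2**31 - 1))
    )
    background_X = present_axes.values_at_cells(bg_rows, bg_cols)

    models: dict[str, NicheModel] = {}
    thresholds: dict[str, float] = {}
    eval_rows = []
    for algo in algorithms:
        model = fit_model(algo, train_X, background_X)
        train_scores = loo_presence_scores(
            algo, train_X, background_X, train_cells=(tr_rows, tr_cols)
        )
        bg_scores = model.predict(background_X)
        thr = max_sss_threshold(train_scores, bg_scores)
        suit_present = predict_stack(model, present_axes)
        res = evaluate(suit_present, thr, te_rows, te_cols)
        models[algo] = model
        thresholds[algo] = thr
        eval_rows.append(
            {
                "algorithm": algo,
                "threshold": thr,
                "tpr": res.tpr,
                "pi": res.predicted_area_fraction,
                "d_stat": res.d_stat,
            }
        )
        logger.info(
            "fitted %s: threshold=%.4f TPR=%.3f pi=%.3f D=%.3f",
            algo, thr, res.tpr, res.predicted_area_fraction, res.d_stat,
        )

    n_times = len(slices)
    shape = present.shape
    A = len(algorithms)
    rule = votes_required if votes_required is not None else -(-A // 2)
    per_algo = {a: np.full((n_times,) + shape, np.nan) for a in algorithms}
    consensus = np.full((n_times,) + shape, np.nan)
    for k, stack in enumerate(slices):
        binaries = []
        for algo in algorithms:
            suit = predict_stack(models[algo], stack)
            binary = np.where(np.isnan(suit), np.nan,
                              (suit >= thresholds[algo]).astype(float))
            per_algo[algo][k] = binary
            binaries.append(binary)
        votes = np.nansum(np.stack(binaries), axis=0)
        cons = (votes >= rule).astype(float)
        cons[~stack.mask] = np.nan
        consensus[k] = cons

    if float(np.asarray(time_grid)[0]) == 0.0:
        cons0 = consensus[0]
        tpr = float(np.mean(cons0[te_rows, te_cols] == 1.0))
        pi = float(np.nanmean(cons0))
        eval_rows.append(
            {
                "algorithm": "ensemble",
                "threshold": np.nan,
                "tpr": tpr,
                "pi": pi,
                "d_stat": tpr * (1.0 - pi),
            }
        )

    return EnsembleSeries(
        times=np.asarray(time_grid, dtype=float),
        consensus=consensus,
        per_algorithm_binary=per_algo,
        thresholds=thresholds,
        evaluations=pd.DataFrame(eval_rows),
        votes_required=rule,
        grid=present.grid,
    )
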