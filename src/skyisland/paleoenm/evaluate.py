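"""Model evaluation, thresholding, ensembles and range dynamics.

Continuous suitability maps are binarized at the threshold maximizing
sensitivity + specificity (max-SSS), evaluated with the presence-only
D statistic D = TPR × (1 − π) — the true-positive rate on test presences
discounted by the proportional predicted area π — and combined across
algorithms by a committee (majority) vote.  Hindcast series are composited
over glacial and interglacial Marine Isotope Stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateStack, GridSpec, OccurrenceSet

__all__ = [
    "EvaluationResult",
    "EnsembleSeries",
    "MisTable",
    "split_occurrences",
    "evaluate",
    "max_sss_threshold",
    "ensemble_consensus",
    "load_mis_table",
    "mis_aggregate",
    "range_metrics",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


# ----------------------------------------------------------------------
# Train/test split
# ----------------------------------------------------------------------

def split_occurrences(
    occ: OccurrenceSet, train_fraction: float = 0.7, seed: int | None = None
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random 70/30 (by default) split; train size = round(f·n)."""
    n = occ.n_points
    if n < 4:
        raise ValueError("need at least four occurrence points to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]

    def _take(idx):
        return OccurrenceSet(
            species=occ.species, lon=occ.lon[idx], lat=occ.lat[idx],
            deduplicated=occ.deduplicated,
        )

    return _take(np.sort(tr)), _take(np.sort(te))


# ----------------------------------------------------------------------
# D statistic and max-SSS threshold
# ----------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Presence-only evaluation: D = TPR × (1 − π)."""

    tpr: float
    predicted_area_fraction: float
    d_stat: float
    threshold: float


def evaluate(
    suitability: np.ndarray,
    threshold: float,
    test_rows: np.ndarray,
    test_cols: np.ndarray,
) -> EvaluationResult:
    """Evaluate a suitability map against held-out presences.

    TPR is the fraction of test presences at or above the threshold; π the
    fraction of non-masked cells at or above it.
    """
    valid = ~np.isnan(suitability)
    if not valid.any():
        raise ValueError("all cells are masked")
    if len(test_rows) < 1:
        raise ValueError("need at least one test presence")
    tpr = float(np.mean(suitability[test_rows, test_cols] >= threshold))
    pi = float(np.mean(suitability[valid] >= threshold))
    return EvaluationResult(
        tpr=tpr, predicted_area_fraction=pi, d_stat=tpr * (1.0 - pi),
        threshold=threshold,
    )


def max_sss_threshold(
    presence_scores: np.ndarray, absence_scores: np.ndarray
) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores; sensitivity = fraction of
    presences ≥ t, specificity = fraction of (pseudo-)absences < t.  Ties
    resolve to the lowest (most inclusive) threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size < 1 or a.size < 1:
        raise ValueError("need at least one presence and one absence score")
    candidates = np.unique(np.concatenate([p, a]))
    best_t, best_ss = candidates[0], -np.inf
    for t in candidates:
        sens = (p >= t).mean()
        spec = (a < t).mean()
        ss = sens + spec
        if ss > best_ss + 1e-12:
            best_ss, best_t = ss, t
    return float(best_t)


# ----------------------------------------------------------------------
# Ensemble
# ----------------------------------------------------------------------

def ensemble_consensus(
    binary_maps: list[np.ndarray], votes_required: int | None = None
) -> np.ndarray:
    """Committee consensus: cell = 1 iff votes ≥ rule (default majority).

    With A algorithms the default is ⌈A/2⌉ votes (3 of 5).  Masked (NaN)
    cells stay masked.
    """
    if not binary_maps:
        raise ValueError("need at least one binary map")
    shape = binary_maps[0].shape
    for m in binary_maps[1:]:
        if m.shape != shape:
            raise ValueError("binary maps must share a grid")
    A = len(binary_maps)
    rule = votes_required if votes_required is not None else -(-A // 2)
    stack = np.stack([np.asarray(m, dtype=float) for m in binary_maps])
    votes = np.nansum(stack, axis=0)
    consensus = (votes >= rule).astype(float)
    masked = np.all(np.isnan(stack), axis=0)
    consensus[masked] = np.nan
    return consensus


@dataclass
class EnsembleSeries:
    """Per-time-slice consensus maps plus per-algorithm artefacts."""

    times: np.ndarray
    consensus: np.ndarray                  # (n_times, rows, cols), NaN masked
    per_algorithm_binary: dict[str, np.ndarray]
    thresholds: dict[str, float]
    evaluations: pd.DataFrame
    votes_required: int
    grid: GridSpec

    def area_fraction(self) -> np.ndarray:
        """Predicted-presence fraction of valid cells per time slice."""
        flat = self.consensus.reshape(len(self.times), -1)
        return np.nanmean(flat, axis=1)


# ----------------------------------------------------------------------
# Marine Isotope Stages
# ----------------------------------------------------------------------

@dataclass
class MisTable:
    """Glacial/interglacial stage boundaries (ky BP), non-overlapping."""

    stages: pd.DataFrame   # columns: name, start_ky, end_ky, type

    def __post_init__(self) -> None:
        s = self.stages.sort_values("start_ky").reset_index(drop=True)
        if not set(s["type"]).issubset({"glacial", "interglacial"}):
            raise ValueError("stage type must be glacial or interglacial")
        starts, ends = s["start_ky"].to_numpy(), s["end_ky"].to_numpy()
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("stages overlap")
        self.stages = s

    def type_of(self, t: float) -> str:
        s = self.stages
        hit = s[(s["start_ky"] <= t) & (t <= s["end_ky"])]
        if hit.empty:
            raise ValueError(f"time {t} ky not covered by any stage")
        return str(hit.iloc[0]["type"])

    @classmethod
    def from_forcing(
        cls, forcing, threshold: float | None = None
    ) -> "MisTable":
        """Delimit stages directly from a δ18O curve.

        Marine Isotope Stages are defined as alternating excursions of
        the benthic δ18O stack; this classifies each time step as glacial
        (δ18O above ``threshold``, default the curve's midrange) or
        interglacial and merges contiguous runs into stages.  This is the
        appropriate table for a synthetic forcing whose cycles do not
        follow the observed record.
        """
        if threshold is None:
            threshold = float((forcing.values.max() + forcing.values.min()) / 2.0)
        kinds = np.where(forcing.values >= threshold, "glacial", "interglacial")
        rows = []
        start = forcing.times[0]
        for k in range(1, len(kinds) + 1):
            if k == len(kinds) or kinds[k] != kinds[k - 1]:
                end = forcing.times[k] if k < len(kinds) else forcing.times[-1]
                rows.append(
                    {
                        "name": f"S{len(rows) + 1}",
                        "start_ky": float(start),
                        "end_ky": float(end),
                        "type": kinds[k - 1],
                    }
                )
                start = end
        return cls(pd.DataFrame(rows))


def load_mis_table() -> MisTable:
    """Packaged LR04-derived stage table (0–790 ky, MIS 1–19)."""
    with resources.files("skyisland.paleoenm").joinpath("data/mis_lr04.csv").open() as fh:
        return MisTable(pd.read_csv(fh))


def mis_aggregate(
    series: EnsembleSeries,
    mis: MisTable | None = None,
    frequency_threshold: float = 0.5,
) -> dict:
    """Glacial and interglacial composites of a hindcast series.

    Per period type and cell: the frequency of predicted presence across
    the slices of that type, plus a binary composite at
    ``frequency_threshold``.
    """
    if mis is None:
        mis = load_mis_table()
    types = np.array([mis.type_of(t) for t in series.times])
    out: dict = {}
    for kind in ("glacial", "interglacial"):
        sel = series.consensus[types == kind]
        if sel.shape[0] == 0:
            raise ValueError(f"no time slices fall in {kind} stages")
        freq = np.nanmean(sel, axis=0)
        out[f"{kind}_frequency"] = freq
        out[f"{kind}_composite"] = np.where(
            np.isnan(freq), np.nan, (freq >= frequency_threshold).astype(float)
        )
        out[f"n_{kind}_slices"] = int(sel.shape[0])
    return out


# ----------------------------------------------------------------------
# Range metrics
# ----------------------------------------------------------------------

def _cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Latitude-corrected cell areas (km²) per row, broadcast to the grid."""
    km_per_deg = 111.32
    lat = np.deg2rad(grid.lat_centers)
    row_area = (grid.cellsize * km_per_deg) ** 2 * np.cos(lat)
    return np.repeat(row_area[:, None], grid.n_cols, axis=1)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    filled = np.where(np.isnan(binary), 0, binary).astype(int)
    labels, n = ndimage.label(filled, structure=_EIGHT_CONNECTED)
    if n == 0:
        return np.zeros_like(filled, dtype=bool)
    sizes = ndimage.sum(filled, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def range_metrics(
    map_a: np.ndarray, map_b: np.ndarray, grid: GridSpec
) -> dict:
    """Areas, overlap, and an 8-connected corridor flag for two range maps.

    The corridor flag is true iff one connected component of the union of
    suitable cells touches both species' core ranges (each core = the
    largest component of that species' own map).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    areas = _cell_areas_km2(grid)
    a = np.where(np.isnan(map_a), 0, map_a).astype(bool)
    b = np.where(np.isnan(map_b), 0, map_b).astype(bool)

    def _area(mask: np.ndarray) -> tuple[int, float]:
        return int(mask.sum()), float(areas[mask].sum())

    cells_a, km2_a = _area(a)
    cells_b, km2_b = _area(b)
    cells_ov, km2_ov = _area(a & b)

    corridor = False
    if cells_a and cells_b:
        core_a = _largest_component(map_a)
        core_b = _largest_component(map_b)
        union = a | b
        labels, n = ndimage.label(union.astype(int), structure=_EIGHT_CONNECTED)
        for comp in range(1, n + 1):
            mask = labels == comp
            if (mask & core_a).any() and (mask & core_b).any():
                corridor = True
                break
    return {
        "area_cells_a": cells_a, "area_km2_a": km2_a,
        "area_cells_b": cells_b, "area_km2_b": km2_b,
        "overlap_cells": cells_ov, "overlap_km2": km2_ov,
        "corridor": corridor,
    }
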