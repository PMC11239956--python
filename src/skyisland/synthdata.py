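"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline's input classes:

* hierarchical SNP genotypes from a nested Balding–Nichols model, with
  direct control of between-group (F_CT) and between-population-within-
  group (F_SC) differentiation;
* aligned mtDNA barcodes in which two nominal species either share the
  ancestral haplotype (no barcode gap) or descend from diverged ancestors
  (a clean gap);
* a smooth multi-variable climate world whose past states are an exact
  affine function of a cyclic δ18O-like forcing curve, plus a Gaussian
  niche "truth" map and presence points sampled from it.

Every generator is a pure function of its spec: the same seed reproduces
output bit for bit.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix
from .sequences import SequenceAlignment
from .paleoenm.grids import ClimateStack, ForcingCurve, GridSpec, OccurrenceSet

__all__ = [
    "SimGenotypeSpec",
    "SimNicheSpec",
    "ClimateWorld",
    "simulate_hierarchical_genotypes",
    "simulate_barcode_alignment",
    "simulate_shared_haplotype_alignment",
    "simulate_gapped_alignment",
    "simulate_climate_history",
]

_BASES = np.array(list("ACGT"))


# ----------------------------------------------------------------------
# Genotypes: nested Balding–Nichols
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SimGenotypeSpec:
    """Nested island-model genotype simulation parameters.

    ``fct_target`` is the Balding–Nichols differentiation of group allele
    frequencies around the ancestral frequency; ``fsc_target`` that of
    population frequencies around their group's.  Either may be 0, in
    which case the frequency passes through unchanged.
    """

    n_groups: int = 2
    pops_per_group: int = 3
    inds_per_pop: int = 20
    n_loci: int = 2000
    fct_target: float = 0.30
    fsc_target: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "pops_per_group", "inds_per_pop", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.fct_target < 1.0 and 0.0 <= self.fsc_target < 1.0):
            raise ValueError("targets must lie in [0, 1)")
        if self.fct_target + self.fsc_target >= 1.0:
            raise ValueError("fct_target + fsc_target must be < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw frequencies around ``p`` with differentiation ``f`` (pass-through at 0)."""
    if f == 0.0:
        return p.copy()
    # beta draws can land exactly on 0/1 in floating point; keep the next
    # nesting level's shape parameters strictly positive
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_hierarchical_genotypes(spec: SimGenotypeSpec) -> GenotypeMatrix:
    """Genotypes from the nested Balding–Nichols model.

    Per locus: ancestral frequency p0 ~ Uniform(0.1, 0.9); group frequency
    ~ Beta around p0 at ``fct_target``; population frequency ~ Beta around
    the group's at ``fsc_target``; genotypes ~ Binomial(2, p_pop).
    Entries are set missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    p0 = rng.uniform(0.1, 0.9, size=L)

    genotypes = []
    individual_ids: list[str] = []
    population: list[str] = []
    group: list[str] = []
    for gi in range(spec.n_groups):
        g_name = f"G{gi + 1}"
        p_group = _balding_nichols(rng, p0, spec.fct_target)
        for pi in range(spec.pops_per_group):
            p_name = f"{g_name}P{pi + 1}"
            p_pop = _balding_nichols(rng, p_group, spec.fsc_target)
            block = rng.binomial(2, p_pop, size=(spec.inds_per_pop, L)).astype(float)
            genotypes.append(block)
            for ii in range(spec.inds_per_pop):
                individual_ids.append(f"{p_name}I{ii + 1}")
                population.append(p_name)
                group.append(g_name)
    G = np.vstack(genotypes)
    if spec.missing_rate > 0.0:
        G[rng.random(G.shape) < spec.missing_rate] = np.nan
    return GenotypeMatrix(
        genotypes=G,
        individual_ids=individual_ids,
        population=population,
        group=group,
    )


# ----------------------------------------------------------------------
# Barcode alignments
# ----------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: np.ndarray, n_subs: int) -> np.ndarray:
    """Substitute ``n_subs`` distinct positions to a different base."""
    out = seq.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(seq.size, size=n_subs, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_barcode_alignment(
    n_a: int,
    n_b: int,
    seq_len: int = 658,
    shared: bool = True,
    seed: int = 0,
    max_mutations: int = 6,
    divergence: int = 33,
    ancestral_fraction: float = 0.6,
) -> SequenceAlignment:
    """Aligned barcodes for two nominal species, A and B.

    With ``shared=True`` both species descend from one ancestral sequence
    and a plurality (``ancestral_fraction``) of each carries it unchanged —
    the shared-haplotype, no-barcode-gap configuration.  With
    ``shared=False`` species B descends from an ancestor ``divergence``
    substitutions away, producing a clean gap when within-species
    variation (``max_mutations`` per individual) is small relative to the
    divergence.
    """
    if seq_len < 100:
        raise ValueError("seq_len must be >= 100")
    rng = np.random.default_rng(seed)
    ancestor_a = rng.choice(_BASES, size=seq_len)
    ancestor_b = ancestor_a if shared else _mutate(rng, ancestor_a, divergence)

    ids: list[str] = []
    species: list[str] = []
    seqs: list[str] = []
    for label, n, ancestor in (("A", n_a, ancestor_a), ("B", n_b, ancestor_b)):
        for i in range(n):
            if shared and rng.random() < ancestral_fraction:
                n_subs = 0
            else:
                n_subs = int(rng.integers(0, max_mutations + 1))
            seq = _mutate(rng, ancestor, n_subs)
            ids.append(f"{label}{i + 1}")
            species.append(label)
            seqs.append("".join(seq))
    return SequenceAlignment(ids=ids, sequences=seqs, species=species)


def simulate_shared_haplotype_alignment(
    n_a: int = 20, n_b: int = 39, seq_len: int = 658, seed: int = 0
) -> SequenceAlignment:
    """Shared-haplotype scenario: overlapping intra/inter distances, no gap."""
    return simulate_barcode_alignment(
        n_a, n_b, seq_len=seq_len, shared=True, seed=seed, max_mutations=6
    )


def simulate_gapped_alignment(
    n_a: int = 20, n_b: int = 39, seq_len: int = 658, seed: int = 0
) -> SequenceAlignment:
    """Well-gapped scenario: ~5% divergence between species, tight within."""
    return simulate_barcode_alignment(
        n_a, n_b, seq_len=seq_len, shared=False, seed=seed,
        max_mutations=2, divergence=33,
    )


# ----------------------------------------------------------------------
# Climate world
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SimNicheSpec:
    """Synthetic climate-history and Gaussian-niche parameters.

    The first variable plays the role of temperature: it cools everywhere
    as the forcing (δ18O) rises, so a niche centered on the cold tail of
    its present-day distribution tracks glacial climates.  When
    ``niche_center`` is None it is placed at the exact present climate of
    the cell at the 5th percentile of variable 0 (cold-adapted default);
    widths default to 0.3 sd for variable 0 and 2 sd elsewhere.
    """

    grid_rows: int = 40
    grid_cols: int = 60
    n_vars: int = 19
    niche_center: tuple[float, ...] | None = None
    niche_width: tuple[float, ...] | None = None
    n_presences: int = 78
    forcing_period: float = 100.0
    forcing_amplitude: float = 1.2
    anchor_times: tuple[float, ...] = (0.0, 21.0, 130.0, 787.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10 x 10")
        if self.n_presences < 10:
            raise ValueError("n_presences must be >= 10")
        if len(set(self.anchor_times)) != len(self.anchor_times):
            raise ValueError("anchor_times must be distinct")
        if 0.0 not in self.anchor_times:
            raise ValueError("anchor_times must include the present (0)")


@dataclass
class ClimateWorld:
    """Bundle returned by :func:`simulate_climate_history`."""

    anchors: list[ClimateStack]
    forcing: ForcingCurve
    truth: dict[float, np.ndarray]
    occurrences: OccurrenceSet
    niche_center: np.ndarray
    niche_width: np.ndarray
    slopes: dict[str, np.ndarray]

    @property
    def present(self) -> ClimateStack:
        return next(s for s in self.anchors if s.time == 0.0)

    def stack_at(self, time: float) -> ClimateStack:
        """Exact climate stack at an arbitrary time (affine in the forcing)."""
        present = self.present
        delta = float(self.forcing.at(time) - self.forcing.at(0.0))
        layers = {
            v: present.layers[v] + self.slopes[v] * delta
            for v in present.variables
        }
        return present.with_layers(layers, time=time)

    def truth_at(self, time: float) -> np.ndarray:
        stack = self.stack_at(time)
        return _gaussian_truth(stack, self.niche_center, self.niche_width)


def _smooth_field(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    n_bumps: int = 4,
    width_range: tuple[float, float] = (0.15, 0.4),
) -> np.ndarray:
    """Smooth spatial field: linear gradient plus Gaussian bumps, sd 1."""
    y, x = np.mgrid[0:n_rows, 0:n_cols]
    y = y / max(n_rows - 1, 1)
    x = x / max(n_cols - 1, 1)
    gx, gy = rng.normal(size=2)
    field = gx * x + gy * y
    for _ in range(n_bumps):
        cy, cx = rng.random(2)
        width = rng.uniform(*width_range)
        amp = rng.normal(scale=1.0)
        field = field + amp * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def _mountain_temperature(
    rng: np.random.Generator, n_rows: int, n_cols: int, n_peaks: int = 5
) -> np.ndarray:
    """Warm plain with a weak gradient and isolated cold peaks (degrees)."""
    y, x = np.mgrid[0:n_rows, 0:n_cols]
    y = y / max(n_rows - 1, 1)
    x = x / max(n_cols - 1, 1)
    field = 20.0 + rng.uniform(-2.0, 2.0) * (y - 0.5) + rng.uniform(-2.0, 2.0) * (
        x - 0.5
    )
    for _ in range(n_peaks):
        cy, cx = rng.random(2)
        width = rng.uniform(0.12, 0.28)
        depth = rng.uniform(5.0, 12.0)
        field -= depth * np.exp(
            -(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
        )
    return field


def _gaussian_truth(
    stack: ClimateStack, center: np.ndarray, width: np.ndarray
) -> np.ndarray:
    """Gaussian-niche suitability of each cell's climate, 1.0 at the center."""
    z2 = np.zeros(stack.shape)
    for k, v in enumerate(stack.variables):
        z2 += ((stack.layers[v] - center[k]) / width[k]) ** 2
    truth = np.exp(-0.5 * z2)
    truth[~stack.mask] = np.nan
    return truth


def simulate_climate_history(spec: SimNicheSpec) -> ClimateWorld:
    """Smooth climate fields, cyclic forcing, anchors exactly affine in it.

    The forcing is a δ18O-like periodic curve sampled at 1-ky steps over
    [0, max(800, anchors)], minimal (interglacial) at t = 0.  Each
    variable's field at time t equals its present field plus a cell-
    specific slope times the forcing increment, so downstream per-cell
    regression on the forcing must reproduce anchors to machine precision.
    Presences are drawn without replacement ∝ present-day truth (at most
    one per cell).
    """
    rng = np.random.default_rng(spec.seed)
    grid = GridSpec(
        n_rows=spec.grid_rows, n_cols=spec.grid_cols,
        xll=-55.0, yll=-30.0, cellsize=5.0 / 60.0,
    )

    times = np.arange(0.0, 801.0, 1.0)
    bad = [t for t in spec.anchor_times if not 0.0 <= t <= times[-1]]
    if bad:
        raise ValueError(f"anchor times {bad} outside the forcing domain [0, 800]")
    phase = 2.0 * np.pi * times / spec.forcing_period
    values = 3.2 + spec.forcing_amplitude * (
        0.5 - 0.5 * np.cos(phase) + 0.12 * (1.0 - np.cos(2.3 * phase + 0.4)) / 2.0
    )
    forcing = ForcingCurve(times=times, values=values)

    var_names = [f"bio{k + 1}" for k in range(spec.n_vars)]
    present_layers: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    # Temperature over a sky-island landscape: a warm plain with a mild
    # latitudinal gradient minus isolated cold mountains, so the area of
    # any cold level set grows monotonically downslope (cone geometry).
    # Cells cool as the forcing (δ18O) rises.
    temp = _mountain_temperature(rng, spec.grid_rows, spec.grid_cols)
    temp_slope = -(1.5 + 0.4 * _smooth_field(rng, spec.grid_rows, spec.grid_cols) ** 2)
    present_layers[var_names[0]] = temp
    slopes[var_names[0]] = temp_slope
    # Two shared regional precipitation regimes: real bioclimatic layer
    # sets have only a few effective degrees of freedom (a temperature
    # family and one or two moisture regimes), which is what lets a
    # thermal belt move downslope without leaving its moisture region.
    regime = [
        _smooth_field(rng, spec.grid_rows, spec.grid_cols,
                      n_bumps=10, width_range=(0.05, 0.14))
        for _ in range(2)
    ]
    # Climate responses are pattern-coherent: each variable's glacial
    # anomaly lies along its own present-day spatial pattern (the
    # space-for-time assumption underpinning paleoclimate projection),
    # with only a small incoherent residual.  Responses with large
    # components orthogonal to the present variance structure would create
    # no-analog axes that no present-trained model can track.
    regime_slope = [0.06 * regime[0], 0.06 * regime[1]]
    # one shared continentality-like field modulating the temperature family
    t_noise = _smooth_field(
        rng, spec.grid_rows, spec.grid_cols, n_bumps=10, width_range=(0.05, 0.14)
    )
    for k, name in enumerate(var_names[1:], start=1):
        if k <= 12:
            # temperature-family variable: elevation-driven, responds to
            # the forcing coherently with temperature; the family shares
            # one secondary field (real temperature layers correlate at
            # r ≳ 0.9, leaving the whole set with few effective axes)
            alpha = rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0])
            eta = rng.uniform(0.8, 1.5)
            texture = _smooth_field(rng, spec.grid_rows, spec.grid_cols)
            present_layers[name] = alpha * temp + eta * t_noise + 0.5 * texture
            slopes[name] = alpha * temp_slope + 0.03 * _smooth_field(
                rng, spec.grid_rows, spec.grid_cols
            )
        else:
            # precipitation-family variable: mixture of the two shared
            # regimes plus a little local texture
            beta, gamma = rng.normal(size=2)
            norm = math.hypot(beta, gamma) or 1.0
            beta, gamma = beta / norm, gamma / norm
            texture = _smooth_field(rng, spec.grid_rows, spec.grid_cols)
            present_layers[name] = 10.0 * (
                beta * regime[0] + gamma * regime[1] + 0.25 * texture
            )
            slopes[name] = 10.0 * (
                beta * regime_slope[0] + gamma * regime_slope[1]
            )

    present = ClimateStack(grid=grid, layers=present_layers, time=0.0)

    # Niche center: exact climate of the cold-tail cell (default), so the
    # truth map attains exactly 1.0 somewhere on the grid.
    if spec.niche_center is None:
        t0 = present.layers[var_names[0]]
        target = np.nanquantile(t0, 0.0)
        flat = np.nanargmin(np.abs(t0 - target))
        r0, c0 = np.unravel_index(flat, present.shape)
        center = present.values_at_cells(np.array([r0]), np.array([c0]))[0]
    else:
        center = np.asarray(spec.niche_center, dtype=float)
        if center.size != spec.n_vars:
            raise ValueError("niche_center length must equal n_vars")
    if spec.niche_width is None:
        # Thermally limited niche with a moderate moisture requirement:
        # tight on temperature, moderate on the precipitation regime
        # (excluding distant lowlands with alien moisture), loose on the
        # redundant temperature-family layers.
        width = np.empty(spec.n_vars)
        for k, v in enumerate(var_names):
            sd = np.nanstd(present.layers[v])
            if k == 0:
                width[k] = 0.7 * sd
            else:
                width[k] = 4.0 * sd
    else:
        width = np.asarray(spec.niche_width, dtype=float)
        if width.size != spec.n_vars or np.any(width <= 0):
            raise ValueError("niche_width must be positive with length n_vars")

    world_slopes = slopes
    f0 = float(forcing.at(0.0))
    anchors: list[ClimateStack] = []
    truth: dict[float, np.ndarray] = {}
    for t in spec.anchor_times:
        if t < forcing.times[0] or t > forcing.times[-1]:
            raise ValueError(f"anchor time {t} outside the forcing domain")
        delta = float(forcing.at(t)) - f0
        layers = {v: present.layers[v] + world_slopes[v] * delta for v in var_names}
        stack = present.with_layers(layers, time=t)
        anchors.append(stack)
        truth[t] = _gaussian_truth(stack, center, width)
    anchors.sort(key=lambda s: s.time)

    # Presences: cells sampled without replacement with probability ∝ truth(0).
    p = truth[0.0].ravel().copy()
    p = np.where(np.isnan(p), 0.0, p)
    p /= p.sum()
    n_cells = p.size
    n_take = min(spec.n_presences, int((p > 0).sum()))
    chosen = rng.choice(n_cells, size=n_take, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, present.shape)
    lonlat = np.array([grid.center_of(r, c) for r, c in zip(rows, cols)])
    occurrences = OccurrenceSet(
        species="synthetic", lon=lonlat[:, 0], lat=lonlat[:, 1], deduplicated=True
    )

    return ClimateWorld(
        anchors=anchors,
        forcing=forcing,
        truth=truth,
        occurrences=occurrences,
        niche_center=center,
        niche_width=width,
        slopes=world_slopes,
    )
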