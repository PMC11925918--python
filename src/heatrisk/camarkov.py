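"""CA-Markov simulation of categorical risk maps.

A Markov chain fitted to two dated class maps supplies the aggregate demand
for each class (``S_{t+1} = S_t P``), and a cellular automaton allocates
that demand spatially: each cell's affinity for class *k* is the product of
a neighbourhood suitability (the share of class-*k* cells in a 5 x 5 Moore
window around it) and the transition probability from the cell's current
class.  Cells are reassigned greedily in score order until every class
demand is met, so the simulated map matches the Markov projection's class
totals while respecting the spatial pattern.

The full-period transition is split across iterations (default 10, one per
simulated year) by linearly interpolating between the identity and the
fitted matrix — matrix p-th roots are ill-defined for some stochastic
matrices — with the exact terminal Markov demand enforced at the last
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid_io import Grid
from .risk_index import RISK_LEVELS, RiskClassMap

__all__ = [
    "TransitionModel",
    "SuitabilityAtlas",
    "SimulationConfig",
    "estimate_transition",
    "project_markov",
    "build_suitability",
    "simulate",
    "predict_pipeline",
]


@dataclass
class TransitionModel:
    """Class-to-class transfer counts and row-stochastic probabilities."""

    states: tuple[str, ...]
    counts: np.ndarray
    P: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.states)
        if self.P.shape != (k, k) or self.counts.shape != (k, k):
            raise ValueError("counts and P must be k x k for k states")
        if np.any(self.P < -1e-12):
            raise ValueError("P must be non-negative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("P rows must sum to 1")


@dataclass
class SuitabilityAtlas:
    """Per-class neighbourhood-frequency surfaces in [0, 1]."""

    surfaces: dict[int, Grid]
    filter_size: int = 5


@dataclass
class SimulationConfig:
    iterations: int = 10
    filter_size: int = 5
    seed: int = 0
    base_year: int | None = None
    target_year: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be an odd integer >= 3")


# ---------------------------------------------------------------------------


def estimate_transition(map1: RiskClassMap, map2: RiskClassMap,
                        period: float = 1.0) -> TransitionModel:
    """Fit the transition matrix from the cross-tabulation of two dates.

    Rows are normalised by their totals; a class absent at date 1 gets an
    identity row (it stays itself if it ever appears).
    """
    map1.classes.require_aligned(map2.classes, "second class map")
    valid = ~(map1.classes.nodata_mask | map2.classes.nodata_mask)
    a = map1.classes.values[valid].astype(int)
    b = map2.classes.values[valid].astype(int)
    k = len(RISK_LEVELS)
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    P = np.empty_like(counts)
    for i in range(k):
        row_total = counts[i].sum()
        if row_total > 0:
            P[i] = counts[i] / row_total
        else:
            P[i] = np.eye(k)[i]
    return TransitionModel(states=RISK_LEVELS, counts=counts, P=P, period=period)


def project_markov(areas: np.ndarray, model: TransitionModel, steps: int = 1) -> np.ndarray:
    """Aggregate Markov projection ``S_{t+steps} = S_t P^steps``.

    Total area is conserved because P is row-stochastic.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.shape != (len(model.states),):
        raise ValueError("areas must have one entry per state")
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    return areas @ np.linalg.matrix_power(model.P, steps)


def _window_sum(arr: np.ndarray, size: int) -> np.ndarray:
    """Exact sum over a size x size window, truncated at the edges."""
    out = np.cumsum(arr, axis=0)
    out = np.cumsum(out, axis=1)
    out = np.pad(out, ((1, 0), (1, 0)))
    r = size // 2
    n, m = arr.shape
    i0 = np.clip(np.arange(n) - r, 0, n)
    i1 = np.clip(np.arange(n) + r + 1, 0, n)
    j0 = np.clip(np.arange(m) - r, 0, m)
    j1 = np.clip(np.arange(m) + r + 1, 0, m)
    return (out[np.ix_(i1, j1)] - out[np.ix_(i0, j1)]
            - out[np.ix_(i1, j0)] + out[np.ix_(i0, j0)])


def build_suitability(classmap: RiskClassMap, filter_size: int = 5) -> SuitabilityAtlas:
    """Neighbourhood class-frequency surfaces.

    Suitability of class k at a cell is the fraction of valid cells of class
    k within the Moore window centred there (centre included); windows
    truncate at the map edge and masked cells drop out of both numerator and
    denominator.  Per cell the surfaces sum to 1 over classes.
    """
    if filter_size < 3 or filter_size % 2 == 0:
        raise ValueError("filter_size must be an odd integer >= 3")
    valid = (~classmap.classes.nodata_mask).astype(float)
    denom = _window_sum(valid, filter_size)
    denom = np.where(denom > 0, denom, 1.0)
    codes = classmap.classes.values.astype(int)
    surfaces: dict[int, Grid] = {}
    for k in range(len(RISK_LEVELS)):
        hits = ((codes == k) & (valid > 0)).astype(float)
        suit = _window_sum(hits, filter_size) / denom
        surfaces[k] = classmap.classes.with_values(suit)
    return SuitabilityAtlas(surfaces=surfaces, filter_size=filter_size)


def _integer_demand(target: np.ndarray, total: int) -> np.ndarray:
    """Round class demands to integers summing to ``total`` (largest remainder)."""
    scaled = target * (total / target.sum()) if target.sum() > 0 else target
    base = np.floor(scaled).astype(int)
    short = total - base.sum()
    remainder = scaled - base
    order = np.argsort(-remainder)
    base[order[:short]] += 1
    return base


def simulate(base: RiskClassMap, model: TransitionModel,
             config: SimulationConfig | None = None) -> RiskClassMap:
    """Run the CA-Markov allocation from ``base`` over one full period.

    Per iteration: (a) demand is the current class totals pushed through the
    per-iteration interpolated matrix ``I + (P - I)/iterations`` (the last
    iteration instead enforces the exact full-period demand ``S_0 P``);
    (b) suitability is rebuilt from the current map; (c) a cell's score for
    class k is ``suitability_k * P[current, k]`` plus a seeded tie-breaking
    jitter; (d) cells are reassigned greedily by score until demand is met.
    Masked cells never change class and contribute no demand.
    """
    if config is None:
        config = SimulationConfig()
    k = len(model.states)
    valid = ~base.classes.nodata_mask
    total = int(valid.sum())
    if total == 0:
        raise ValueError("base map has no unmasked cells")
    cur = base.classes.values.astype(int)
    base_areas = np.bincount(cur[valid], minlength=k).astype(float)
    terminal = project_markov(base_areas, model)
    if terminal.sum() > total + 0.5:
        raise ValueError("infeasible demand: exceeds total unmasked cells")
    rng = np.random.default_rng(config.seed)
    T = config.iterations
    Q = np.eye(k) + (model.P - np.eye(k)) / T

    flat_valid = np.flatnonzero(valid.ravel())
    for t in range(1, T + 1):
        areas = np.bincount(cur[valid], minlength=k).astype(float)
        target = areas @ Q if t < T else terminal
        demand = _integer_demand(target, total)

        atlas = build_suitability(
            RiskClassMap(base.classes.with_values(cur.astype(float)), base.thresholds,
                         base.year),
            config.filter_size,
        )
        suit = np.stack([atlas.surfaces[s].values.ravel()[flat_valid] for s in range(k)],
                        axis=1)
        pcur = model.P[cur.ravel()[flat_valid]]          # (ncells, k)
        score = suit * pcur + 1e-9 * rng.random(suit.shape)

        # greedy allocation: highest score first, subject to per-class demand
        order = np.argsort(-score, axis=None)
        cells, classes = np.unravel_index(order, score.shape)
        assigned = np.full(flat_valid.size, -1, dtype=int)
        remaining = demand.copy()
        n_assigned = 0
        for cell, cls in zip(cells, classes):
            if assigned[cell] >= 0 or remaining[cls] == 0:
                continue
            assigned[cell] = cls
            remaining[cls] -= 1
            n_assigned += 1
            if n_assigned == flat_valid.size:
                break
        new = cur.copy()
        new.ravel()[flat_valid] = assigned
        cur = new

    out = base.classes.with_values(cur.astype(float))
    return RiskClassMap(out, base.thresholds,
                        config.target_year if config.target_year is not None else base.year)


def predict_pipeline(map_t0: RiskClassMap, map_t1: RiskClassMap,
                     config: SimulationConfig | None = None) -> RiskClassMap:
    """Estimate P from two dated maps and project one period past the second.

    Assumes the transition trend is stationary: the fitted matrix for
    t0 -> t1 is reapplied from t1 forward.
    """
    model = estimate_transition(map_t0, map_t1)
    return simulate(map_t1, model, config)
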