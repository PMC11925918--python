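"""Seeded synthetic study regions, indicator stacks and Markov map series.

The generator emulates the spatial structure the risk pipeline expects from
an eastern-China-style study area: an elliptical study boundary, a smooth
urbanisation gradient peaking at a few urban cores, mountain and water
subregions away from the cores, and 13 indicator rasters driven by a shared
latent urbanisation factor plus indicator-specific smooth fields and noise.
Risk-raising indicators (land-surface temperature, population density,
elderly share, ...) load positively on urbanisation and protective
indicators (NDVI, water resources, GDP, ...) load negatively, so high
composite risk concentrates in the urban cores and each indicator's
direction is recoverable as the sign of its correlation with urbanisation.

Ground truth (latent loadings, landform fractions, transition matrices) is
always returned alongside the data so downstream tests are self-validating.
Everything is driven by ``numpy.random.default_rng`` seeded from the
scenario, so output is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .grid_io import CANONICAL_INDICATORS, Grid, IndicatorSpec, IndicatorStack

__all__ = [
    "SyntheticScenario",
    "StudyRegion",
    "make_study_region",
    "gen_indicator_stack",
    "gen_markov_series",
    "LANDFORM_CODES",
]

#: Integer codes of the categorical landform grid.
LANDFORM_CODES = {"urban": 0, "rural": 1, "mountain": 2, "water": 3}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study region.

    The defaults describe a 128 x 128 cell (1 km resolution) region with
    three urban cores, 15 % mountains and 8 % water, observed in 2010, 2015
    and 2019 with a mild warming/densification drift between years — enough
    to move cells between adjacent risk levels without wholesale reshuffling.
    """

    shape: tuple[int, int] = (128, 128)
    seed: int = 0
    n_urban_cores: int = 3
    urban_radius: float = 10.0
    mountain_fraction: float = 0.15
    water_fraction: float = 0.08
    years: tuple[int, ...] = (2010, 2015, 2019)
    trend_per_year: float = 0.02
    noise_sd: float = 0.30
    smoothing_scale: float = 4.0
    cell_size: float = 1000.0
    crs_tag: str = "synthetic-utm"

    def __post_init__(self) -> None:
        if self.shape[0] < 32 or self.shape[1] < 32:
            raise ValueError("scenario shape must be at least 32 x 32")
        if not (0 <= self.mountain_fraction and 0 <= self.water_fraction):
            raise ValueError("landform fractions must be non-negative")
        if self.mountain_fraction + self.water_fraction >= 1:
            raise ValueError("mountain_fraction + water_fraction must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_urban_cores < 1:
            raise ValueError("need at least one urban core")


class StudyRegion(NamedTuple):
    boundary: Grid        # 1 inside the study area, 0 outside
    landform: Grid        # categorical, LANDFORM_CODES, masked outside
    urbanization: Grid    # [0, 1], masked outside


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Standardised Gaussian random field: smoothed white noise, mean 0, sd 1."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=scale, mode="reflect")
    return (f - f.mean()) / f.std()


def _grid(scenario: SyntheticScenario, values: np.ndarray, mask: np.ndarray) -> Grid:
    return Grid(values, mask, cell_size=scenario.cell_size,
                origin=(0.0, scenario.shape[0] * scenario.cell_size),
                crs_tag=scenario.crs_tag)


def make_study_region(scenario: SyntheticScenario) -> StudyRegion:
    """Build boundary, landform classes and the urbanisation gradient.

    The landform split is done by ranking smooth suitability scores, so the
    realised mountain/water cell shares match the requested fractions exactly
    (up to integer cell counts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 101]))
    nrows, ncols = scenario.shape

    ii, jj = np.mgrid[0:nrows, 0:ncols]
    cy, cx = (nrows - 1) / 2.0, (ncols - 1) / 2.0
    inside = ((ii - cy) / (0.49 * nrows)) ** 2 + ((jj - cx) / (0.49 * ncols)) ** 2 <= 1.0
    outside = ~inside

    # urban cores in the central half of the region
    core_r = rng.uniform(0.25 * nrows, 0.75 * nrows, size=scenario.n_urban_cores)
    core_c = rng.uniform(0.25 * ncols, 0.75 * ncols, size=scenario.n_urban_cores)
    urb = np.zeros(scenario.shape)
    for r0, c0 in zip(core_r, core_c):
        d2 = (ii - r0) ** 2 + (jj - c0) ** 2
        urb += np.exp(-d2 / (2.0 * scenario.urban_radius ** 2))
    urb += 0.25 * _smooth_field(rng, scenario.shape, scenario.smoothing_scale)
    urb = ndimage.gaussian_filter(urb, sigma=scenario.smoothing_scale / 2.0, mode="reflect")
    vals = urb[inside]
    urb = (urb - vals.min()) / (vals.max() - vals.min())
    urb = np.clip(urb, 0.0, 1.0)

    # landform: water and mountains preferentially away from the cores
    water_score = _smooth_field(rng, scenario.shape, scenario.smoothing_scale) - 1.5 * urb
    mountain_score = _smooth_field(rng, scenario.shape, scenario.smoothing_scale) - 1.5 * urb
    n_inside = int(inside.sum())
    landform = np.full(scenario.shape, LANDFORM_CODES["rural"], dtype=int)

    n_water = int(round(scenario.water_fraction * n_inside))
    if n_water:
        ws = np.where(inside, water_score, -np.inf).ravel()
        idx = np.argpartition(ws, -n_water)[-n_water:]
        landform.ravel()[idx] = LANDFORM_CODES["water"]
    n_mountain = int(round(scenario.mountain_fraction * n_inside))
    if n_mountain:
        ms = np.where(inside & (landform == LANDFORM_CODES["rural"]), mountain_score, -np.inf).ravel()
        idx = np.argpartition(ms, -n_mountain)[-n_mountain:]
        landform.ravel()[idx] = LANDFORM_CODES["mountain"]
    urban_cells = inside & (landform == LANDFORM_CODES["rural"]) & (urb > 0.55)
    landform[urban_cells] = LANDFORM_CODES["urban"]

    boundary = _grid(scenario, inside.astype(float), np.zeros(scenario.shape, bool))
    landform_grid = _grid(scenario, landform.astype(float), outside.copy())
    urb_grid = _grid(scenario, urb, outside.copy())
    return StudyRegion(boundary, landform_grid, urb_grid)


# latent-model structure: (primary |loading| on urbanisation, secondary
# |loading| on an indicator-specific smooth field).  The primary loading sign
# follows the indicator's risk direction.
_PRIMARY_LOADING = {
    "lst": 0.90,
    "gdp": 0.80,
    "disposable_income": 0.80,
    "physicians": 0.85,
    "hospital_beds": 0.85,
    "older_adults": 0.70,
    "female": 0.60,
    "unemployment": 0.65,
    "ndvi": 0.85,
    "population_density": 0.90,
    "water_resources": 0.75,
    "agricultural_practitioners": 0.55,
    "construction_practitioners": 0.85,
}
_SECONDARY_LOADING = 0.35

#: Indicators that drift upward over the years (warming, densification).
#: The drift is proportional to urbanisation, so cities warm and densify
#: faster than the countryside and the trend survives min-max normalisation.
_TRENDED = ("lst", "population_density")

#: Share of the stochastic part of each indicator that is redrawn per year;
#: the remainder persists across years so class transitions stay mostly
#: between adjacent risk levels rather than reshuffling the map.
_YEAR_MIX = 0.45


def gen_indicator_stack(
    scenario: SyntheticScenario,
    region: StudyRegion,
    year: int,
    *,
    primary_loadings: dict[str, float] | None = None,
    secondary_loading: float = _SECONDARY_LOADING,
) -> tuple[IndicatorStack, dict[str, float]]:
    """Generate the 13 indicator rasters for one year.

    Each indicator is ``sign * loading * urbanisation_z + l2 * field_i +
    noise`` in standardised units, where ``field_i`` is an indicator-specific
    smooth Gaussian field.  The stochastic parts blend a persistent
    component (shared by all years) with a year-specific redraw, so
    successive years are strongly but not perfectly correlated.  NDVI is
    additionally elevated on mountain cells and water resources on water
    cells, tying the protective indicators to the landform map.  Returns the
    stack together with the signed ground-truth primary loadings.
    """
    if year not in scenario.years:
        raise ValueError(f"unknown year {year}; scenario years are {scenario.years}")
    rng_p = np.random.default_rng(np.random.SeedSequence([scenario.seed, 202]))
    rng_y = np.random.default_rng(np.random.SeedSequence([scenario.seed, 203, int(year)]))
    mask = region.urbanization.nodata_mask
    urb = region.urbanization.values
    inside = ~mask
    urb_z = np.zeros_like(urb)
    urb_z[inside] = (urb[inside] - urb[inside].mean()) / urb[inside].std()

    landform = region.landform.values
    drift = scenario.trend_per_year * (year - scenario.years[0])
    m = _YEAR_MIX
    keep = np.sqrt(1.0 - m * m)

    loadings = dict(_PRIMARY_LOADING)
    if primary_loadings:
        loadings.update(primary_loadings)

    specs: list[IndicatorSpec] = []
    grids: list[Grid] = []
    truth: dict[str, float] = {}
    for spec in CANONICAL_INDICATORS:
        sign = 1.0 if spec.direction == "positive" else -1.0
        lam = loadings[spec.name]
        f2 = keep * _smooth_field(rng_p, scenario.shape, scenario.smoothing_scale) \
            + m * _smooth_field(rng_y, scenario.shape, scenario.smoothing_scale)
        eps = keep * rng_p.standard_normal(scenario.shape) \
            + m * rng_y.standard_normal(scenario.shape)
        vals = sign * lam * urb_z + secondary_loading * f2 + scenario.noise_sd * eps
        if spec.name == "ndvi":
            vals += 1.0 * (landform == LANDFORM_CODES["mountain"])
        if spec.name == "water_resources":
            vals += 1.0 * (landform == LANDFORM_CODES["water"])
        if spec.name in _TRENDED:
            vals += drift * urb
        specs.append(spec)
        grids.append(_grid(scenario, vals, mask.copy()))
        truth[spec.name] = sign * lam
    return IndicatorStack(specs, grids, year), truth


def _modal_class(classes: np.ndarray, valid: np.ndarray, states: np.ndarray,
                 size: int = 5) -> np.ndarray:
    """Per-cell modal class over a size x size window (valid cells only)."""
    best_count = np.full(classes.shape, -1.0)
    mode = classes.copy()
    for s in states:
        hits = ((classes == s) & valid).astype(float)
        count = ndimage.uniform_filter(hits, size=size, mode="constant", cval=0.0)
        better = count > best_count + 1e-12
        mode = np.where(better, s, mode)
        best_count = np.maximum(best_count, count)
    return mode


def gen_markov_series(
    P: np.ndarray,
    init: Grid,
    steps: int,
    seed: int,
    spatial_mixing: float = 0.0,
) -> list[Grid]:
    """Evolve a categorical map ``steps`` times under transition matrix ``P``.

    Each unmasked cell transitions independently according to its row of
    ``P``; afterwards, with probability ``spatial_mixing`` a cell adopts the
    modal class of its 5 x 5 neighbourhood, which injects the spatial
    autocorrelation a cellular-automaton allocator relies on.  With
    ``spatial_mixing=0`` the empirical one-step transition frequencies
    converge to ``P`` as the cell count grows.

    Returns the ``steps`` maps after ``init`` (``init`` itself excluded).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    if np.any(P < -1e-12):
        raise ValueError("P must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P rows must sum to 1")
    states = np.arange(P.shape[0])
    valid = ~init.nodata_mask
    cur = init.values.astype(int)
    present = np.unique(cur[valid])
    if not set(present) <= set(states):
        raise ValueError(f"init contains classes {present} outside the states of P")

    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    out: list[Grid] = []
    for _ in range(steps):
        u = rng.random(cur.shape)
        nxt = (u[..., None] > cum[cur]).sum(axis=-1)
        nxt = np.where(valid, nxt, cur)
        if spatial_mixing > 0:
            adopt = (rng.random(cur.shape) < spatial_mixing) & valid
            mode = _modal_class(nxt, valid, states)
            nxt = np.where(adopt, mode, nxt)
        cur = nxt
        out.append(init.with_values(cur.astype(float), init.nodata_mask.copy()))
    return out
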