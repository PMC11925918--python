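"""Composite heat-health-risk surface, five-level classification and accounting.

The index is the cellwise product of the three normalised assessments —
hazard H (normalised land-surface temperature), social vulnerability S and
exposure E — rescaled to [0, 1] over the study area:

    HHR = minmax(H * S * E)

Classification into five levels (lowest, low, medium, high, highest) uses
Jenks natural breaks: the exact dynamic-programming optimum of within-class
sum of squared deviations, computed on the baseline year and then frozen so
later years and forecasts are graded on one common standard.  The published
five-level grading standard (0.2 / 0.4 / 0.5 / 0.58) can be supplied instead
for replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_io import Grid

__all__ = [
    "RISK_LEVELS",
    "REFERENCE_BREAKS",
    "RiskMap",
    "RiskClassMap",
    "TransitionAccounting",
    "DominanceMap",
    "compute_hhr",
    "jenks_breaks",
    "classify",
    "area_proportions",
    "transition_accounting",
    "dominant_factor_subzones",
]

#: Class labels in ascending risk order; class codes are their indices 0..4.
RISK_LEVELS = ("lowest", "low", "medium", "high", "highest")

#: Published five-level grading standard for an HHR surface on [0, 1].
REFERENCE_BREAKS = (0.2, 0.4, 0.5, 0.58)

#: Components of the index, in the tie-break precedence order used by
#: :func:`dominant_factor_subzones`.
COMPONENTS = ("hazard", "social_vulnerability", "exposure")


@dataclass
class RiskMap:
    """HHR surface plus the three component surfaces it was built from."""

    hhr: Grid
    h: Grid
    s: Grid
    e: Grid
    year: int = 0


@dataclass
class RiskClassMap:
    """Five-level categorical risk map and the thresholds that produced it."""

    classes: Grid          # integer codes 0..4 (indices into RISK_LEVELS)
    thresholds: tuple[float, float, float, float]
    year: int = 0

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
            raise ValueError(f"thresholds must be 4 strictly ascending values, got {t}")
        self.thresholds = t

    def counts(self) -> np.ndarray:
        """Cell count per level (length 5)."""
        codes = self.classes.values[~self.classes.nodata_mask].astype(int)
        return np.bincount(codes, minlength=len(RISK_LEVELS)).astype(float)


@dataclass
class TransitionAccounting:
    """Cross-tabulation of class membership between two dates."""

    counts: np.ndarray       # 5 x 5, rows = level at date 1, cols = date 2
    proportions: np.ndarray  # counts / total unmasked cells


@dataclass
class DominanceMap:
    """Leading-component zoning of the high and highest risk areas."""

    zones: Grid                    # codes = indices into COMPONENTS, masked elsewhere
    proportions: dict[str, float]  # share of each component, percent


# ---------------------------------------------------------------------------


def compute_hhr(h: Grid, s: Grid, e: Grid, year: int = 0) -> RiskMap:
    """Multiply the three component surfaces and rescale onto [0, 1].

    The product is only defined where all three components are valid; the
    output mask is the union of the component masks.  A constant raw product
    cannot be rescaled and is an error.
    """
    h.require_aligned(s, "social vulnerability surface")
    h.require_aligned(e, "exposure surface")
    mask = h.nodata_mask | s.nodata_mask | e.nodata_mask
    raw = h.values * s.values * e.values
    vals = raw[~mask]
    if vals.size == 0:
        raise ValueError("no jointly valid cells")
    lo, hi = vals.min(), vals.max()
    if hi - lo == 0:
        raise ValueError("constant risk product: min-max rescale undefined")
    hhr = np.where(mask, 0.0, (raw - lo) / (hi - lo))
    grid = Grid(hhr, mask, cell_size=h.cell_size, origin=h.origin, crs_tag=h.crs_tag)
    return RiskMap(hhr=grid, h=h, s=s, e=e, year=year)


def jenks_breaks(values: np.ndarray, n_classes: int) -> tuple[float, ...]:
    """Exact Jenks natural breaks via dynamic programming.

    Finds the partition of the sorted values into ``n_classes`` contiguous
    groups minimising the total within-class sum of squared deviations
    (equivalently maximising between-class variance).  Returns the
    ``n_classes - 1`` ascending thresholds; each threshold is the smallest
    value of the class above it, matching the half-open binning of
    :func:`classify` so re-classifying the input reproduces the optimum.
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    distinct = np.unique(values)
    if distinct.size < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct values, got {distinct.size}"
        )
    if n_classes == 1:
        return ()
    v = np.sort(values)
    n = v.size
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def interval_cost(a: np.ndarray, b: int) -> np.ndarray:
        # SSD of v[a..b] inclusive, vectorised over the start index a
        cnt = b - a + 1
        tot = s1[b + 1] - s1[a]
        return (s2[b + 1] - s2[a]) - tot * tot / cnt

    cost = np.empty((n_classes, n))
    first = np.zeros((n_classes, n), dtype=int)  # start index of the last class
    # one class covering v[0..i]
    cnt = np.arange(1, n + 1, dtype=float)
    cost[0] = s2[1:] - s1[1:] ** 2 / cnt
    for k in range(1, n_classes):
        cost[k, :k] = np.inf
        for i in range(k, n):
            starts = np.arange(k, i + 1)
            total = cost[k - 1, starts - 1] + interval_cost(starts, i)
            j = int(np.argmin(total))
            cost[k, i] = total[j]
            first[k, i] = starts[j]
    # backtrack class start positions
    breaks: list[float] = []
    i = n - 1
    for k in range(n_classes - 1, 0, -1):
        start = first[k, i]
        breaks.append(float(v[start]))
        i = start - 1
    return tuple(sorted(breaks))


def classify(risk: RiskMap | Grid, thresholds: tuple[float, float, float, float],
             year: int | None = None) -> RiskClassMap:
    """Bin an HHR surface into the five levels.

    Binning is half-open, ``[lower, upper)``: a value equal to a threshold
    belongs to the class above it.
    """
    grid = risk.hhr if isinstance(risk, RiskMap) else risk
    if year is None:
        year = risk.year if isinstance(risk, RiskMap) else 0
    t = tuple(float(x) for x in thresholds)
    if len(t) != 4 or any(t[i] >= t[i + 1] for i in range(3)):
        raise ValueError(f"thresholds must be 4 strictly ascending values, got {t}")
    codes = np.digitize(grid.values, t, right=False)
    classes = Grid(np.where(grid.nodata_mask, 0, codes).astype(float), grid.nodata_mask.copy(),
                   cell_size=grid.cell_size, origin=grid.origin, crs_tag=grid.crs_tag)
    return RiskClassMap(classes=classes, thresholds=t, year=year)


def area_proportions(classmap: RiskClassMap) -> dict[str, float]:
    """Percent of unmasked cells in each risk level (sums to 100)."""
    counts = classmap.counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("class map has no unmasked cells")
    return {level: float(100.0 * c / total) for level, c in zip(RISK_LEVELS, counts)}


def transition_accounting(map1: RiskClassMap, map2: RiskClassMap) -> TransitionAccounting:
    """Cell-count cross-tabulation from the levels of date 1 to date 2."""
    map1.classes.require_aligned(map2.classes, "second class map")
    valid = ~(map1.classes.nodata_mask | map2.classes.nodata_mask)
    a = map1.classes.values[valid].astype(int)
    b = map2.classes.values[valid].astype(int)
    k = len(RISK_LEVELS)
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no jointly valid cells between the two dates")
    return TransitionAccounting(counts=counts, proportions=counts / total)


def dominant_factor_subzones(risk: RiskMap, classmap: RiskClassMap) -> DominanceMap:
    """Zone the high + highest risk area by its leading component.

    Within the high and highest cells, each of H, S and E is min-max
    rescaled to [0, 1] (over those cells), and a cell's dominant component is
    the argmax of the three rescaled values.  Ties resolve in the fixed
    order hazard > social vulnerability > exposure.  Proportions are percent
    of the high + highest domain.
    """
    risk.hhr.require_aligned(classmap.classes, "class map")
    high_code = RISK_LEVELS.index("high")
    domain = (~classmap.classes.nodata_mask) & (classmap.classes.values >= high_code)
    if not domain.any():
        raise ValueError("no high or highest risk cells to zone")

    rescaled = []
    for comp in (risk.h, risk.s, risk.e):
        vals = comp.values[domain]
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else 1.0
        rescaled.append((comp.values - lo) / span)
    stackv = np.stack(rescaled)  # (3, rows, cols)
    # argmax returns the first maximum, which is exactly the H > S > E tie order
    dominant = np.argmax(stackv, axis=0)

    zones = Grid(np.where(domain, dominant, 0).astype(float), ~domain,
                 cell_size=risk.hhr.cell_size, origin=risk.hhr.origin,
                 crs_tag=risk.hhr.crs_tag)
    n = domain.sum()
    proportions = {
        comp: float(100.0 * np.sum(dominant[domain] == i) / n)
        for i, comp in enumerate(COMPONENTS)
    }
    return DominanceMap(zones=zones, proportions=proportions)
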