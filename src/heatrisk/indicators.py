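"""Indicator normalisation and PCA-based weighting.

The weighting scheme converts a correlation-matrix PCA of the social
vulnerability and exposure indicators into non-negative per-indicator
weights.  With ``a_ij`` the loading of indicator *i* on component *j*,
``X_j`` the component's eigenvalue and ``PC_j`` its variance contribution
(percent), the score coefficient is ``b_ij = |a_ij| / sqrt(X_j)`` and the
raw weight is the contribution-weighted mean

    W_i = sum_j b_ij * PC_j / sum_j PC_j

over the retained components (eigenvalue > 1 by default).  Weights are then
renormalised to sum to 1 within each indicator category, so that the social
vulnerability score and the exposure score are each convex combinations of
their normalised indicators.  Loadings enter in absolute value — weights
carry importance only; an indicator's protective or aggravating sense is
carried by the direction used during min-max normalisation.

Sampling adequacy is checked with the Kaiser-Meyer-Olkin statistic and
Bartlett's test of sphericity before the PCA is trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .grid_io import Grid, IndicatorSpec, IndicatorStack

__all__ = [
    "AdequacyReport",
    "PCAWeights",
    "normalize",
    "normalize_stack",
    "kmo",
    "bartlett",
    "pca_weights",
    "composite_score",
    "sample_observations",
]


@dataclass(frozen=True)
class AdequacyReport:
    """KMO sampling adequacy and Bartlett sphericity diagnostics."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_obs: int
    n_vars: int


@dataclass
class PCAWeights:
    """Correlation-matrix PCA decomposition and derived indicator weights.

    ``eigenvalues``, ``loadings``, ``contribution`` and ``cumulative`` cover
    all components; ``score_coefficients`` and the weight formula use only
    the ``n_retained`` leading ones.
    """

    names: list[str]
    categories: list[str]
    eigenvalues: np.ndarray          # all p components, descending
    loadings: np.ndarray             # p indicators x p components (a_ij)
    contribution: np.ndarray         # percent of variance per component
    cumulative: np.ndarray           # running sum of contribution
    score_coefficients: np.ndarray   # p x n_retained (b_ij)
    weights: dict[str, float]        # per indicator, category-renormalised
    n_retained: int

    def category_weights(self, category: str) -> dict[str, float]:
        return {n: self.weights[n] for n, c in zip(self.names, self.categories)
                if c == category}


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def normalize(grid: Grid, direction: str) -> Grid:
    """Min-max normalise onto [0.01, 1.01] over unmasked cells.

    ``positive`` maps MIN -> 0.01 and MAX -> 1.01; ``negative`` reverses the
    sense so that higher protective values yield lower normalised risk.  A
    constant layer is an error: the formula's denominator vanishes.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    vals = grid.unmasked_values()
    if vals.size == 0:
        raise ValueError("cannot normalize a fully masked grid")
    lo, hi = vals.min(), vals.max()
    if hi - lo == 0:
        raise ValueError("cannot normalize a constant grid (max == min)")
    if direction == "positive":
        out = (grid.values - lo) / (hi - lo) + 0.01
    else:
        out = (hi - grid.values) / (hi - lo) + 0.01
    out = np.where(grid.nodata_mask, np.nan, out)
    return grid.with_values(np.nan_to_num(out, nan=0.0))


def normalize_stack(stack: IndicatorStack) -> IndicatorStack:
    """Normalise every layer of a stack per its spec's direction."""
    grids = [normalize(g, s.direction) for s, g in zip(stack.specs, stack.grids)]
    return IndicatorStack(list(stack.specs), grids, stack.year)


# ---------------------------------------------------------------------------
# sampling adequacy
# ---------------------------------------------------------------------------

def _correlation(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be a 2-D observation x indicator matrix with >= 2 columns")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant indicator column: correlation undefined")
    return np.corrcoef(data, rowvar=False)


def kmo(data: np.ndarray) -> AdequacyReport:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum u^2) over off-diagonal pairs, where u are
    the partial correlations obtained from the inverse correlation matrix.
    Values above ~0.7 indicate the correlation structure is compact enough
    for factor extraction.
    """
    R = _correlation(data)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular; KMO undefined") from exc
    d = np.sqrt(np.abs(np.diag(Rinv)))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    u2 = (partial[off] ** 2).sum()
    report = bartlett(data)
    return AdequacyReport(kmo=float(r2 / (r2 + u2)), bartlett_chi2=report.bartlett_chi2,
                          bartlett_df=report.bartlett_df, bartlett_p=report.bartlett_p,
                          n_obs=data.shape[0], n_vars=data.shape[1])


def bartlett(data: np.ndarray) -> AdequacyReport:
    """Bartlett's test of sphericity against an identity correlation matrix.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), with p(p-1)/2 degrees of
    freedom.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than indicators ({p})")
    R = _correlation(data)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return AdequacyReport(kmo=float("nan"), bartlett_chi2=float(chi2), bartlett_df=df,
                          bartlett_p=pval, n_obs=n, n_vars=p)


# ---------------------------------------------------------------------------
# PCA weights
# ---------------------------------------------------------------------------

def pca_weights(
    data: np.ndarray,
    specs: Sequence[IndicatorSpec],
    retention: int | Literal["eigenvalue_gt_1"] = "eigenvalue_gt_1",
    b_formula: Literal["abs_over_sqrt", "a_over_x"] = "abs_over_sqrt",
) -> PCAWeights:
    """Derive per-indicator weights from a correlation-matrix PCA.

    ``data`` is an observation x indicator matrix whose columns match
    ``specs`` in order.  Hazard indicators are excluded: the weighting
    covers the social-vulnerability and exposure blocks only (the hazard
    layer enters the risk index directly as normalised LST).

    ``retention`` keeps either the components with eigenvalue > 1 (default)
    or a fixed count.  ``b_formula`` selects the loading-to-score-coefficient
    conversion: ``abs_over_sqrt`` is ``|a_ij|/sqrt(X_j)`` (default);
    ``a_over_x`` is ``a_ij/X_j``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(specs):
        raise ValueError("data must have one column per spec")
    keep = [i for i, s in enumerate(specs) if s.category != "hazard"]
    if not keep:
        raise ValueError("no non-hazard indicators to weight")
    specs = [specs[i] for i in keep]
    data = data[:, keep]
    p = data.shape[1]

    if p == 1:
        # degenerate: a single indicator carries its category entirely
        return PCAWeights(
            names=[specs[0].name], categories=[specs[0].category],
            eigenvalues=np.array([1.0]), loadings=np.array([[1.0]]),
            contribution=np.array([100.0]), cumulative=np.array([100.0]),
            score_coefficients=np.array([[1.0]]), weights={specs[0].name: 1.0},
            n_retained=1,
        )

    R = _correlation(data)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    contribution = 100.0 * eigval / p
    cumulative = np.cumsum(contribution)

    if retention == "eigenvalue_gt_1":
        n_retained = int(np.sum(eigval > 1.0))
    else:
        n_retained = int(retention)
    if n_retained < 1:
        raise ValueError("retention rule keeps no components")
    n_retained = min(n_retained, p)

    a = loadings[:, :n_retained]
    X = eigval[:n_retained]
    if b_formula == "abs_over_sqrt":
        b = np.abs(a) / np.sqrt(X)
    elif b_formula == "a_over_x":
        b = a / X
    else:
        raise ValueError(f"unknown b_formula {b_formula!r}")
    pc = contribution[:n_retained]
    raw = b @ pc / pc.sum()

    weights: dict[str, float] = {}
    for category in ("social_vulnerability", "exposure"):
        idx = [i for i, s in enumerate(specs) if s.category == category]
        if not idx:
            continue
        total = raw[idx].sum()
        if total <= 0:
            raise ValueError(f"non-positive raw weight total in category {category!r}")
        for i in idx:
            weights[specs[i].name] = float(raw[i] / total)

    return PCAWeights(
        names=[s.name for s in specs],
        categories=[s.category for s in specs],
        eigenvalues=eigval, loadings=loadings, contribution=contribution,
        cumulative=cumulative, score_coefficients=b, weights=weights,
        n_retained=n_retained,
    )


def composite_score(stack: IndicatorStack, weights: PCAWeights | dict[str, float],
                    category: str) -> Grid:
    """Cellwise weighted sum of a category's normalised indicators.

    Because the category weights sum to 1 and each normalised layer lives in
    [0.01, 1.01], the score lives there too.  Cells missing in any layer are
    masked in the output.
    """
    sub = stack.select(category)
    wmap = weights.weights if isinstance(weights, PCAWeights) else dict(weights)
    missing = [s.name for s in sub.specs if s.name not in wmap]
    if missing:
        raise ValueError(f"weights missing for indicators: {missing}")
    out = np.zeros(sub.grids[0].shape)
    for spec, g in zip(sub.specs, sub.grids):
        out += wmap[spec.name] * g.values
    mask = sub.union_mask()
    ref = sub.grids[0]
    return Grid(np.where(mask, 0.0, out), mask, cell_size=ref.cell_size,
                origin=ref.origin, crs_tag=ref.crs_tag)


def sample_observations(stacks: Sequence[IndicatorStack], cap: int = 50_000) -> np.ndarray:
    """Pool unmasked cells of one or more yearly stacks into a PCA matrix.

    Cells are thinned on a regular stride so at most ``cap`` observations
    are drawn per stack; column order follows the first stack's specs.
    """
    if not stacks:
        raise ValueError("no stacks given")
    names = stacks[0].names
    rows = []
    for stack in stacks:
        if stack.names != names:
            raise ValueError("stacks disagree on indicator order")
        mask = stack.union_mask()
        idx = np.flatnonzero(~mask.ravel())
        if idx.size == 0:
            continue
        if idx.size > cap:
            stride = int(np.ceil(idx.size / cap))
            idx = idx[::stride]
        mat = np.column_stack([g.values.ravel()[idx] for g in stack.grids])
        rows.append(mat)
    if not rows:
        raise ValueError("all stacks fully masked")
    return np.vstack(rows)
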