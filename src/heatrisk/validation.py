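"""Map-agreement validation with Cohen's kappa and the robustness sweep.

Cohen's kappa corrects the raw cellwise agreement between two categorical
maps for the agreement expected from their marginal class distributions
alone:

    kappa = (p_o - p_e) / (1 - p_e)

where ``p_o`` is the observed agreement (diagonal share of the confusion
matrix) and ``p_e`` the chance agreement (sum of products of the row and
column marginal shares).  Significance uses the large-sample normal
approximation for kappa under the independence null (Fleiss, Cohen &
Everitt variance), giving a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .camarkov import SimulationConfig, predict_pipeline
from .risk_index import RISK_LEVELS, RiskClassMap

__all__ = ["ValidationReport", "kappa", "kappa_from_confusion", "robustness_sweep"]


@dataclass(frozen=True)
class ValidationReport:
    kappa: float
    z: float
    p_value: float
    confusion: np.ndarray
    observed_agreement: float
    expected_agreement: float
    n: int


def kappa_from_confusion(confusion: np.ndarray) -> ValidationReport:
    """Cohen's kappa and its independence-null z test from a confusion matrix."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix: the maps share no valid cells")
    row = C.sum(axis=1) / n
    col = C.sum(axis=0) / n
    p_o = float(np.trace(C) / n)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1: kappa undefined")
    k = (p_o - p_e) / (1.0 - p_e)
    # large-sample variance of kappa under the null of independence
    var0 = (p_e + p_e ** 2 - float(np.sum(row * col * (row + col)))) / (n * (1.0 - p_e) ** 2)
    z = k / np.sqrt(var0) if var0 > 0 else np.inf * np.sign(k)
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return ValidationReport(kappa=float(k), z=float(z), p_value=p_value, confusion=C,
                            observed_agreement=p_o, expected_agreement=p_e, n=int(n))


def kappa(map_a: RiskClassMap, map_b: RiskClassMap) -> ValidationReport:
    """Chance-corrected agreement between two class maps.

    Cells masked in either map are excluded pairwise.
    """
    map_a.classes.require_aligned(map_b.classes, "second class map")
    valid = ~(map_a.classes.nodata_mask | map_b.classes.nodata_mask)
    if not valid.any():
        raise ValueError("the maps share no valid cells")
    a = map_a.classes.values[valid].astype(int)
    b = map_b.classes.values[valid].astype(int)
    k = len(RISK_LEVELS)
    C = np.zeros((k, k))
    np.add.at(C, (a, b), 1.0)
    return kappa_from_confusion(C)


def robustness_sweep(map_t0: RiskClassMap, map_t1: RiskClassMap, truth: RiskClassMap,
                     iteration_counts: Sequence[int],
                     config: SimulationConfig | None = None) -> pd.DataFrame:
    """Hindcast once per CA iteration count and score each against truth.

    Returns a DataFrame with columns ``iterations``, ``kappa``, ``p``,
    sorted by iterations.  A stable model shows nearly identical kappa
    across neighbouring iteration counts.
    """
    base = config if config is not None else SimulationConfig()
    rows = []
    for n_it in sorted(int(i) for i in iteration_counts):
        cfg = SimulationConfig(iterations=n_it, filter_size=base.filter_size,
                               seed=base.seed, base_year=base.base_year,
                               target_year=base.target_year)
        pred = predict_pipeline(map_t0, map_t1, cfg)
        report = kappa(pred, truth)
        rows.append({"iterations": n_it, "kappa": report.kappa, "p": report.p_value})
    return pd.DataFrame(rows, columns=["iterations", "kappa", "p"])
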