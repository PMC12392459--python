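"""Benchmark metrics between experimental and calculated value vectors.

The standard seven-number summary used for solvation free-energy and LogP
benchmarks: Lin's concordance correlation coefficient (CCC), Pearson ρ,
ordinary-least-squares slope/intercept of calculated on experimental, mean
unsigned error, Kendall τ (tie-corrected τ-b), and mean signed error with the
experimental-minus-calculated sign convention. Cross-protocol agreement is
summarized by a symmetric matrix of pairwise CCC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricRow", "pearson", "kendall_tau", "mue", "mse", "fit_line",
           "ccc", "metric_row", "ccc_matrix", "METRIC_COLUMNS"]

#: Canonical column order for reports.
METRIC_COLUMNS = ("ccc", "rho", "a", "b", "mue", "tau", "mse")


def _pair(x, y, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _pair(x, y, min_n=3)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(x, y) -> float:
    """Kendall rank correlation, τ-b convention (tie-corrected)."""
    x, y = _pair(x, y, min_n=3)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def mue(exp, calc) -> float:
    """Mean unsigned error, mean |exp_i − calc_i|."""
    exp, calc = _pair(exp, calc)
    return float(np.abs(exp - calc).mean())


def mse(exp, calc) -> float:
    """Mean signed error, mean (exp_i − calc_i).

    With this convention a method that overestimates the magnitude of negative
    free energies yields a positive MSE.
    """
    exp, calc = _pair(exp, calc)
    return float((exp - calc).mean())


def fit_line(exp, calc) -> tuple[float, float]:
    """OLS best-fit line of calculated (y) on experimental (x): (slope, intercept)."""
    x, y = _pair(exp, calc, min_n=2)
    if x.std() == 0:
        raise ValueError("degenerate x: zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments).

    CCC = 2 cov(x,y) / (var(x) + var(y) + (x̄ − ȳ)²); equals Pearson ρ scaled
    by a bias-correction factor that penalizes departures of the best-fit line
    from the 45° identity line, so |CCC| ≤ |ρ| always.
    """
    x, y = _pair(x, y, min_n=3)
    vx, vy = x.var(), y.var()
    shift = (x.mean() - y.mean()) ** 2
    denom = vx + vy + shift
    if denom == 0:
        raise ValueError("degenerate input: both variances and mean shift are zero")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * cov / denom)


@dataclass
class MetricRow:
    """All seven benchmark metrics on one (experimental, calculated) pairing."""

    ccc: float
    rho: float
    a: float
    b: float
    mue: float
    tau: float
    mse: float
    n_used: int = 0
    excluded: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def metric_row(exp, calc, names: Sequence[str] | None = None,
               exclude: Sequence[str] = ()) -> MetricRow:
    """Compute the full metric row, optionally excluding named outliers.

    ``names`` labels the entries of both vectors; every member of ``exclude``
    must appear in ``names``.
    """
    exp, calc = _pair(exp, calc, min_n=3)
    exclude = list(exclude)
    if exclude:
        if names is None:
            raise ValueError("exclusions require entry names")
        names = list(names)
        missing = [e for e in exclude if e not in names]
        if missing:
            raise ValueError(f"excluded names not in data: {missing}")
        keep = np.array([n not in exclude for n in names])
        exp, calc = exp[keep], calc[keep]
        if exp.size < 3:
            raise ValueError("fewer than 3 compounds left after exclusion")
    a, b = fit_line(exp, calc)
    return MetricRow(ccc=ccc(exp, calc), rho=pearson(exp, calc), a=a, b=b,
                     mue=mue(exp, calc), tau=kendall_tau(exp, calc),
                     mse=mse(exp, calc), n_used=int(exp.size), excluded=exclude)


def ccc_matrix(columns: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Symmetric matrix of pairwise CCC values between named columns."""
    keys = list(columns)
    if len(keys) < 2:
        raise ValueError("need at least two columns")
    arrays = {k: np.asarray(columns[k], dtype=float) for k in keys}
    n = len(arrays[keys[0]])
    if any(a.size != n for a in arrays.values()):
        raise ValueError("columns must have equal lengths")
    out = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            v = ccc(arrays[ki], arrays[kj])
            out.loc[ki, kj] = out.loc[kj, ki] = v
    return out
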