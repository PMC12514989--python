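"""Additive (L+M) model of the 680/543-nm sensitivity ratio.

At detection threshold the response of a mechanism that sums L and M cone
excitations is the same for the two primaries, which gives the predicted
sensitivity ratio at a retinal site with L proportion pL:

    S680 / S543 = (pL * L680 + w (1-pL) * M680) / (pL * L543 + w (1-pL) * M543)

where Lx, Mx are the average quantal excitations per corneal quantum of the
x-nm primary, and w is a relative M-cone weight (1 in the plain additive
model; 1.5 in the unequal-weight variant).  Model comparison sweeps the L
pigment lambda_max over a grid and reports the RMSE between predicted and
observed ratios per candidate peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: L-pigment spectral peaks (nm) of the common opsin variants.
PLAUSIBLE_L_LAMBDA_MAX = (555.5, 558.9, 563.4)


@dataclass
class AdditiveModelInput:
    prop_L: float
    L680: float
    M680: float
    L543: float
    M543: float
    m_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prop_L <= 1.0):
            raise ValueError("prop_L must be in [0, 1]")
        for name in ("L680", "M680", "L543", "M543"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_weight <= 0:
            raise ValueError("m_weight must be positive")


@dataclass
class ModelFitResult:
    lambda_max_grid: np.ndarray
    rmse: np.ndarray
    argmin: float
    predicted: np.ndarray       # per-site predictions at the best lambda_max
    observed: np.ndarray
    scale: str = "linear"


def predicted_ratio(inp: AdditiveModelInput) -> float:
    """S680/S543 predicted by the additive model at one site."""
    w = inp.m_weight
    p = inp.prop_L
    num = p * inp.L680 + w * (1.0 - p) * inp.M680
    den = p * inp.L543 + w * (1.0 - p) * inp.M543
    return num / den


def predicted_ratio_curve(prop_L, excitations: dict, m_weight: float = 1.0) -> np.ndarray:
    """Vectorized predicted ratio over an array of prop_L values.

    ``excitations`` holds keys L680, M680, L543, M543.
    """
    p = np.asarray(prop_L, dtype=float)
    w = m_weight
    num = p * excitations["L680"] + w * (1.0 - p) * excitations["M680"]
    den = p * excitations["L543"] + w * (1.0 - p) * excitations["M543"]
    return num / den


def _rmse(pred: np.ndarray, obs: np.ndarray, scale: str) -> float:
    if scale == "log10":
        r = np.log10(pred) - np.log10(obs)
    elif scale == "linear":
        r = pred - obs
    else:
        raise ValueError("scale must be 'linear' or 'log10'")
    return float(np.sqrt(np.mean(r ** 2)))


def rmse_sweep(
    observed: pd.DataFrame,
    fundamentals_factory,
    grid,
    m_weight: float = 1.0,
    scale: str = "linear",
) -> ModelFitResult:
    """RMSE of additive-model predictions as a function of L-cone lambda_max.

    ``observed`` needs columns ``prop_L`` and ``ratio``;
    ``fundamentals_factory(lambda_max)`` returns the excitation dict for that
    candidate L-pigment peak.  The grid point with minimal RMSE is reported.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda_max grid")
    if len(observed) < 1:
        raise ValueError("no observed sites")
    p = observed["prop_L"].to_numpy(float)
    obs = observed["ratio"].to_numpy(float)
    rmses = np.empty(grid.size)
    for i, lmax in enumerate(grid):
        exc = fundamentals_factory(float(lmax))
        rmses[i] = _rmse(predicted_ratio_curve(p, exc, m_weight), obs, scale)
    best = int(np.argmin(rmses))
    exc = fundamentals_factory(float(grid[best]))
    return ModelFitResult(
        lambda_max_grid=grid,
        rmse=rmses,
        argmin=float(grid[best]),
        predicted=predicted_ratio_curve(p, exc, m_weight),
        observed=obs,
        scale=scale,
    )


def weight_variant_test(
    observed: pd.DataFrame,
    fundamentals_factory,
    lambda_list=PLAUSIBLE_L_LAMBDA_MAX,
    m_weight: float = 1.5,
    scale: str = "linear",
) -> pd.DataFrame:
    """Percent RMSE change of the w-weighted variant relative to w = 1.

    One row per candidate lambda_max with columns ``rmse_base``,
    ``rmse_variant``, ``pct_change``.  Summarize across lists/subjects with
    ``.pct_change.mean()`` and ``.std()``.
    """
    lambda_list = list(lambda_list)
    if not lambda_list:
        raise ValueError("lambda_list is empty")
    p = observed["prop_L"].to_numpy(float)
    obs = observed["ratio"].to_numpy(float)
    rows = []
    for lmax in lambda_list:
        exc = fundamentals_factory(float(lmax))
        base = _rmse(predicted_ratio_curve(p, exc, 1.0), obs, scale)
        var = _rmse(predicted_ratio_curve(p, exc, m_weight), obs, scale)
        rows.append({
            "lambda_max": lmax,
            "rmse_base": base,
            "rmse_variant": var,
            "pct_change": 100.0 * (var - base) / base if base > 0 else np.inf,
        })
    return pd.DataFrame(rows)
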