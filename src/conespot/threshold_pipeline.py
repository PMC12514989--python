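"""From trial tables to thresholds and sensitivity ratios.

Stages: (1) delivery-quality inclusion filter (per-frame stimulus position
within 0.75 arcmin of the tracked position on both axes), (2) maximum-
likelihood Weibull psychometric fits with threshold read off at 50%
frequency of seeing, (3) per-site 680/543 sensitivity ratios
(sensitivity = 1/threshold), and (4) Spearman rank correlation of the ratio
against the local proportion of L cones, with a seeded permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata, spearmanr

log = logging.getLogger(__name__)

INCLUSION_LIMIT_ARCMIN = 0.75


class DegenerateDataError(ValueError):
    """Raised when psychometric data cannot identify a threshold."""


def inclusion_filter(
    trials: pd.DataFrame, limit: float = INCLUSION_LIMIT_ARCMIN
) -> tuple[pd.DataFrame, float]:
    """Keep trials whose worst-frame |dx| and |dy| are both <= limit (inclusive).

    Trials with missing offsets are rejected (with a log warning) but still
    count toward the denominator of the returned inclusion rate.
    """
    dx = trials["max_abs_dx_arcmin"]
    dy = trials["max_abs_dy_arcmin"]
    missing = dx.isna() | dy.isna()
    if missing.any():
        log.warning("%d trials missing delivery offsets; rejected", missing.sum())
    keep = (~missing) & (dx <= limit) & (dy <= limit)
    rate = float(keep.sum()) / len(trials) if len(trials) else float("nan")
    return trials.loc[keep].copy(), rate


@dataclass
class ThresholdEstimate:
    site_id: object
    wavelength: float
    alpha: float            # intensity at 50% seen, linear units
    beta: float             # Weibull slope
    n_trials: int
    loglik: float
    guess: float
    lapse: float

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.alpha


def _weibull_p(log10_i: np.ndarray, log10_scale: float, beta: float,
               guess: float, lapse: float) -> np.ndarray:
    # Weibull in intensity == Gumbel in log10 intensity
    z = 10.0 ** (beta * (log10_i - log10_scale))
    return guess + (1.0 - guess - lapse) * (1.0 - np.exp(-z))


def fit_weibull(
    intensity: np.ndarray,
    seen: np.ndarray,
    guess: float = 0.0,
    lapse: float = 0.01,
    site_id=None,
    wavelength: float = float("nan"),
) -> ThresholdEstimate:
    """Maximum-likelihood Weibull psychometric fit.

    P(seen | I) = guess + (1 - guess - lapse) * (1 - exp(-(I/scale)^beta)),
    fitted on log10 intensity for stability.  The reported threshold alpha is
    the intensity where the fitted P(seen) equals 0.5.
    """
    intensity = np.asarray(intensity, dtype=float)
    seen = np.asarray(seen).astype(bool)
    if intensity.size < 10:
        raise DegenerateDataError("need at least 10 trials")
    if np.any(intensity <= 0):
        raise ValueError("intensities must be positive")
    if np.unique(intensity).size < 2:
        raise DegenerateDataError("trials span a single intensity")
    if seen.all() or not seen.any():
        raise DegenerateDataError("all trials seen (or none): threshold unidentified")
    if not (0.0 <= guess < 0.5 and 0.0 <= lapse < 0.5):
        raise ValueError("guess and lapse must be in [0, 0.5)")

    li = np.log10(intensity)
    y = seen.astype(float)

    def nll(theta):
        scale, logbeta = theta
        beta = np.exp(np.clip(logbeta, -4.0, 4.0))
        p = _weibull_p(li, scale, beta, guess, lapse)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))

    # initialize scale between the highest unseen and lowest seen intensities
    lo = li[seen].min()
    hi = li[~seen].max()
    x0 = np.array([0.5 * (lo + hi), np.log(3.0)])
    best = None
    for start in (x0, x0 + [0.3, 0.0], x0 - [0.3, 0.0]):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best.fun > nll(x0) + 1e-6:
        best = minimize(nll, x0, method="Nelder-Mead",
                        options={"maxiter": 4000})
    scale, logbeta = best.x
    beta = float(np.exp(np.clip(logbeta, -4.0, 4.0)))
    # invert for the 50%-seen intensity
    frac = (0.5 - guess) / (1.0 - guess - lapse)
    if not (0.0 < frac < 1.0):
        raise ValueError("guess/lapse leave 50% unreachable")
    alpha = 10.0 ** (scale + np.log10(-np.log(1.0 - frac)) / beta)
    return ThresholdEstimate(site_id=site_id, wavelength=wavelength,
                             alpha=float(alpha), beta=beta,
                             n_trials=int(intensity.size),
                             loglik=-float(best.fun), guess=guess, lapse=lapse)


def fit_thresholds(
    trials: pd.DataFrame, guess: float = 0.0, lapse: float = 0.01
) -> pd.DataFrame:
    """Weibull fit per (site_id, wavelength_nm), pooling interleaved staircases.

    Conditions whose data are degenerate are skipped with a log entry.
    """
    rows = []
    for (site, wl), g in trials.groupby(["site_id", "wavelength_nm"]):
        try:
            est = fit_weibull(g["intensity_quanta_s_deg2"].to_numpy(),
                              g["seen"].to_numpy(), guess=guess, lapse=lapse,
                              site_id=site, wavelength=float(wl))
        except DegenerateDataError as exc:
            log.warning("site %s / %s nm: %s", site, wl, exc)
            continue
        rows.append({
            "site_id": site, "wavelength_nm": float(wl),
            "alpha": est.alpha, "beta": est.beta,
            "n_trials_used": est.n_trials, "sensitivity": est.sensitivity,
        })
    return pd.DataFrame(rows)


def sensitivity_ratio(
    estimates: pd.DataFrame, sites: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-site S680/S543 = alpha543/alpha680.

    Sites missing either wavelength are dropped with a log entry.  If a
    ``sites`` table (site_id, prop_L, ...) is supplied, it is joined in.
    """
    wide = estimates.pivot_table(index="site_id", columns="wavelength_nm",
                                 values="alpha")
    for wl in (543.0, 680.0):
        if wl not in wide.columns:
            wide[wl] = np.nan
    ok = wide[543.0].notna() & wide[680.0].notna()
    dropped = wide.index[~ok]
    if len(dropped):
        log.warning("dropping sites without both wavelengths: %s", list(dropped))
    out = pd.DataFrame({
        "site_id": wide.index[ok],
        "ratio": (wide.loc[ok, 543.0] / wide.loc[ok, 680.0]).to_numpy(),
    })
    if sites is not None:
        out = out.merge(sites, on="site_id", how="left")
    return out.reset_index(drop=True)


def rank_correlation(
    x, y, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho of x vs y with a two-sided permutation p-value.

    Uses average ranks for ties; the permutation null shuffles y with a
    seeded generator, so small-sample p-values are exact to Monte Carlo
    error rather than relying on the asymptotic t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired sites")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input vector")
    rho = float(spearmanr(x, y).statistic)
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
    perm = ry[idx] @ rx / x.size
    p = (1.0 + np.sum(np.abs(perm) >= abs(rho) - 1e-12)) / (n_perm + 1.0)
    return rho, float(p)
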