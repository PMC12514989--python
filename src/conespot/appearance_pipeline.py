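"""Color-naming analysis: heterogeneity, response matrices, and the GLMM.

Seen trials are labeled with whether the subject's color report matched the
large-field appearance of the stimulus wavelength ("red" for 680 nm,
"green" for 543 nm — the "expected" chromatic response).  The probability
of an expected response is modeled as

    logit pi = b0 + b1 * log2(intensity / local threshold)
                  + b2 * heterogeneity + b3 * S-cone distance
                  + u_subject + u_wavelength

with random intercepts for subject and wavelength, fitted by Laplace
maximum likelihood (see ``conespot.glmm``).  Heterogeneity indexes the
spectral balance of the stimulated cones: 1 when local L/M ratio is 1, 0
when one class fully dominates.  S-cone distance is measured in units of
the mosaic's mean Delaunay cone spacing.

Rare non-expected chromatic reports (e.g. "green" to 680 nm) are excluded
from the modeled table but can be returned for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GlmmFit, SeparationError, fit_logistic_glmm, lr_test

EXPECTED_COLOR = {543.0: "green", 680.0: "red"}
GLMM_COLUMNS = ["intercept", "log2_intensity", "heterogeneity", "s_cone_distance"]


def heterogeneity(prop_L):
    """Spectral heterogeneity index: 1 - |pL - 0.5| / 0.5, in [0, 1]."""
    p = np.asarray(prop_L, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prop_L must be in [0, 1]")
    out = 1.0 - np.abs(p - 0.5) / 0.5
    return float(out) if out.ndim == 0 else out


def build_appearance_table(
    trials: pd.DataFrame,
    thresholds: pd.DataFrame,
    sites: pd.DataFrame,
    return_excluded: bool = False,
):
    """Assemble the per-trial table the color-naming model consumes.

    Parameters
    ----------
    trials : trial table with site_id, wavelength_nm, intensity, seen,
        response; a per-trial ``prop_L_trial`` column is used when present,
        otherwise the site-level prop_L applies to every trial at the site.
    thresholds : per (site_id, wavelength_nm) ``alpha`` estimates.
    sites : per site_id ``prop_L`` and ``s_cone_distance`` (in cone spacings).

    Only seen trials are kept; non-expected chromatic responses are excluded
    from the returned table (set ``return_excluded`` to also get them).
    """
    t = trials.loc[trials["seen"].astype(bool)].copy()
    alpha = thresholds.set_index(["site_id", "wavelength_nm"])["alpha"]
    key = pd.MultiIndex.from_frame(t[["site_id", "wavelength_nm"]])
    missing = ~key.isin(alpha.index)
    if missing.any():
        bad = sorted(set(key[missing]))
        raise KeyError(f"trials reference conditions without thresholds: {bad[:5]}")
    t["alpha"] = alpha.loc[key].to_numpy()
    t["intensity_rel_threshold"] = t["intensity_quanta_s_deg2"] / t["alpha"]

    site_cols = sites.set_index("site_id")
    unknown = set(t["site_id"]) - set(site_cols.index)
    if unknown:
        raise KeyError(f"trials reference unknown sites: {sorted(unknown)[:5]}")
    if "prop_L_trial" in t.columns and t["prop_L_trial"].notna().all():
        t["prop_L"] = t["prop_L_trial"]
    else:
        t["prop_L"] = site_cols["prop_L"].loc[t["site_id"]].to_numpy()
    t["heterogeneity"] = heterogeneity(t["prop_L"].to_numpy())
    t["s_cone_distance"] = site_cols["s_cone_distance"].loc[t["site_id"]].to_numpy()

    expected = t["wavelength_nm"].map(EXPECTED_COLOR)
    t["expected_response"] = t["response"] == expected
    chromatic = t["response"].isin(["red", "green"])
    non_expected = chromatic & ~t["expected_response"]
    kept = t.loc[~non_expected].copy()
    if return_excluded:
        return kept, t.loc[non_expected].copy()
    return kept


def fit_glmm(table: pd.DataFrame) -> GlmmFit:
    """Fit the mixed-effects color-naming model to an appearance table."""
    if len(table) < 200:
        raise ValueError("need at least 200 seen trials for a stable fit")
    for col in ("subject_id", "wavelength_nm"):
        if table[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}")
    X = _design(table)
    return fit_logistic_glmm(
        table["expected_response"].astype(float).to_numpy(), X,
        {"subject": table["subject_id"].to_numpy(),
         "wavelength": table["wavelength_nm"].to_numpy()},
    )


def _design(table: pd.DataFrame, drop: str | None = None) -> pd.DataFrame:
    X = pd.DataFrame({
        "intercept": np.ones(len(table)),
        "log2_intensity": np.log2(table["intensity_rel_threshold"].to_numpy(float)),
        "heterogeneity": table["heterogeneity"].to_numpy(float),
        "s_cone_distance": table["s_cone_distance"].to_numpy(float),
    })
    if drop is not None:
        X = X.drop(columns=[drop])
    return X


def fit_fixed_only(table: pd.DataFrame):
    """Plain logistic fit with only the three fixed covariates (plus intercept).

    Companion model for the mixed-vs-fixed likelihood-ratio comparison and
    the fixed-vs-random coefficient check.
    """
    import statsmodels.api as smapi

    y = table["expected_response"].astype(float).to_numpy()
    if y.min() == y.max():
        raise SeparationError("response has no variation")
    X = _design(table)
    return smapi.Logit(y, X).fit(disp=0)


def compare_models(table: pd.DataFrame) -> pd.DataFrame:
    """Likelihood-ratio comparisons for the color-naming model.

    (a) mixed model vs the fixed-effects-only logistic model (delta df = 2,
        the two random-intercept variances);
    (b) full mixed model vs a reduced mixed model without the heterogeneity
        term (delta df = 1).
    """
    full = fit_glmm(table)
    fixed = fit_fixed_only(table)
    no_het = fit_logistic_glmm(
        table["expected_response"].astype(float).to_numpy(),
        _design(table, drop="heterogeneity"),
        {"subject": table["subject_id"].to_numpy(),
         "wavelength": table["wavelength_nm"].to_numpy()},
    )
    rows = []
    a = lr_test(full.loglik, float(fixed.llf), 2)
    a.update(comparison="mixed_vs_fixed_only",
             delta_aic=full.aic - float(fixed.aic))
    rows.append(a)
    b = lr_test(full.loglik, no_het.loglik, 1)
    b.update(comparison="full_vs_no_heterogeneity",
             delta_aic=full.aic - no_het.aic)
    rows.append(b)
    return pd.DataFrame(rows)[
        ["comparison", "lr_stat", "delta_df", "delta_aic", "p"]
    ]


@dataclass
class ResponseMatrix:
    """Expected-response fraction binned by intensity x local prop_L."""

    intensity_edges: np.ndarray
    prop_L_edges: np.ndarray
    fraction: np.ndarray        # (n_int_bins, n_prop_bins), NaN where masked
    counts: np.ndarray
    successes: np.ndarray
    min_count: int

    @property
    def unmasked_fraction(self) -> np.ndarray:
        """Fractions for every non-empty cell, ignoring the min-count mask."""
        with np.errstate(invalid="ignore"):
            return np.where(self.counts > 0,
                            self.successes / np.maximum(self.counts, 1), np.nan)


def default_intensity_edges(n: int = 8, lo: float = 0.25, hi: float = 16.0) -> np.ndarray:
    """Geometric intensity bins (threshold multiples) straddling 1.0."""
    return np.geomspace(lo, hi, n + 1)


def response_matrix(
    table: pd.DataFrame,
    intensity_edges=None,
    prop_L_edges=None,
    min_count: int = 10,
) -> ResponseMatrix:
    """Bin expected-response fractions by intensity and local prop_L.

    Cells with fewer than ``min_count`` trials are masked (NaN fraction)
    but their counts are retained.
    """
    if len(table) == 0:
        raise ValueError("empty appearance table")
    ie = default_intensity_edges() if intensity_edges is None \
        else np.asarray(intensity_edges, float)
    pe = np.linspace(0.0, 1.0, 9) if prop_L_edges is None \
        else np.asarray(prop_L_edges, float)
    if np.any(np.diff(ie) <= 0) or np.any(np.diff(pe) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    i_bin = np.clip(np.searchsorted(ie, table["intensity_rel_threshold"], "right") - 1,
                    0, len(ie) - 2)
    p_bin = np.clip(np.searchsorted(pe, table["prop_L"], "right") - 1,
                    0, len(pe) - 2)
    shape = (len(ie) - 1, len(pe) - 1)
    counts = np.zeros(shape)
    succ = np.zeros(shape)
    np.add.at(counts, (i_bin, p_bin), 1.0)
    np.add.at(succ, (i_bin, p_bin),
              table["expected_response"].to_numpy(float))
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, succ / np.maximum(counts, 1), np.nan)
    frac = np.where(counts >= min_count, frac, np.nan)
    return ResponseMatrix(intensity_edges=ie, prop_L_edges=pe, fraction=frac,
                          counts=counts, successes=succ, min_count=min_count)


def tertile_curves(table: pd.DataFrame, intensity_edges=None) -> pd.DataFrame:
    """Expected-response fraction vs intensity for heterogeneity tertiles.

    Tertile edges are the empirical 1/3 and 2/3 quantiles of heterogeneity
    over the (seen) trials in ``table``.  Returns one row per
    (tertile, intensity bin) with the fraction, count, and median intensity.
    """
    het = table["heterogeneity"].to_numpy(float)
    if np.unique(het).size < 3:
        raise ValueError("need >= 3 distinct heterogeneity values for tertiles")
    q1, q2 = np.quantile(het, [1.0 / 3.0, 2.0 / 3.0])
    tert = np.digitize(het, [q1, q2])  # 0 = bottom, 1 = middle, 2 = top
    ie = default_intensity_edges() if intensity_edges is None \
        else np.asarray(intensity_edges, float)
    i_bin = np.clip(np.searchsorted(ie, table["intensity_rel_threshold"], "right") - 1,
                    0, len(ie) - 2)
    df = pd.DataFrame({
        "tertile": tert, "intensity_bin": i_bin,
        "expected": table["expected_response"].to_numpy(float),
        "intensity": table["intensity_rel_threshold"].to_numpy(float),
    })
    out = df.groupby(["tertile", "intensity_bin"]).agg(
        fraction=("expected", "mean"),
        count=("expected", "size"),
        median_intensity=("intensity", "median"),
    ).reset_index()
    out.attrs["tertile_edges"] = (float(q1), float(q2))
    return out
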