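"""Synthetic cone mosaics, observers, and psychophysical sessions.

Everything downstream of the instrument is testable without human data:
this module generates (a) jittered-triangular-lattice parafoveal cone
mosaics with a configurable global L/(L+M) proportion and S-cone fraction,
(b) ground-truth observers whose site thresholds follow the additive L+M
model plus log-normal site noise, and (c) full trial tables produced by
interleaved QUEST-like Bayesian staircases with random high-intensity
probe trials, per-frame delivery jitter, Weibull detection behavior, and a
logistic color-naming generator that shares its functional form with the
appearance-analysis GLMM (so parameter recovery is a closed loop).

Default parameters are the study conditions emulated throughout the test
suite: 2.25-arcmin square stimuli at 543 and 680 nm, two 25-trial
staircases per condition starting at 25% and 75% of the maximum intensity,
20% random-intensity probes, and three-frame delivery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spectral_model as sm
from .stimulation_optics import ConeMosaic, StimulationKernel, StimulusSpec

WAVELENGTHS = (543.0, 680.0)

#: global L/(L+M) proportions implied by the two study mosaics' L/M ratios
#: of 1.47 and 3.66.
PROP_L_SUBJECT_A = 1.47 / 2.47
PROP_L_SUBJECT_B = 3.66 / 4.66


@dataclass
class MosaicSpec:
    """Parameters of a jittered triangular cone lattice.

    ``center_spacing`` defaults to 1.1 arcmin, a parafoveal (~2 deg
    eccentricity) cone spacing that puts roughly 4-5 cones under a
    2.25-arcmin stimulus, matching the study geometry.
    """

    n_rows: int = 80
    n_cols: int = 80
    center_spacing: float = 1.1          # arcmin
    positional_jitter_sd: float | None = None  # default 0.1 * spacing
    global_prop_L: float = PROP_L_SUBJECT_A
    s_fraction: float = 0.05
    unclassified_fraction: float = 0.02
    eccentricity_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_spacing <= 0:
            raise ValueError("spacing must be positive")
        for name in ("global_prop_L", "s_fraction", "unclassified_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.s_fraction + self.unclassified_fraction >= 1.0:
            raise ValueError("s_fraction + unclassified_fraction must be < 1")
        if self.positional_jitter_sd is None:
            self.positional_jitter_sd = 0.1 * self.center_spacing


def generate_mosaic(spec: MosaicSpec) -> ConeMosaic:
    """Jittered triangular lattice with i.i.d. cone-type assignment.

    Types: S with probability s_fraction, unclassified with probability
    unclassified_fraction, the rest L with probability global_prop_L
    (else M).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.center_spacing
    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    cc, rr = np.meshgrid(cols, rows)
    x = (cc + 0.5 * (rr % 2)) * s
    y = rr * s * np.sqrt(3.0) / 2.0
    pos = np.c_[x.ravel(), y.ravel()]
    pos -= pos.mean(axis=0)
    pos = pos + rng.normal(0.0, spec.positional_jitter_sd, size=pos.shape)
    n = pos.shape[0]
    u = rng.random(n)
    types = np.full(n, "M", dtype="U1")
    types[u < spec.s_fraction] = "S"
    mid = (u >= spec.s_fraction) & (u < spec.s_fraction + spec.unclassified_fraction)
    types[mid] = "U"
    lm = u >= spec.s_fraction + spec.unclassified_fraction
    types[lm & (rng.random(n) < spec.global_prop_L)] = "L"
    return ConeMosaic(positions=pos, types=types,
                      eccentricity_deg=spec.eccentricity_deg,
                      provenance=f"synthetic(seed={spec.seed})")


@dataclass
class ObserverSpec:
    """Ground-truth observer: optics-independent sensory parameters.

    ``baseline_log10_sensitivity_543`` anchors absolute sensitivity: it is
    the log10 sensitivity (1 / threshold, in (quanta s^-1 deg^-2)^-1) to the
    543-nm primary at a site with balanced L/M input.  ``site_noise_sd`` is
    shared between the two wavelengths at a site (and cancels in their
    ratio); ``wavelength_noise_sd`` is drawn independently per wavelength
    and sets the scatter of observed sensitivity ratios around the additive
    model.  ``chromatic_betas`` are the generative coefficients
    (b0, b1, b2, b3) of the color-naming logistic model.
    """

    age: float = 40.0
    eccentricity_deg: float = 2.0
    outer_segment_length: float = 35.7       # micron
    lambda_max_L: float = 563.4              # nm
    lambda_max_M: float = 530.0
    baseline_log10_sensitivity_543: float = -6.0
    site_noise_sd: float = 0.08              # log10 units, shared per site
    wavelength_noise_sd: float = 0.05        # log10 units, per wavelength
    psychometric_slope: float = 3.0          # Weibull beta
    lapse_rate: float = 0.01
    guess_rate: float = 0.0
    chromatic_betas: tuple = (-2.5, 1.078, 1.707, 0.0)
    random_intercept_sds: tuple = (0.4, 1.0)  # (subject, wavelength)
    bleach_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate < 0.5 and 0.0 <= self.guess_rate < 0.5):
            raise ValueError("lapse and guess rates must be in [0, 0.5)")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric slope must be positive")
        if self.outer_segment_length <= 0:
            raise ValueError("outer segment length must be positive")
        if self.site_noise_sd < 0 or self.wavelength_noise_sd < 0:
            raise ValueError("noise sds must be nonnegative")


def observer_fundamentals(observer: ObserverSpec,
                          wavelengths: np.ndarray | None = None) -> sm.ConeFundamentals:
    """Subject-specific quantal fundamentals for a synthetic observer."""
    filters = sm.PreReceptoralFilters.from_age(
        observer.age, observer.eccentricity_deg, wavelengths=wavelengths)
    pigments = sm.PigmentSpec(
        lambda_max={"L": observer.lambda_max_L, "M": observer.lambda_max_M,
                    "S": 420.0},
        outer_segment_length=observer.outer_segment_length,
        bleach_fraction=observer.bleach_fraction,
    )
    return sm.build_fundamentals(filters, pigments)


def _baseline_intensity(observer: ObserverSpec, exc: dict) -> float:
    """Numerator of the threshold law, anchored at 543 nm and pL = 0.5."""
    mean543 = 0.5 * exc["L543"] + 0.5 * exc["M543"]
    return 10.0 ** (-observer.baseline_log10_sensitivity_543) * mean543


def simulate_threshold_truth(
    observer: ObserverSpec,
    site_prop_L: float,
    wavelength: float,
    fundamentals: sm.ConeFundamentals,
    rng: np.random.Generator,
    shared_noise: float | None = None,
) -> float:
    """Ground-truth detection threshold (quanta s^-1 deg^-2) at one site.

    threshold = baseline / (pL * L_lam + (1 - pL) * M_lam) * 10^eps, where
    eps combines a site-level draw shared between wavelengths
    (``shared_noise``; drawn here from ``site_noise_sd`` if not supplied)
    and an independent per-wavelength draw from ``wavelength_noise_sd``.
    """
    if not (0.0 <= site_prop_L <= 1.0):
        raise ValueError("site_prop_L must be in [0, 1]")
    exc = fundamentals.excitations(wavelengths=(543.0, float(wavelength)))
    key = f"{int(round(wavelength))}"
    denom = site_prop_L * exc[f"L{key}"] + (1.0 - site_prop_L) * exc[f"M{key}"]
    base = _baseline_intensity(observer, fundamentals.excitations())
    if shared_noise is None:
        shared_noise = rng.normal(0.0, observer.site_noise_sd) \
            if observer.site_noise_sd > 0 else 0.0
    eps = shared_noise
    if observer.wavelength_noise_sd > 0:
        eps = eps + rng.normal(0.0, observer.wavelength_noise_sd)
    return base / denom * 10.0 ** eps


def weibull_p_seen(intensity, alpha: float, beta: float,
                   guess: float, lapse: float):
    """Frequency of seeing at the generator's Weibull, anchored at 50%."""
    frac = (0.5 - guess) / (1.0 - guess - lapse)
    scale = alpha / (-np.log(1.0 - frac)) ** (1.0 / beta)
    return guess + (1.0 - guess - lapse) * (
        1.0 - np.exp(-(np.asarray(intensity, float) / scale) ** beta))


class QuestLikeStaircase:
    """Simplified Bayesian staircase over log10 threshold.

    Maintains a grid posterior over the Weibull 50% point (slope, guess,
    and lapse assumed known) and places each trial at the posterior mean.
    A simplification of multi-parameter Bayesian adaptive procedures: the
    simulation only needs realistic intensity placement.
    """

    def __init__(self, start_intensity: float, slope: float,
                 guess: float, lapse: float,
                 grid_lo: float, grid_hi: float, n_grid: int = 201) -> None:
        self.grid = np.linspace(grid_lo, grid_hi, n_grid)
        self.logpost = np.full(n_grid, -np.log(n_grid))
        self.slope = slope
        self.guess = guess
        self.lapse = lapse
        self._next = float(start_intensity)

    def next_intensity(self) -> float:
        return self._next

    def update(self, intensity: float, seen: bool) -> None:
        p = weibull_p_seen(intensity, 10.0 ** self.grid, self.slope,
                           self.guess, self.lapse)
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
        self.logpost += np.log(p if seen else 1.0 - p)
        self.logpost -= self.logpost.max()
        post = np.exp(self.logpost)
        post /= post.sum()
        self._next = float(10.0 ** (self.grid @ post))


@dataclass
class SessionSpec:
    """Structure of a measurement session."""

    n_locations: int = 32
    trials_per_staircase: int = 25
    staircases_per_condition: int = 2
    staircase_starts: tuple = (0.25, 0.75)   # fractions of max intensity
    random_probe_rate: float = 0.2
    delivery_jitter_sd: float = 0.08         # arcmin, per frame and axis
    n_frames: int = 3
    max_intensity_multiple: float = 50.0     # x predicted threshold at pL=0.5
    non_expected_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_staircase < 1:
            raise ValueError("trials_per_staircase must be >= 1")
        if self.staircases_per_condition < 1:
            raise ValueError("need at least one staircase per condition")
        if not (0.0 <= self.random_probe_rate <= 1.0):
            raise ValueError("random_probe_rate must be in [0, 1]")
        if len(self.staircase_starts) < self.staircases_per_condition:
            raise ValueError("need a start fraction per staircase")


def draw_random_intercepts(rng: np.random.Generator, sds, n_levels: int = 2,
                           center: bool = True) -> np.ndarray:
    """Random-intercept values per factor level.

    With ``center=True`` each factor's draws are recentered to sum to zero,
    so the fixed intercept stays identified in simulated datasets (the
    grouping factors here have only two levels each).
    """
    out = np.array([rng.normal(0.0, sd, n_levels) for sd in np.atleast_1d(sds)])
    if center:
        out = out - out.mean(axis=1, keepdims=True)
    return out


def simulate_color_response(
    intensity_rel_threshold: float,
    heterogeneity: float,
    s_cone_distance: float,
    observer: ObserverSpec,
    wavelength: float,
    rng: np.random.Generator,
    b_subject: float = 0.0,
    b_wavelength: float = 0.0,
    non_expected_rate: float = 0.005,
) -> str:
    """Color report for one seen trial: 'red', 'green', or 'achromatic'.

    P(expected chromatic) follows the logistic model; a non-expected
    chromatic report occurs with the small fixed probability
    ``non_expected_rate`` (independent of covariates); otherwise the
    report is achromatic.
    """
    if intensity_rel_threshold <= 0:
        raise ValueError("intensity_rel_threshold must be positive")
    from scipy.special import expit

    b0, b1, b2, b3 = observer.chromatic_betas
    eta = (b0 + b1 * np.log2(intensity_rel_threshold) + b2 * heterogeneity
           + b3 * s_cone_distance + b_subject + b_wavelength)
    p = expit(eta)
    expected = "red" if int(round(wavelength)) == 680 else "green"
    other = "green" if expected == "red" else "red"
    u = rng.random()
    if u < p:
        return expected
    if u < p + non_expected_rate * (1.0 - p):
        return other
    return "achromatic"


def choose_sites(mosaic: ConeMosaic, n: int, rng: np.random.Generator,
                 margin: float = 4.0) -> np.ndarray:
    """Uniform-random test sites inside the mosaic minus a safety margin."""
    (x0, x1), (y0, y1) = mosaic.bounds()
    if x1 - x0 <= 2 * margin or y1 - y0 <= 2 * margin:
        raise ValueError("mosaic too small for the requested margin")
    return np.c_[rng.uniform(x0 + margin, x1 - margin, n),
                 rng.uniform(y0 + margin, y1 - margin, n)]


def simulate_session(
    mosaic: ConeMosaic,
    observer: ObserverSpec,
    session: SessionSpec,
    sites: np.ndarray | None = None,
    fundamentals: sm.ConeFundamentals | None = None,
    kernels: dict | None = None,
    subject_id: str = "S1",
    b_subject: float = 0.0,
    b_wavelength: dict | None = None,
    pitch: float = 0.025,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full detection-plus-naming experiment at one retina.

    Returns ``(trials, sites_table)``.  The trial table has one row per
    presentation with delivery offsets, the QUEST-like or probe intensity,
    the seen flag, and the color response; the sites table carries
    ground-truth thresholds, nominal and trial-averaged prop_L, and S-cone
    distances.  Reproducible: every (site, wavelength, staircase) stream is
    seeded from the session seed.
    """
    from .stimulation_optics import cone_spacing, s_cone_distance

    if fundamentals is None:
        fundamentals = observer_fundamentals(observer)
    if kernels is None:
        kernels = {wl: StimulationKernel(StimulusSpec(wavelength=wl), pitch=pitch)
                   for wl in WAVELENGTHS}
    master = np.random.default_rng(session.seed)
    if sites is None:
        sites = choose_sites(mosaic, session.n_locations, master)
    sites = np.atleast_2d(np.asarray(sites, float))
    n_sites = sites.shape[0]
    spacing = cone_spacing(mosaic)
    exc = fundamentals.excitations()
    base = _baseline_intensity(observer, exc)
    if b_wavelength is None:
        b_wavelength = {wl: 0.0 for wl in WAVELENGTHS}

    site_rows = []
    trial_specs = []   # (site, wl, staircase_id, is_probe flags ordered)
    truth = {}
    for s_idx in range(n_sites):
        center = sites[s_idx]
        shared = master.normal(0.0, observer.site_noise_sd) \
            if observer.site_noise_sd > 0 else 0.0
        row = {"site_id": s_idx, "x_arcmin": center[0], "y_arcmin": center[1],
               "s_cone_distance": s_cone_distance(mosaic, center, spacing)}
        for wl in WAVELENGTHS:
            summ = kernels[wl].summary(mosaic, center)
            key = f"{int(wl)}"
            denom = (summ.prop_L * exc[f"L{key}"]
                     + (1.0 - summ.prop_L) * exc[f"M{key}"])
            rng_wl = np.random.default_rng(
                [session.seed, s_idx, int(wl), 999])
            eps = shared + (rng_wl.normal(0.0, observer.wavelength_noise_sd)
                            if observer.wavelength_noise_sd > 0 else 0.0)
            alpha = base / denom * 10.0 ** eps
            truth[(s_idx, wl)] = alpha
            row[f"prop_L_{int(wl)}"] = summ.prop_L
            row[f"prop_L_min_{int(wl)}"] = summ.prop_L_range[0]
            row[f"prop_L_max_{int(wl)}"] = summ.prop_L_range[1]
            row[f"true_threshold_{int(wl)}"] = alpha
        site_rows.append(row)
        for wl in WAVELENGTHS:
            for k in range(session.staircases_per_condition):
                for t in range(session.trials_per_staircase):
                    trial_specs.append((s_idx, wl, k))

    order = master.permutation(len(trial_specs))
    staircases = {}
    max_int = {}
    for wl in WAVELENGTHS:
        key = f"{int(wl)}"
        denom = 0.5 * exc[f"L{key}"] + 0.5 * exc[f"M{key}"]
        max_int[wl] = session.max_intensity_multiple * base / denom

    records = []
    for trial_id, j in enumerate(order):
        s_idx, wl, k = trial_specs[j]
        sc_key = (s_idx, wl, k)
        if sc_key not in staircases:
            alpha = truth[(s_idx, wl)]
            lo = np.log10(alpha) - 1.5
            hi = np.log10(max_int[wl])
            staircases[sc_key] = QuestLikeStaircase(
                session.staircase_starts[k] * max_int[wl],
                observer.psychometric_slope, observer.guess_rate,
                observer.lapse_rate, lo, hi)
        rng = np.random.default_rng([session.seed, s_idx, int(wl), k, trial_id])
        sc = staircases[sc_key]
        is_probe = rng.random() < session.random_probe_rate
        intensity = (rng.uniform(0.0, max_int[wl]) if is_probe
                     else sc.next_intensity())
        intensity = max(intensity, max_int[wl] * 1e-6)
        offsets = rng.normal(0.0, session.delivery_jitter_sd,
                             size=(session.n_frames, 2)) \
            if session.delivery_jitter_sd > 0 else np.zeros((session.n_frames, 2))
        delivered = sites[s_idx] + offsets.mean(axis=0)
        p_trial = float(kernels[wl].prop_L(mosaic, delivered[None, :])[0])
        alpha = truth[(s_idx, wl)]
        p_seen = weibull_p_seen(intensity, alpha, observer.psychometric_slope,
                                observer.guess_rate, observer.lapse_rate)
        seen = bool(rng.random() < p_seen)
        sc.update(intensity, seen)
        if seen:
            het = 1.0 - abs(p_trial - 0.5) / 0.5 if np.isfinite(p_trial) else np.nan
            response = simulate_color_response(
                intensity / alpha, het,
                site_rows[s_idx]["s_cone_distance"], observer, wl, rng,
                b_subject=b_subject, b_wavelength=b_wavelength[wl],
                non_expected_rate=session.non_expected_rate)
        else:
            response = "not_seen"
        records.append({
            "trial_id": trial_id, "subject_id": subject_id, "site_id": s_idx,
            "wavelength_nm": wl, "staircase": k, "is_probe": is_probe,
            "intensity_quanta_s_deg2": intensity,
            "max_abs_dx_arcmin": float(np.abs(offsets[:, 0]).max()),
            "max_abs_dy_arcmin": float(np.abs(offsets[:, 1]).max()),
            "prop_L_trial": p_trial,
            "seen": seen, "response": response,
        })
    trials = pd.DataFrame(records)
    sites_df = pd.DataFrame(site_rows)
    # trial-averaged prop_L per site/wavelength (the value analyses report)
    avg = trials.groupby(["site_id", "wavelength_nm"])["prop_L_trial"].mean()
    for wl in WAVELENGTHS:
        col = [avg.get((s, wl), np.nan) for s in range(n_sites)]
        sites_df[f"prop_L_mean_{int(wl)}"] = col
    return trials, sites_df


def simulate_appearance_dataset(
    n: int,
    betas,
    intercept_sds,
    rng: np.random.Generator,
    s_cone_effect_subjects: int = 2,
    center_intercepts: bool = True,
) -> pd.DataFrame:
    """Covariate-level generator for color-naming model recovery studies.

    Draws realistic covariates directly (bypassing the optics): log2
    threshold multiples concentrated near threshold with a supra-threshold
    probe tail, heterogeneity from per-subject beta-distributed local
    prop_L, and S-cone distances on the cone-spacing scale.  Responses
    follow the logistic model with the given fixed effects and recentered
    random intercepts.
    """
    from scipy.special import expit

    betas = np.asarray(betas, float)
    subj = rng.integers(0, s_cone_effect_subjects, n)
    wl = np.where(rng.integers(0, 2, n) == 0, 543.0, 680.0)
    bs, bw = draw_random_intercepts(rng, intercept_sds, 2, center_intercepts)
    log2_int = np.where(rng.random(n) < 0.8,
                        rng.normal(0.3, 0.7, n), rng.uniform(2.0, 5.0, n))
    ab = np.where(subj == 0, 4.0, 7.0)
    prop_l = rng.beta(ab, 9.0 - ab)
    het = 1.0 - np.abs(prop_l - 0.5) / 0.5
    sdist = rng.gamma(3.0, 0.5, n) + 0.2
    eta = (betas[0] + betas[1] * log2_int + betas[2] * het + betas[3] * sdist
           + bs[subj] + bw[(wl == 680.0).astype(int)])
    y = rng.random(n) < expit(eta)
    return pd.DataFrame({
        "subject_id": subj, "wavelength_nm": wl,
        "intensity_rel_threshold": 2.0 ** log2_int,
        "prop_L": prop_l, "heterogeneity": het, "s_cone_distance": sdist,
        "expected_response": y,
    })
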