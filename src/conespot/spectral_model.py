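"""Subject-specific quantal cone fundamentals.

Builds corneal quantal spectral sensitivities for the L, M, and S cone
classes from four ingredients:

* an age-scaled lens optical-density spectrum,
* a macular pigment template scaled by the peak macular pigment optical
  density (MPOD) estimated over the interval of eccentricities spanned by
  the stimulus,
* a photopigment absorbance template positioned at a class-specific
  lambda_max (Govardovskii A1 nomogram), and
* self-screening through an axial pigment density
  d_eff = specific density x outer-segment length x (1 - bleached fraction),
  with steady-state bleaching given by first-order kinetics
  I / (I + I0) at half-bleach constant I0.

The corneal quantal sensitivity is

    S_c(lambda) = [1 - 10^(-d_eff * A_c(lambda))] * 10^(-D_lens(lambda) - MPOD * T_mac(lambda))

Only ratios of sensitivities at the two stimulus primaries (543 and 680 nm)
enter the additive detection model, so the overall normalization convention
cancels there; the curves are returned unnormalized.

The lens and macular shapes are smooth parametric approximations with the
standard qualitative behavior (steeply falling lens density above 400 nm,
scaled linearly with age; macular template peaking at 460 nm and vanishing
above ~550 nm).  Both are configurable: pass custom callables or arrays
where an individually measured spectrum is available.  At 543 and 680 nm
both filters are near zero, so the detection-model predictions are
insensitive to their exact shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_GRID = np.arange(390.0, 781.0, 1.0)
HALF_BLEACH_ISO_PER_S = 10 ** 6.4
#: default axial specific density of cone photopigment, OD per micron
DEFAULT_SPECIFIC_DENSITY = 0.015


# ---------------------------------------------------------------------------
# templates

def pigment_absorbance(wavelength_nm, lambda_max: float) -> np.ndarray:
    """Normalized A1 photopigment absorbance template (Govardovskii nomogram).

    Peak value 1 at ``lambda_max``; includes the alpha and beta bands.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lmb) / b) ** 2))
    t = alpha + beta
    return t / t.max() if t.ndim else t


def lens_density(wavelength_nm, age: float = 40.0) -> np.ndarray:
    """Lens optical density vs wavelength, scaled for age-related yellowing.

    Parametric: OD(400 nm) = 1.7 for a 32-year-old standard eye, decaying
    exponentially with wavelength (scale 45 nm), scaled by 1 + 0.02*(age-32).
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    base = 1.7 * np.exp(-(lam - 400.0) / 45.0)
    base = np.where(lam < 400.0, 1.7 * (1.0 + (400.0 - lam) * 0.02), base)
    scale = max(1.0 + 0.02 * (age - 32.0), 0.2)
    return np.maximum(base * scale, 0.0)


def _macular_shape(lam: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * ((lam - 460.0) / 25.0) ** 2) \
        + 0.35 * np.exp(-0.5 * ((lam - 480.0) / 12.0) ** 2)


_MACULAR_PEAK = float(_macular_shape(np.arange(420.0, 520.0, 0.01)).max())


def macular_template(wavelength_nm) -> np.ndarray:
    """Macular pigment optical density template, normalized to 1 at its peak."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return _macular_shape(lam) / _MACULAR_PEAK


def default_mpod_vs_field_size(field_deg) -> np.ndarray:
    """Average MPOD within a centered field, as a function of field size (deg).

    Monotone decline with field size: 0.485 at 2 deg falling with scale
    4.9 deg, matching the standard-observer convention that macular density
    is lower for larger fields.
    """
    f = np.asarray(field_deg, dtype=float)
    return 0.485 * np.exp(-(f - 2.0) / 4.9)


# ---------------------------------------------------------------------------
# MPOD at an eccentric test locus

def mpod_peak(e1: float, e2: float, density_vs_fieldsize=default_mpod_vs_field_size) -> float:
    """Peak MPOD between eccentricities e1 and e2 (degrees).

    Inverts the field-size-averaged density function D(.) on the annulus
    between e1 and e2:

        MPOD_peak = -log10[ (10^(-D(2 e2)) e2^2 - 10^(-D(2 e1)) e1^2) / (e2^2 - e1^2) ]

    assuming radial symmetry of the macular pigment distribution.
    """
    if not (0.0 < e1 < e2):
        raise ValueError("need 0 < e1 < e2")
    d1 = float(density_vs_fieldsize(2.0 * e1))
    d2 = float(density_vs_fieldsize(2.0 * e2))
    num = 10.0 ** (-d2) * e2 ** 2 - 10.0 ** (-d1) * e1 ** 2
    den = e2 ** 2 - e1 ** 2
    arg = num / den
    if arg <= 0:
        raise ValueError("inconsistent density function: log argument <= 0")
    return float(-np.log10(arg))


def mpod_peak_for_stimulus(
    eccentricity_deg: float,
    stimulus_diameter_deg: float,
    density_vs_fieldsize=default_mpod_vs_field_size,
) -> float:
    """MPOD at a test locus: the e2 - e1 interval equals the stimulus
    diameter, centered on the tested eccentricity."""
    half = stimulus_diameter_deg / 2.0
    return mpod_peak(eccentricity_deg - half, eccentricity_deg + half,
                     density_vs_fieldsize)


# ---------------------------------------------------------------------------
# bleaching

def steady_state_bleach(isomerization_rate: float,
                        half_bleach: float = HALF_BLEACH_ISO_PER_S) -> float:
    """Steady-state bleached fraction I / (I + I0), first-order kinetics."""
    if isomerization_rate < 0 or half_bleach <= 0:
        raise ValueError("rates must be nonnegative (half_bleach positive)")
    return isomerization_rate / (isomerization_rate + half_bleach)


# ---------------------------------------------------------------------------
# fundamentals

@dataclass
class PreReceptoralFilters:
    """Lens and macular pigment filtering on a wavelength grid."""

    wavelengths: np.ndarray
    lens: np.ndarray              # OD
    macular: np.ndarray           # normalized template
    mpod_peak: float              # OD at template peak

    @classmethod
    def from_age(
        cls,
        age: float = 40.0,
        eccentricity_deg: float = 2.0,
        stimulus_diameter_deg: float = 2.25 / 60.0,
        wavelengths: np.ndarray | None = None,
        density_vs_fieldsize=default_mpod_vs_field_size,
    ) -> "PreReceptoralFilters":
        grid = DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, float)
        return cls(
            wavelengths=grid,
            lens=lens_density(grid, age),
            macular=macular_template(grid),
            mpod_peak=mpod_peak_for_stimulus(eccentricity_deg,
                                             stimulus_diameter_deg,
                                             density_vs_fieldsize),
        )

    def __post_init__(self) -> None:
        if np.any(self.lens < 0) or self.mpod_peak < 0:
            raise ValueError("densities must be nonnegative")


@dataclass
class PigmentSpec:
    """Photopigment peak wavelengths and axial density inputs."""

    lambda_max: dict = field(
        default_factory=lambda: {"L": 563.4, "M": 530.0, "S": 420.0})
    specific_density: float = DEFAULT_SPECIFIC_DENSITY   # OD / micron
    outer_segment_length: float = 35.7                   # micron
    bleach_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.outer_segment_length <= 0 or self.specific_density <= 0:
            raise ValueError("axial density factors must be positive")
        if not (0.0 <= self.bleach_fraction < 1.0):
            raise ValueError("bleach_fraction must be in [0, 1)")

    @property
    def effective_axial_density(self) -> float:
        return (self.specific_density * self.outer_segment_length
                * (1.0 - self.bleach_fraction))


@dataclass
class ConeFundamentals:
    """Corneal quantal sensitivities per cone class on a wavelength grid."""

    wavelengths: np.ndarray
    sensitivities: dict           # class -> array
    primary_fwhm: dict | None = None

    def excitation(self, cone_class: str, wavelength: float) -> float:
        """Quantal excitation per corneal quantum at one primary wavelength.

        If ``primary_fwhm`` defines a bandwidth for this wavelength, the
        sensitivity is integrated under a Gaussian primary spectrum of that
        FWHM; otherwise the primary is treated as monochromatic.
        """
        grid = self.wavelengths
        if wavelength < grid[0] or wavelength > grid[-1]:
            raise ValueError(f"wavelength {wavelength} nm outside the grid")
        s = self.sensitivities[cone_class]
        if self.primary_fwhm and wavelength in self.primary_fwhm:
            fwhm = self.primary_fwhm[wavelength]
            sig = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            w = np.exp(-0.5 * ((grid - wavelength) / sig) ** 2)
            return float(np.trapezoid(w * s, grid) / np.trapezoid(w, grid))
        return float(np.interp(wavelength, grid, s))

    def excitations(self, wavelengths=(543.0, 680.0), classes=("L", "M")) -> dict:
        """e.g. {"L543": ..., "M543": ..., "L680": ..., "M680": ...}"""
        return {
            f"{c}{int(round(w))}": self.excitation(c, w)
            for w in wavelengths for c in classes
        }


def build_fundamentals(
    filters: PreReceptoralFilters,
    pigments: PigmentSpec,
    wavelengths: np.ndarray | None = None,
    primary_fwhm: dict | None = None,
) -> ConeFundamentals:
    """Assemble corneal quantal fundamentals from filters and pigments.

    absorptance(lambda) = 1 - 10^(-d_eff * A(lambda)) (self-screening), then
    multiplied by the pre-receptoral transmittance
    10^(-lens - mpod_peak * macular).
    """
    grid = filters.wavelengths if wavelengths is None else np.asarray(wavelengths, float)
    if not (grid[0] <= 680.0 <= grid[-1]):
        raise ValueError("wavelength grid must cover 680 nm")
    lens = np.interp(grid, filters.wavelengths, filters.lens)
    mac = np.interp(grid, filters.wavelengths, filters.macular)
    pre = 10.0 ** (-(lens + filters.mpod_peak * mac))
    d = pigments.effective_axial_density
    sens = {}
    for c, lmax in pigments.lambda_max.items():
        a = pigment_absorbance(grid, lmax)
        absorptance = 1.0 - 10.0 ** (-d * a)
        sens[c] = absorptance * pre
    return ConeFundamentals(wavelengths=grid, sensitivities=sens,
                            primary_fwhm=primary_fwhm)


def fundamentals_to_frame(f: ConeFundamentals):
    """CSV-ready table: wavelength_nm plus one column per cone class."""
    import pandas as pd

    d = {"wavelength_nm": f.wavelengths}
    d.update({c: f.sensitivities[c] for c in sorted(f.sensitivities)})
    return pd.DataFrame(d)
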