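"""Retinal light distributions and aperture-weighted cone stimulation.

A small square stimulus delivered through a large pupil is blurred by
diffraction and residual defocus before it reaches the photoreceptors.  This
module computes the retinal light field of such a stimulus (circular-pupil
diffraction PSF with a quadratic defocus phase, convolved with the stimulus
shape) and the fractional number of L/M/S cones it stimulates, where each
cone's light-collecting aperture is a unit-volume 2-D Gaussian.  The key
derived quantity is "proportion L": the aperture-weighted number of
stimulated L cones out of all stimulated L and M cones.

Coordinates are arcmin of visual angle, y-up, origin at the mosaic center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.spatial import Delaunay, QhullError, cKDTree

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi
CONE_TYPES = ("L", "M", "S", "U")

#: Default cone aperture full width at half maximum, arcmin.
APERTURE_FWHM_ARCMIN = 0.59


class PropLUndefinedError(ValueError):
    """Raised when no classified L or M cone receives any stimulus light."""


def pixel_subtense_arcmin(field_deg: float, n_pixels: int) -> float:
    """Angular subtense of one pixel for a square imaging field.

    A 0.9 degree field sampled over 512 pixels subtends ~0.11 arcmin/pixel.
    """
    if field_deg <= 0 or n_pixels <= 0:
        raise ValueError("field size and pixel count must be positive")
    return field_deg * 60.0 / n_pixels


@dataclass
class ConeMosaic:
    """Labeled cone positions: (x, y) in arcmin and a spectral type per cone.

    Types are 'L', 'M', 'S', or 'U' (unclassified).
    """

    positions: np.ndarray
    types: np.ndarray
    eccentricity_deg: float = 2.0
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.types = np.asarray(self.types, dtype="U1")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.types.shape[0] != self.positions.shape[0]:
            raise ValueError("types and positions must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("cone positions must be finite")
        bad = set(np.unique(self.types)) - set(CONE_TYPES)
        if bad:
            raise ValueError(f"unknown cone types: {sorted(bad)}")
        contig = np.ascontiguousarray(self.positions)
        uniq = np.unique(contig.view([("x", float), ("y", float)]))
        if uniq.shape[0] != self.positions.shape[0]:
            raise ValueError("duplicate cone positions")

    @property
    def n_cones(self) -> int:
        return self.positions.shape[0]

    def type_mask(self, cone_type: str) -> np.ndarray:
        return self.types == cone_type

    def counts(self) -> dict:
        return {t: int(np.sum(self.types == t)) for t in CONE_TYPES}

    def global_prop_L(self) -> float:
        c = self.counts()
        if c["L"] + c["M"] == 0:
            raise PropLUndefinedError("mosaic has no classified L or M cones")
        return c["L"] / (c["L"] + c["M"])

    def bounds(self) -> tuple:
        """((xmin, xmax), (ymin, ymax)) of cone centers."""
        lo = self.positions.min(axis=0)
        hi = self.positions.max(axis=0)
        return (lo[0], hi[0]), (lo[1], hi[1])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_arcmin": self.positions[:, 0],
                "y_arcmin": self.positions[:, 1],
                "type": self.types,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, eccentricity_deg: float = 2.0,
                 provenance: str = "file") -> "ConeMosaic":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x_arcmin", "y_arcmin"]].to_numpy(float),
            types=df["type"].to_numpy(str),
            eccentricity_deg=eccentricity_deg,
            provenance=provenance,
        )


@dataclass
class StimulusSpec:
    """Square increment stimulus and the optics it is delivered through."""

    side_length: float = 2.25        # arcmin
    wavelength: float = 543.0        # nm
    pupil_diameter: float = 6.5      # mm
    residual_defocus: float = 0.05   # diopters
    center: tuple = (0.0, 0.0)       # arcmin

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.pupil_diameter <= 0:
            raise ValueError("pupil_diameter must be positive")
        if self.residual_defocus < 0:
            raise ValueError("residual_defocus must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def area(self) -> float:
        return self.side_length ** 2


@dataclass
class RetinalLightField:
    """2-D scalar intensity grid.  values[i, j] lives at
    (x, y) = (origin[0] + j*pitch, origin[1] + i*pitch)."""

    values: np.ndarray
    pitch: float
    origin: tuple

    def integral(self) -> float:
        return float(self.values.sum() * self.pitch ** 2)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.pitch * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.pitch * np.arange(self.values.shape[0])


@dataclass
class StimulationSummary:
    """Aperture-weighted fractional cone counts under one delivered stimulus.

    Counts are dimensionless: with a unit-height stimulus profile a cone fully
    inside the stimulus contributes ~1, so ``total_cones`` approximates the
    number of cones receiving the light.  ``prop_L`` uses classified cones
    only; ``prop_L_range`` brackets it by assigning every unclassified cone's
    aperture mass entirely to L (max) or entirely to M (min).
    """

    n_L: float
    n_M: float
    n_S: float
    n_U: float
    prop_L: float
    prop_L_range: tuple

    @property
    def total_cones(self) -> float:
        return self.n_L + self.n_M + self.n_S


def _airy_radius_arcmin(wavelength_nm: float, pupil_diameter_mm: float) -> float:
    return 1.22 * (wavelength_nm * 1e-9) / (pupil_diameter_mm * 1e-3) * ARCMIN_PER_RAD


def diffraction_psf(
    wavelength: float,
    pupil_diameter: float = 6.5,
    defocus: float = 0.05,
    pitch: float = 0.025,
    extent: float | None = None,
    n_quad: int = 400,
) -> RetinalLightField:
    """Diffraction-limited PSF of a circular pupil with residual defocus.

    The amplitude at field angle theta is the radial pupil integral
    ``U(theta) = 2 * int_0^1 exp(i*phi0*rho^2) J0(pi*D*theta*rho/lambda) rho drho``
    with the defocus wavefront W(rho) = dD * a^2 * rho^2 / 2 entering as
    phi0 = pi * dD * a^2 / lambda (a = pupil radius).  PSF = |U|^2, volume
    normalized to unity on the returned grid.

    Parameters are nm, mm, diopters, arcmin.
    """
    if pitch > 0.05:
        raise ValueError("grid pitch must be <= 0.05 arcmin to resolve the Airy core")
    airy = _airy_radius_arcmin(wavelength, pupil_diameter)
    # defocus blur disc radius (geometric): dD * a, in radians
    blur = defocus * (pupil_diameter * 1e-3 / 2.0) * ARCMIN_PER_RAD
    if extent is None:
        extent = max(6.0 * airy, 4.0 * blur + 6.0 * airy, 4.0)
    n = int(np.ceil(extent / pitch / 2)) * 2 + 1  # odd, symmetric about 0
    half = (n - 1) // 2
    coords = pitch * (np.arange(n) - half)
    xx, yy = np.meshgrid(coords, coords)
    rr = np.hypot(xx, yy)

    lam_m = wavelength * 1e-9
    a = pupil_diameter * 1e-3 / 2.0
    phi0 = np.pi * defocus * a ** 2 / lam_m

    # radial profile on a fine 1-D grid, then interpolated onto the 2-D grid
    r1d = np.arange(0.0, rr.max() + pitch, pitch / 2.0)
    theta = r1d / ARCMIN_PER_RAD  # radians
    from numpy.polynomial.legendre import leggauss
    from scipy.special import j0

    nodes, wts = leggauss(n_quad)
    rho = 0.5 * (nodes + 1.0)     # map to (0, 1)
    w = 0.5 * wts
    ker = np.exp(1j * phi0 * rho ** 2) * rho * w          # (q,)
    arg = (np.pi * pupil_diameter * 1e-3 / lam_m) * np.outer(theta, rho)
    u = 2.0 * (j0(arg) @ ker)                              # (len(r1d),)
    prof = np.abs(u) ** 2

    vals = np.interp(rr.ravel(), r1d, prof).reshape(rr.shape)
    vals /= vals.sum() * pitch ** 2
    return RetinalLightField(values=vals, pitch=pitch,
                             origin=(-half * pitch, -half * pitch))


def _square_indicator(side: float, pitch: float, n: int, half: int) -> np.ndarray:
    """Separable partial-pixel coverage of a centered square on an n x n grid."""
    c = pitch * (np.arange(n) - half)
    # overlap of pixel [c - pitch/2, c + pitch/2] with [-side/2, side/2]
    lo = np.maximum(c - pitch / 2.0, -side / 2.0)
    hi = np.minimum(c + pitch / 2.0, side / 2.0)
    cov = np.clip(hi - lo, 0.0, None) / pitch
    return np.outer(cov, cov)


def stimulus_light_field(stim: StimulusSpec, psf: RetinalLightField) -> RetinalLightField:
    """Unit-integral square stimulus convolved with a unit-volume PSF.

    The result is centered on ``stim.center`` and has integral 1.
    """
    pitch = psf.pitch
    npsf = psf.values.shape[0]
    nsq = int(np.ceil(stim.side_length / pitch / 2)) * 2 + 1
    sq = _square_indicator(stim.side_length, pitch, nsq, (nsq - 1) // 2)
    sq = sq / (sq.sum() * pitch ** 2)
    out = fftconvolve(sq, psf.values, mode="full") * pitch ** 2
    out = np.clip(out, 0.0, None)
    n = out.shape[0]
    half = (n - 1) // 2
    return RetinalLightField(
        values=out,
        pitch=pitch,
        origin=(stim.center[0] - half * pitch, stim.center[1] - half * pitch),
    )


def aperture_sigma(fwhm: float = APERTURE_FWHM_ARCMIN) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def stimulated_cone_counts(
    field: RetinalLightField,
    mosaic: ConeMosaic,
    aperture_fwhm: float = APERTURE_FWHM_ARCMIN,
    scale: float = 1.0,
) -> StimulationSummary:
    """Aperture-weighted cone counts under a retinal light field.

    Each cone contributes ``scale * integral(field * G_cone)`` where G_cone is
    a unit-volume Gaussian aperture (FWHM ``aperture_fwhm``).  With a
    unit-integral field, pass ``scale = stimulus area`` so a fully covered
    cone counts ~1 (see ``stimulate``).
    """
    if mosaic.n_cones == 0:
        raise ValueError("mosaic is empty")
    sig = aperture_sigma(aperture_fwhm)
    pitch = field.pitch
    gx, gy = field.x, field.y
    reach = 4.0 * sig
    # restrict to cones whose aperture overlaps the field support
    inside = (
        (mosaic.positions[:, 0] >= gx[0] - reach)
        & (mosaic.positions[:, 0] <= gx[-1] + reach)
        & (mosaic.positions[:, 1] >= gy[0] - reach)
        & (mosaic.positions[:, 1] <= gy[-1] + reach)
    )
    idx = np.nonzero(inside)[0]
    totals = dict.fromkeys(CONE_TYPES, 0.0)
    norm = 1.0 / (2.0 * np.pi * sig ** 2)
    for i in idx:
        cx, cy = mosaic.positions[i]
        j0 = np.searchsorted(gx, cx - reach)
        j1 = np.searchsorted(gx, cx + reach)
        i0 = np.searchsorted(gy, cy - reach)
        i1 = np.searchsorted(gy, cy + reach)
        if j1 <= j0 or i1 <= i0:
            continue
        ax = np.exp(-0.5 * ((gx[j0:j1] - cx) / sig) ** 2)
        ay = np.exp(-0.5 * ((gy[i0:i1] - cy) / sig) ** 2)
        g = norm * np.outer(ay, ax)
        totals[mosaic.types[i]] += float(
            (field.values[i0:i1, j0:j1] * g).sum() * pitch ** 2
        )
    n_L = totals["L"] * scale
    n_M = totals["M"] * scale
    n_S = totals["S"] * scale
    n_U = totals["U"] * scale
    lm = n_L + n_M
    if lm <= 1e-12:
        raise PropLUndefinedError("no classified L or M cone under the stimulus")
    prop_L = n_L / lm
    prop_L_range = (n_L / (lm + n_U), (n_L + n_U) / (lm + n_U))
    return StimulationSummary(n_L=n_L, n_M=n_M, n_S=n_S, n_U=n_U,
                              prop_L=prop_L, prop_L_range=prop_L_range)


def stimulate(
    mosaic: ConeMosaic,
    stim: StimulusSpec,
    aperture_fwhm: float = APERTURE_FWHM_ARCMIN,
    pitch: float = 0.025,
) -> StimulationSummary:
    """PSF -> light field -> aperture-weighted counts for one stimulus."""
    psf = diffraction_psf(stim.wavelength, stim.pupil_diameter,
                          stim.residual_defocus, pitch=pitch)
    field = stimulus_light_field(stim, psf)
    return stimulated_cone_counts(field, mosaic, aperture_fwhm, scale=stim.area)


class StimulationKernel:
    """Precomputed stimulation kernel for fast repeated prop_L queries.

    Because the light field is translation invariant, the count contributed
    by a cone at displacement d from the stimulus center equals
    K(d) = scale * (field * aperture)(d).  K is precomputed once on a grid;
    querying a delivery center reduces to bilinear interpolation of K at the
    displacements of nearby cones.  Used by the session simulator and the
    Monte Carlo site sampler, and cross-checked against
    ``stimulated_cone_counts`` in the test suite.
    """

    def __init__(
        self,
        stim: StimulusSpec,
        aperture_fwhm: float = APERTURE_FWHM_ARCMIN,
        pitch: float = 0.025,
    ) -> None:
        self.stim = stim
        self.pitch = pitch
        psf = diffraction_psf(stim.wavelength, stim.pupil_diameter,
                              stim.residual_defocus, pitch=pitch)
        centered = StimulusSpec(
            side_length=stim.side_length, wavelength=stim.wavelength,
            pupil_diameter=stim.pupil_diameter,
            residual_defocus=stim.residual_defocus, center=(0.0, 0.0),
        )
        field = stimulus_light_field(centered, psf)
        sig = aperture_sigma(aperture_fwhm)
        reach = 4.0 * sig
        nap = int(np.ceil(reach / pitch)) * 2 + 1
        hap = (nap - 1) // 2
        c = pitch * (np.arange(nap) - hap)
        g = np.exp(-0.5 * (c / sig) ** 2)
        ap = np.outer(g, g) / (2.0 * np.pi * sig ** 2)
        k = fftconvolve(field.values, ap, mode="full") * pitch ** 2 * stim.area
        n = k.shape[0]
        half = (n - 1) // 2
        self.k = k
        self.half = half
        # effective radius: where the radial max of K falls below 1e-9 of peak
        coords = pitch * (np.arange(n) - half)
        xx, yy = np.meshgrid(coords, coords)
        rr = np.hypot(xx, yy)
        thresh = k.max() * 1e-9
        live = rr[k > thresh]
        self.radius = float(live.max()) if live.size else half * pitch

    def _interp(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of K at displacements (dx, dy)."""
        p = self.pitch
        fx = dx / p + self.half
        fy = dy / p + self.half
        n = self.k.shape[0]
        j0 = np.clip(np.floor(fx).astype(int), 0, n - 2)
        i0 = np.clip(np.floor(fy).astype(int), 0, n - 2)
        tx = np.clip(fx - j0, 0.0, 1.0)
        ty = np.clip(fy - i0, 0.0, 1.0)
        k = self.k
        out = (
            k[i0, j0] * (1 - tx) * (1 - ty)
            + k[i0, j0 + 1] * tx * (1 - ty)
            + k[i0 + 1, j0] * (1 - tx) * ty
            + k[i0 + 1, j0 + 1] * tx * ty
        )
        oob = (fx < 0) | (fx > n - 1) | (fy < 0) | (fy > n - 1)
        out[oob] = 0.0
        return out

    def counts(self, mosaic: ConeMosaic, centers: np.ndarray) -> np.ndarray:
        """Per-center class counts.  Returns an (m, 4) array in L, M, S, U order."""
        centers = np.atleast_2d(np.asarray(centers, dtype=float))
        tree = cKDTree(mosaic.positions)
        type_code = np.searchsorted(np.array(CONE_TYPES), mosaic.types)
        # CONE_TYPES sorted order is L, M, S, U already
        neigh = tree.query_ball_point(centers, r=self.radius)
        lens = np.fromiter((len(v) for v in neigh), dtype=int, count=len(neigh))
        flat = np.concatenate([np.asarray(v, dtype=int) for v in neigh]) \
            if lens.sum() else np.empty(0, dtype=int)
        cidx = np.repeat(np.arange(centers.shape[0]), lens)
        disp = mosaic.positions[flat] - centers[cidx]
        w = self._interp(disp[:, 0], disp[:, 1]) if flat.size else np.empty(0)
        out = np.zeros((centers.shape[0], 4))
        np.add.at(out, (cidx, type_code[flat]), w)
        return out

    def prop_L(self, mosaic: ConeMosaic, centers: np.ndarray) -> np.ndarray:
        """prop_L per center; NaN where no classified L/M mass is stimulated."""
        c = self.counts(mosaic, centers)
        lm = c[:, 0] + c[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(lm > 1e-12, c[:, 0] / np.where(lm > 0, lm, 1.0), np.nan)
        return p

    def summary(self, mosaic: ConeMosaic, center) -> StimulationSummary:
        c = self.counts(mosaic, np.asarray(center, dtype=float))[0]
        lm = c[0] + c[1]
        if lm <= 1e-12:
            raise PropLUndefinedError("no classified L or M cone under the stimulus")
        return StimulationSummary(
            n_L=c[0], n_M=c[1], n_S=c[2], n_U=c[3],
            prop_L=c[0] / lm,
            prop_L_range=(c[0] / (lm + c[3]), (c[0] + c[3]) / (lm + c[3])),
        )


def s_cone_distance(mosaic: ConeMosaic, center, spacing: float) -> float:
    """Distance from ``center`` to the nearest S cone, in units of cone spacing.

    Ties are broken by lowest cone index (deterministic).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    s_pos = mosaic.positions[mosaic.types == "S"]
    if s_pos.shape[0] == 0:
        raise ValueError("mosaic contains no S cones")
    d = np.hypot(s_pos[:, 0] - center[0], s_pos[:, 1] - center[1])
    return float(d.min() / spacing)


def cone_spacing(mosaic: ConeMosaic) -> float:
    """Mean edge length of the Delaunay triangulation of cone positions (arcmin)."""
    if mosaic.n_cones < 3:
        raise ValueError("need at least 3 cones for a triangulation")
    try:
        tri = Delaunay(mosaic.positions)
    except QhullError as exc:  # collinear or otherwise degenerate
        raise ValueError("degenerate (collinear) mosaic") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    e = np.array(sorted(edges))
    d = np.hypot(*(mosaic.positions[e[:, 0]] - mosaic.positions[e[:, 1]]).T)
    return float(d.mean())
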