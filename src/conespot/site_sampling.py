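"""Monte Carlo comparison of tested vs randomly selected stimulus sites.

Were the manually chosen test loci representative of the mosaic?  The
check: repeatedly drop the same number of stimulus footprints at uniform-
random locations, compute the local proportion L at each, histogram the
values into eight equal-width bins over [0, 1], and report the mean and
standard deviation of each bin count across iterations alongside the
observed histogram.  The same machinery yields tail probabilities for rare
site configurations (e.g. "three or more majority-M sites").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulation_optics import ConeMosaic, StimulationKernel, StimulusSpec

N_BINS = 8


@dataclass
class SamplingResult:
    bin_edges: np.ndarray
    mean_counts: np.ndarray
    sd_counts: np.ndarray
    n_sites: int
    n_iter: int
    seed: int
    observed_counts: np.ndarray | None = None


def _sampling_region(mosaic: ConeMosaic, stim: StimulusSpec,
                     psf_margin: float = 2.0) -> tuple:
    """Interior rectangle for random centers: mosaic bounds minus half the
    stimulus footprint plus a PSF-tail margin."""
    (x0, x1), (y0, y1) = mosaic.bounds()
    m = stim.side_length / 2.0 + psf_margin
    if x1 - x0 <= 2 * m or y1 - y0 <= 2 * m:
        raise ValueError("stimulus footprint does not fit inside the mosaic")
    return (x0 + m, x1 - m), (y0 + m, y1 - m)


def _prop_l_draws(
    mosaic: ConeMosaic,
    n_sites: int,
    n_iter: int,
    stim: StimulusSpec,
    seed: int,
    kernel: StimulationKernel | None = None,
    chunk: int = 200,
) -> np.ndarray:
    """(n_iter, n_sites) matrix of prop_L values at uniform-random centers.

    Centers that stimulate no classified L/M cone are redrawn (cannot occur
    at realistic densities, but the contract requires a defined value).
    """
    if kernel is None:
        kernel = StimulationKernel(stim)
    (xa, xb), (ya, yb) = _sampling_region(mosaic, stim)
    rng = np.random.default_rng(seed)
    out = np.empty((n_iter, n_sites))
    for start in range(0, n_iter, chunk):
        stop = min(start + chunk, n_iter)
        m = (stop - start) * n_sites
        centers = np.c_[rng.uniform(xa, xb, m), rng.uniform(ya, yb, m)]
        p = kernel.prop_L(mosaic, centers)
        bad = ~np.isfinite(p)
        while bad.any():
            redraw = np.c_[rng.uniform(xa, xb, bad.sum()),
                           rng.uniform(ya, yb, bad.sum())]
            p[bad] = kernel.prop_L(mosaic, redraw)
            bad = ~np.isfinite(p)
        out[start:stop] = p.reshape(stop - start, n_sites)
    return out


def random_site_simulation(
    mosaic: ConeMosaic,
    n_sites: int,
    n_iter: int = 10_000,
    stim: StimulusSpec | None = None,
    seed: int = 0,
    observed_prop_l=None,
    kernel: StimulationKernel | None = None,
) -> SamplingResult:
    """Null distribution of the tested-site prop_L histogram.

    Eight equal-width bins over [0, 1]; per-bin mean and SD of the count
    across ``n_iter`` random placements of ``n_sites`` stimuli.  Pass the
    observed per-site prop_L values to histogram them with the same rule.
    """
    stim = stim or StimulusSpec()
    draws = _prop_l_draws(mosaic, n_sites, n_iter, stim, seed, kernel)
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    idx = np.clip(np.digitize(draws, edges[1:-1]), 0, N_BINS - 1)
    counts = np.zeros((n_iter, N_BINS))
    rows = np.repeat(np.arange(n_iter), n_sites)
    np.add.at(counts, (rows, idx.ravel()), 1.0)
    observed = None
    if observed_prop_l is not None:
        o = np.asarray(observed_prop_l, dtype=float)
        observed = np.bincount(np.clip(np.digitize(o, edges[1:-1]), 0, N_BINS - 1),
                               minlength=N_BINS).astype(float)
    return SamplingResult(
        bin_edges=edges,
        mean_counts=counts.mean(axis=0),
        sd_counts=counts.std(axis=0),
        n_sites=n_sites, n_iter=n_iter, seed=seed,
        observed_counts=observed,
    )


def tail_probability(
    mosaic: ConeMosaic,
    n_sites: int,
    predicate,
    k: int,
    n_iter: int = 10_000,
    stim: StimulusSpec | None = None,
    seed: int = 0,
    kernel: StimulationKernel | None = None,
) -> float:
    """P(at least k of n random sites satisfy a per-site condition).

    ``predicate`` maps an array of prop_L values to booleans, e.g.
    ``lambda p: p < 0.5`` for majority-M sites.
    """
    if k > n_sites:
        raise ValueError("k cannot exceed n_sites")
    stim = stim or StimulusSpec()
    draws = _prop_l_draws(mosaic, n_sites, n_iter, stim, seed, kernel)
    hits = np.asarray(predicate(draws), dtype=bool).reshape(draws.shape)
    return float(np.mean(hits.sum(axis=1) >= k))
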