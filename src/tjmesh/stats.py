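"""Population-level statistics over per-mesh measurements.

Covers the aggregate results of the mesh analysis: normalized diameter
histograms, two-component Gaussian fits with FWHM and standard errors,
two-sample distribution comparison, the width-corrected strand/off-strand
density ratio, and the Feret/orientation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.stats import ks_2samp

#: FWHM of a Gaussian per unit standard deviation, 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class FitError(RuntimeError):
    """The two-Gaussian fit failed to converge."""


def diameter_histogram(
    diameters, bin_width: float = 50.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram normalized to the total number of analyzed meshes.

    Returns (bin_centers, heights, bin_edges); heights sum to exactly 1.
    Bins cover [0, max + bin_width).
    """
    d = np.asarray(diameters, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no diameters to histogram")
    nbins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(nbins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    heights = counts / d.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, heights, edges


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)


@dataclass
class GaussianComponent:
    amplitude: float
    mean: float
    sigma: float
    amplitude_se: float
    mean_se: float
    sigma_se: float

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    @property
    def fwhm_se(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_se


@dataclass
class TwoGaussianFit:
    """Sum-of-two-Gaussians fit to a normalized histogram.

    Components are ordered by mean.  Standard errors come from the
    Jacobian-based covariance of the unweighted least-squares fit.
    """

    components: tuple[GaussianComponent, GaussianComponent]
    residual_norm: float
    flags: tuple[str, ...] = field(default=())

    @property
    def small(self) -> GaussianComponent:
        return self.components[0]

    @property
    def large(self) -> GaussianComponent:
        return self.components[1]

    def __call__(self, x):
        a, b = self.components
        return _two_gauss(np.asarray(x, dtype=float), a.amplitude, a.mean, a.sigma,
                          b.amplitude, b.mean, b.sigma)


def _start_candidates(centers: np.ndarray, heights: np.ndarray) -> list[tuple]:
    """Initial parameter vectors: the two tallest well-separated smoothed
    peaks, plus two quantile-based seedings (robust when one component is
    only a shoulder of the other)."""
    ys = gaussian_filter1d(heights.astype(float), 1.0, mode="nearest")
    span = centers.max() - centers.min()
    top = heights.max()
    starts: list[tuple] = []
    idx = [i for i in range(len(ys))
           if ys[i] > 0 and (i == 0 or ys[i] >= ys[i - 1]) and (i == len(ys) - 1 or ys[i] >= ys[i + 1])]
    idx.sort(key=lambda i: -ys[i])
    if idx:
        first = idx[0]
        second = next((i for i in idx[1:] if abs(i - first) >= 3), None)
        if second is None:
            step = max(len(ys) // 4, 2)
            second = first + step if first + step < len(ys) else max(first - step, 0)
        starts.append((top, float(centers[first]), span / 8.0,
                       top / 2.0, float(centers[second]), span / 8.0))
    cum = np.cumsum(heights) / max(heights.sum(), 1e-300)
    q = lambda p: float(centers[min(np.searchsorted(cum, p), len(centers) - 1)])
    starts.append((top, q(0.15), span / 10.0, top / 2.0, q(0.65), span / 4.0))
    starts.append((top / 2.0, q(0.25), span / 6.0, top, q(0.75), span / 5.0))
    if not starts:
        raise FitError("histogram has no usable structure")
    return starts


def _hessian_se(nll, popt: np.ndarray) -> np.ndarray:
    """Standard errors from a central-difference Hessian of the likelihood."""
    n = len(popt)
    h = np.maximum(np.abs(popt) * 1e-4, 1e-8)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pi, pj = np.zeros(n), np.zeros(n)
            pi[i], pj[j] = h[i], h[j]
            H[i, j] = H[j, i] = (
                nll(popt + pi + pj) - nll(popt + pi - pj)
                - nll(popt - pi + pj) + nll(popt - pi - pj)
            ) / (4.0 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_two_gaussians(
    bin_centers,
    heights,
    p0: tuple | None = None,
    amp_ratio_floor: float = 0.05,
    n_total: int | None = None,
) -> TwoGaussianFit:
    """Fit A1·exp(...) + A2·exp(...) to a normalized histogram.

    Needs at least 6 nonzero bins.  Several initializations are tried (the
    two largest smoothed peaks, plus quantile seedings) and the best
    solution kept.  By default the fit is unweighted least squares on the
    heights; when ``n_total`` (the number of histogrammed values) is given,
    the fit instead maximizes the Poisson likelihood of the implied bin
    counts, which is markedly more stable when one component is sparse.

    Flags: ``mean_outside_range`` when a fitted mean falls outside the data
    support (a vague fit), ``minor_component`` when one amplitude drops
    below ``amp_ratio_floor`` of the other (the two-population reading is
    then doubtful).
    """
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(heights, dtype=float)
    if (y > 0).sum() < 6:
        raise FitError("need at least 6 nonzero histogram bins")
    span = x.max() - x.min()
    bw = np.median(np.diff(x)) if len(x) > 1 else 1.0
    starts = [p0] if p0 is not None else _start_candidates(x, y)
    lower = np.array([0.0, x.min() - span, bw / 4.0] * 2)
    upper = np.array([y.max() * 10 + 1e-12, x.max() + span, 2.0 * span + bw] * 2)

    popt = perr = None
    if n_total is None:
        best = np.inf
        for start in starts:
            try:
                p_, cov_ = curve_fit(
                    _two_gauss, x, y, p0=np.clip(start, lower, upper),
                    bounds=(lower, upper), maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = float(np.sum((_two_gauss(x, *p_) - y) ** 2))
            if resid < best:
                best, popt, pcov = resid, p_, cov_
        if popt is None:
            raise FitError("two-Gaussian fit did not converge from any start")
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    else:
        from scipy.optimize import minimize

        counts = y * n_total

        def nll(p):
            lam = np.maximum(_two_gauss(x, *p) * n_total, 1e-12)
            return float(np.sum(lam - counts * np.log(lam)))

        best = np.inf
        for start in starts:
            res = minimize(nll, np.clip(start, lower, upper), method="L-BFGS-B",
                           bounds=list(zip(lower, upper)))
            if res.fun < best:
                best, popt = res.fun, res.x
        if popt is None:
            raise FitError("two-Gaussian fit did not converge from any start")
        perr = _hessian_se(nll, popt)
    comps = [
        GaussianComponent(popt[k], popt[k + 1], abs(popt[k + 2]),
                          perr[k], perr[k + 1], perr[k + 2])
        for k in (0, 3)
    ]
    comps.sort(key=lambda c: c.mean)
    flags = []
    for c in comps:
        if not (x.min() - bw <= c.mean <= x.max() + bw):
            flags.append("mean_outside_range")
            break
    amps = sorted(c.amplitude for c in comps)
    if amps[1] > 0 and amps[0] < amp_ratio_floor * amps[1]:
        flags.append("minor_component")
    resid = float(np.linalg.norm(_two_gauss(x, *popt) - y))
    return TwoGaussianFit((comps[0], comps[1]), resid, tuple(flags))


def compare_distributions(sample_a, sample_b) -> dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test.

    The statistic is the exact supremum difference of the two empirical
    CDFs; the p-value uses the asymptotic distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("both samples need at least 5 values")
    res = ks_2samp(a, b, method="asymp")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


@dataclass
class DensityComparison:
    """Strand vs off-strand molecule density, with the strand-width correction.

    The apparent strand width in the reconstructed image (~50 nm, set by
    the localization accuracy) spreads the on-strand molecules over a band
    much wider than the ~10 nm physical strand; the corrected ratio rescales
    the raw band ratio by apparent/physical width.
    """

    on_strand_density: float
    interior_density: float
    apparent_width: float = 50.0
    physical_width: float = 10.0
    flags: tuple[str, ...] = field(default=())

    @property
    def raw_ratio(self) -> float:
        if self.interior_density == 0:
            return np.inf
        return self.on_strand_density / self.interior_density

    @property
    def corrected_ratio(self) -> float:
        return self.raw_ratio * (self.apparent_width / self.physical_width)


def density_ratio(
    on_strand_density: float,
    interior_density: float,
    apparent_width: float = 50.0,
    physical_width: float = 10.0,
) -> DensityComparison:
    """Raw and width-corrected on-strand/off-strand density ratio."""
    if apparent_width <= 0 or physical_width <= 0:
        raise ValueError("widths must be > 0")
    if on_strand_density < 0 or interior_density < 0:
        raise ValueError("densities must be >= 0")
    flags = ("infinite_ratio",) if interior_density == 0 else ()
    return DensityComparison(on_strand_density, interior_density,
                             apparent_width, physical_width, flags)


def feret_and_orientation_summary(
    measurements: pd.DataFrame,
    feret_bin: float = 0.05,
    orientation_min_diameter: float = 200.0,
) -> dict:
    """Normalized Feret histogram with its mode, and the orientation mean/STD.

    Feret bins are centred on multiples of ``feret_bin`` so the mode is
    directly readable.  Orientation statistics are restricted to meshes
    with diameter above ``orientation_min_diameter`` (their shape is
    measured precisely enough for the extent ratio to be meaningful).
    """
    fr = measurements["feret_ratio"].to_numpy(dtype=float)
    fr = fr[np.isfinite(fr)]
    if fr.size == 0:
        raise ValueError("no feret ratios to summarize")
    nbins = int(np.floor((fr.max() + feret_bin / 2) / feret_bin)) + 1
    edges = (np.arange(nbins + 1) - 0.5) * feret_bin
    counts, _ = np.histogram(fr, bins=edges)
    heights = counts / fr.size
    centers = np.arange(nbins) * feret_bin
    smoothed = gaussian_filter1d(heights.astype(float), 1.0, mode="nearest")
    mode = float(centers[int(np.argmax(smoothed))])

    d = measurements["diameter_nm"].to_numpy(dtype=float)
    orient = measurements["orientation_ratio"].to_numpy(dtype=float)
    sel = np.isfinite(orient) & np.isfinite(d) & (d > orientation_min_diameter)
    omean = float(orient[sel].mean()) if sel.any() else np.nan
    ostd = float(orient[sel].std(ddof=1)) if sel.sum() > 1 else np.nan

    return {
        "feret_bin_centers": centers,
        "feret_histogram": heights,
        "feret_mode": mode,
        "orientation_mean": omean,
        "orientation_std": ostd,
        "n_orientation": int(sel.sum()),
    }
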