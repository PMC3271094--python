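"""Per-mesh morphometry of tight-junction strand networks.

One mesh (a closed loop enclosed by strands) is measured from the rendered
super-resolution image, the underlying localization table and a seed point
near its centre:

1. the radial intensity profile around the seed gives a rough mean radius
   (position of the first profile maximum, located as the first +→− zero
   crossing of the smoothed derivative);
2. a Canny edge filter on the normalized region of interest yields a raw
   closed contour enclosing the seed;
3. the edge filter systematically underestimates the true loop: the mode of
   the distances between in-ROI molecule positions and the raw contour is
   the offset, and dilating the contour by it recovers the true shape;
4. circumference C, diameter d = C/π, mesh area, Feret ratio and the
   along-network/perpendicular extent ratio are read off the corrected
   contour; molecule densities are counted in a strand band (half-width
   set by the localization accuracy) and in the eroded interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Polygon
from skimage import feature, measure, morphology

from .io import MEASUREMENT_COLUMNS, LocalizationTable
from .render import RenderedImage, adaptive_blur_render


class MeshAnalysisError(RuntimeError):
    """A mesh could not be measured; ``reason`` is a short machine tag."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


class NoMeshError(MeshAnalysisError):
    def __init__(self, message: str):
        super().__init__("no_mesh", message)


class OpenMeshError(MeshAnalysisError):
    def __init__(self, message: str):
        super().__init__("open_mesh", message)


# ---------------------------------------------------------------------------
# radial profile


@dataclass
class RadialProfile:
    """Annulus-averaged intensity versus distance from a seed centre."""

    r: np.ndarray  # bin centres, nm
    intensity: np.ndarray  # mean intensity per annulus (NaN where empty)
    n_pixels: np.ndarray
    bin_width: float

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n_pixels == 0


def radial_profile(
    image: RenderedImage,
    center: tuple[float, float],
    bin_width: float = 4.0,
    r_max: float = 800.0,
) -> RadialProfile:
    """Mean intensity per radial annulus around ``center``.

    ``r_max`` is clamped to the distance from the centre to the nearest
    image border so annuli stay fully inside the raster.
    """
    cx, cy = center
    xmin, xmax, ymin, ymax = image.extent
    if not (xmin <= cx < xmax and ymin <= cy < ymax):
        raise MeshAnalysisError("seed_outside", f"centre ({cx:.0f}, {cy:.0f}) outside image")
    margin = min(cx - xmin, xmax - cx, cy - ymin, ymax - cy)
    r_max = min(r_max, margin)
    if r_max < bin_width:
        raise MeshAnalysisError("seed_outside", "centre too close to the image border")
    xs, ys = image.pixel_centers()
    rr = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    inside = rr <= r_max
    bins = (rr[inside] / bin_width).astype(int)
    nbins = int(np.ceil(r_max / bin_width))
    sums = np.bincount(bins, weights=image.data[inside], minlength=nbins)[:nbins]
    counts = np.bincount(bins, minlength=nbins)[:nbins]
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return RadialProfile(centers, mean, counts, bin_width)


def _first_peak(
    x: np.ndarray,
    y: np.ndarray,
    smoothing_sigma: float,
    min_rel_height: float,
) -> float | None:
    """First maximum of a sampled curve: first +→− zero crossing of the
    smoothed derivative, refined sub-sample by linear interpolation.

    Maxima below ``min_rel_height`` times the global maximum of the smoothed
    curve are skipped (guards against isolated low-intensity bumps).
    A curve whose global maximum sits at the first sample counts as a peak
    at that sample.
    """
    ys = gaussian_filter1d(y, smoothing_sigma, mode="nearest")
    top = ys.max()
    if top <= 0:
        return None
    dy = np.gradient(ys, x)
    for i in range(len(dy) - 1):
        if dy[i] > 0 and dy[i + 1] <= 0:
            frac = dy[i] / (dy[i] - dy[i + 1])
            xc = x[i] + frac * (x[i + 1] - x[i])
            height = ys[i] + frac * (ys[i + 1] - ys[i])
            if height >= min_rel_height * top:
                return float(xc)
    return None


def profile_peak_intensity(profile: RadialProfile, smoothing_sigma: float = 2.0) -> float:
    """Smoothed peak of the radial profile: the mean strand brightness.

    Used as the normalization scale for edge detection, so the Canny
    thresholds refer to fractions of the typical strand intensity.
    """
    y = profile.intensity.copy()
    bad = ~np.isfinite(y)
    if bad.all():
        return 0.0
    if bad.any():
        y[bad] = np.interp(profile.r[bad], profile.r[~bad], y[~bad])
    return float(gaussian_filter1d(y, smoothing_sigma, mode="nearest").max())


def estimate_mean_radius(
    profile: RadialProfile,
    smoothing_sigma: float = 2.0,
    min_rel_height: float = 0.6,
) -> float:
    """Mean mesh radius: position of the first radial-profile maximum."""
    if len(profile.r) < 3:
        raise NoMeshError("radial profile has fewer than 3 bins")
    y = profile.intensity.copy()
    bad = ~np.isfinite(y)
    if bad.all():
        raise NoMeshError("radial profile is empty")
    if bad.any():
        y[bad] = np.interp(profile.r[bad], profile.r[~bad], y[~bad])
    r = _first_peak(profile.r, y, smoothing_sigma, min_rel_height)
    if r is None or r <= 0:
        raise NoMeshError("no maximum in the radial intensity profile (monotone profile?)")
    return r


# ---------------------------------------------------------------------------
# contour extraction and correction


@dataclass
class MeshContour:
    """Ordered closed polygon (nm) describing one mesh boundary."""

    vertices: np.ndarray  # (N, 2), first != last (ring closes implicitly)
    corrected: bool = False
    offset_nm: float = 0.0
    flags: tuple[str, ...] = field(default=())

    @property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    @property
    def circumference(self) -> float:
        ring = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.hypot(*np.diff(ring, axis=0).T).sum())

    def contains(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self.polygon, x, y))


def _largest_polygon(geom) -> Polygon:
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        raise OpenMeshError("contour correction produced no polygon")
    return max(polys, key=lambda g: g.area)


def _flood_enclosed(
    edges: np.ndarray, ci: int, cj: int, r_mean: float, pixel_size: float
) -> np.ndarray | None:
    """Connected non-edge region around (ci, cj), if bounded by edges.

    Small closed loops around isolated interior clusters can trap the
    seed; such regions (effective radius below 0.4·r_mean) have their
    bounding edges erased and the flood retried.  Returns None when the
    region leaks to the ROI border.
    """
    edges = edges.copy()
    free = ~edges
    if not free[ci, cj]:
        fi, fj = np.nonzero(free)
        if fi.size == 0:
            return None
        k = np.argmin((fi - ci) ** 2 + (fj - cj) ** 2)
        ci, cj = int(fi[k]), int(fj[k])
    for _ in range(8):
        labels = measure.label(~edges, connectivity=1)
        mask = labels == labels[ci, cj]
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            return None
        r_eff = np.sqrt(mask.sum() / np.pi) * pixel_size
        if r_eff >= 0.4 * r_mean:
            return mask
        edges[morphology.dilation(mask, morphology.disk(2))] = False
    return None


def _polar_trace(
    edges: np.ndarray,
    roi: RenderedImage,
    center: tuple[float, float],
    r_mean: float,
    n_angles: int = 360,
    min_coverage: float = 0.5,
) -> np.ndarray | None:
    """Link edge pixels into a closed contour by polar tracing.

    For every bearing from the seed the edge pixel radially closest to the
    estimated mean radius is selected; outliers against a circular median
    filter are rejected and gaps interpolated periodically.  Robust to
    breaks in the edge chains, at the price of forcing a star-shaped
    contour.  Returns vertices in nm, or None when edge support covers
    less than ``min_coverage`` of the bearings.
    """
    cx, cy = center
    ii, jj = np.nonzero(edges)
    if ii.size == 0:
        return None
    rx0, ry0 = roi.origin
    p = roi.pixel_size
    ex = rx0 + (jj + 0.5) * p - cx
    ey = ry0 + (ii + 0.5) * p - cy
    rr = np.hypot(ex, ey)
    keep = (rr >= max(0.4 * r_mean, 10.0)) & (rr <= r_mean + max(0.9 * r_mean, 80.0))
    if keep.sum() < 10:
        return None
    rr = rr[keep]
    tt = np.arctan2(ey[keep], ex[keep])
    bins = ((tt + np.pi) / (2 * np.pi) * n_angles).astype(int) % n_angles
    r_ref = np.full(n_angles, float(r_mean))
    r_sel = np.full(n_angles, np.nan)
    for _pass in range(2):
        score = np.abs(rr - r_ref[bins])
        order = np.argsort(score)[::-1]  # the best candidate wins the slot
        r_sel = np.full(n_angles, np.nan)
        r_sel[bins[order]] = rr[order]
        if np.isfinite(r_sel).sum() < min_coverage * n_angles:
            return None
        good0 = np.isfinite(r_sel)
        ang0 = (np.arange(n_angles) + 0.5) / n_angles * 2 * np.pi - np.pi
        gx0 = np.concatenate([ang0[good0] - 2 * np.pi, ang0[good0], ang0[good0] + 2 * np.pi])
        gy0 = np.tile(r_sel[good0], 3)
        # heavily smoothed first-pass profile guides the second selection,
        # so an elongated mesh does not get snapped toward a circle
        r_ref = gaussian_filter1d(np.interp(ang0, gx0, gy0), 15.0, mode="wrap")

    # circular median filter + outlier rejection, then periodic fill
    half_w = 7
    med = np.full(n_angles, np.nan)
    for k in range(n_angles):
        idx = (np.arange(k - half_w, k + half_w + 1)) % n_angles
        vals = r_sel[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            med[k] = np.median(vals)
    resid = np.abs(r_sel - med)
    tol = max(3.0 * np.nanmedian(resid[np.isfinite(resid)]), 20.0)
    r_sel[resid > tol] = np.nan
    good = np.isfinite(r_sel)
    if good.sum() < min_coverage * n_angles:
        return None
    ang = (np.arange(n_angles) + 0.5) / n_angles * 2 * np.pi - np.pi
    # periodic interpolation over the gaps
    gx = np.concatenate([ang[good] - 2 * np.pi, ang[good], ang[good] + 2 * np.pi])
    gy = np.tile(r_sel[good], 3)
    r_fill = np.interp(ang, gx, gy)
    # periodic smoothing at the structural-resolution scale: radial wiggles
    # shorter than ~25 nm of arc are sampling artifacts that would inflate
    # the circumference (and hence d = C/π) without carrying shape
    sigma_samples = np.clip(
        np.degrees(25.0 / max(r_mean, 1.0)) / (360.0 / n_angles), 1.0, 12.0
    )
    r_smooth = gaussian_filter1d(r_fill, sigma_samples, mode="wrap")
    return np.column_stack([cx + r_smooth * np.cos(ang), cy + r_smooth * np.sin(ang)])


def extract_contour(
    image: RenderedImage,
    center: tuple[float, float],
    r_mean: float,
    canny_low: float = 0.04,
    canny_high: float = 0.1,
    canny_sigma_nm: float = 10.0,
    roi_factor: float = 2.0,
    norm_scale: float | None = None,
) -> MeshContour:
    """Raw mesh contour from a Canny edge filter around the seed.

    The ROI (square of side ``roi_factor * 2 * r_mean``) is normalized to
    [0, 1] before edge detection so the gradient thresholds are
    interpretable: by min-max scaling, or — when ``norm_scale`` is given —
    by clipping at that intensity (typically the radial-profile peak, i.e.
    the mean strand brightness, which keeps isolated hot pixels from
    compressing the scale).  The Gaussian pre-filter width is specified in
    nm and converted via the pixel size.

    Edge pixels partition the ROI; the connected non-edge region holding
    the seed, if bounded, is the mesh interior up to the inner flank of
    the strand and its outline is the raw contour.  When breaks in the
    edge chains let the region leak out (escalating morphological closings
    are tried first), the contour is recovered by polar tracing of the
    edge pixels around the seed and flagged ``polar_traced``.
    """
    cx, cy = center
    half = max(roi_factor * r_mean, r_mean + 100.0)
    roi = image.crop(cx - half, cx + half, cy - half, cy + half)
    if norm_scale is None:
        lo, hi = roi.data.min(), roi.data.max()
        if hi <= lo:
            raise OpenMeshError("blank ROI: no intensity variation around the seed")
        norm = (roi.data - lo) / (hi - lo)
    else:
        if norm_scale <= 0 or roi.data.max() <= 0:
            raise OpenMeshError("blank ROI: no intensity around the seed")
        # stretch between the local intensity floor and the strand
        # brightness: small meshes sit on a partially filled background, and
        # without the floor their shallow ring/centre contrast would fall
        # below the gradient thresholds
        lo = np.percentile(roi.data, 5.0)
        lo = min(lo, 0.8 * norm_scale)
        norm = np.clip((roi.data - lo) / max(norm_scale - lo, 1e-12), 0.0, 1.0)
    sigma_px = canny_sigma_nm / roi.pixel_size
    base = feature.canny(norm, sigma=sigma_px, low_threshold=canny_low, high_threshold=canny_high)
    if not base.any():
        raise OpenMeshError("Canny filter found no edges in the ROI")

    ci, cj = roi.nm_to_index(cx, cy)
    ci = int(np.clip(ci, 0, roi.shape[0] - 1))
    cj = int(np.clip(cj, 0, roi.shape[1] - 1))

    mask = None
    for disk in (0, 2, 4):
        edge_map = base if disk == 0 else morphology.closing(base, morphology.disk(disk))
        mask = _flood_enclosed(edge_map, ci, cj, r_mean, roi.pixel_size)
        if mask is not None:
            break

    flags: tuple[str, ...] = ()
    if mask is not None:
        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            raise OpenMeshError("enclosed region has no traceable outline")
        rx0, ry0 = roi.origin
        p = roi.pixel_size
        best = max(contours, key=len)
        verts = np.column_stack([rx0 + (best[:, 1] + 0.5) * p, ry0 + (best[:, 0] + 0.5) * p])
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) >= 3:
            # morphological closing+opening at half the structural
            # resolution: bead-scale bulges on the region outline would
            # otherwise inflate the circumference
            s = 12.0
            poly = Polygon(verts)
            if not poly.is_valid:
                poly = poly.buffer(0)
            smoothed = poly.buffer(s, quad_segs=16).buffer(-2 * s, quad_segs=16).buffer(
                s, quad_segs=16
            )
            try:
                verts = np.asarray(_largest_polygon(smoothed).exterior.coords)[:-1]
            except OpenMeshError:
                pass
    else:
        verts = _polar_trace(base, roi, center, r_mean)
        if verts is None:
            raise OpenMeshError(
                "no closed edge contour encloses the seed "
                f"(ROI side {2 * half:.0f} nm, r_mean {r_mean:.0f} nm)"
            )
        flags = ("polar_traced",)
    if len(verts) < 3:
        raise OpenMeshError("degenerate contour")
    return MeshContour(verts, corrected=False, flags=flags)


def signed_contour_distances(
    contour: MeshContour, table: LocalizationTable
) -> np.ndarray:
    """Signed distance of every record to the contour (positive outside)."""
    ring = np.vstack([contour.vertices, contour.vertices[:1]])
    line = LineString(ring)
    dists = shapely.distance(shapely.points(table.xy), line)
    inside = shapely.contains_xy(contour.polygon, table.x, table.y)
    return np.where(inside, -dists, dists)


def offset_histogram(
    contour: MeshContour,
    table: LocalizationTable,
    bin_width: float = 2.0,
    max_distance: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (centres, counts) of point-to-contour signed distances.

    The location of its dominant peak is the systematic offset between the
    edge-filter contour and the molecule positions that mark the true
    strand; :func:`correct_contour` resolves that offset per angular
    sector.
    """
    signed = signed_contour_distances(contour, table)
    signed = signed[np.abs(signed) <= max_distance]
    nbins = 2 * int(np.ceil(max_distance / bin_width))
    hist, edges_ = np.histogram(signed, bins=nbins, range=(-max_distance, max_distance))
    centers = 0.5 * (edges_[:-1] + edges_[1:])
    return centers, hist.astype(float)


def correct_contour(
    raw: MeshContour,
    table: LocalizationTable,
    center: tuple[float, float] | None = None,
    r_mean: float | None = None,
    max_distance: float | None = None,
    min_points: int = 20,
    n_sectors: int | None = None,
    n_iter: int = 3,
    scatter_sigma: float | None = None,
) -> MeshContour:
    """Correct the systematic offset between the edge filter and the strand.

    The edge filter lands on a flank of the strand intensity ridge, not on
    the strand centreline where the molecules sit.  The offset is read
    from the signed distances between the in-ROI molecule positions and
    the raw contour, evaluated per angular sector around the mesh centre
    (the classic single global offset is the one-sector limit; sectors
    accommodate a contour that sits on different flanks along its length).
    Each sector's median offset, smoothed periodically, moves the contour
    vertices radially onto the molecule ridge; two passes converge well
    below the localization accuracy.  ``offset_nm`` reports the mean
    applied offset.  Too few points within ``max_distance``: returned
    uncorrected and flagged.  A mean |offset| above half the mean radius
    is flagged suspect.
    """
    if len(table) < min_points:
        return replace(raw, flags=raw.flags + ("uncorrected",))
    verts = raw.vertices.copy()
    if center is None:
        c = Polygon(verts).centroid
        center = (c.x, c.y)
    cx, cy = center
    if max_distance is None:
        # on meshes not much larger than the scatter a wide window mixes in
        # points from the opposite strand; scale it with the mesh
        max_distance = 60.0 if r_mean is None else float(np.clip(0.6 * r_mean, 25.0, 60.0))
    if n_sectors is None:
        n_sectors = 36 if r_mean is None else int(np.clip(2 * np.pi * r_mean / 30.0, 12, 48))
    if scatter_sigma is None:
        sig = table.sigma_loc
        scatter_sigma = float(np.median(sig)) if len(sig) else 20.0
    xy = table.xy
    pang = np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
    sector = ((pang + np.pi) / (2 * np.pi) * n_sectors).astype(int) % n_sectors
    vrad_all = np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)

    total_offset = np.zeros(len(verts))
    vang = np.arctan2(verts[:, 1] - cy, verts[:, 0] - cx)
    applied_any = False
    for _ in range(n_iter):
        work = MeshContour(verts)
        signed = signed_contour_distances(work, table)
        near = np.abs(signed) <= max_distance
        if near.sum() < min_points:
            break
        med = np.full(n_sectors, np.nan)
        rr_v = np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)
        vsec = ((vang + np.pi) / (2 * np.pi) * n_sectors).astype(int) % n_sectors
        for k in range(n_sectors):
            vals = signed[near & (sector == k)]
            if vals.size >= 2:
                med[k] = np.median(vals)
                # Jacobian de-bias: detections scattered from a convex arc of
                # radius R have median radial excess sigma^2/(2R)
                sel = vsec == k
                if sel.any():
                    r_k = float(np.median(rr_v[sel]))
                    if r_k > scatter_sigma:
                        med[k] -= scatter_sigma**2 / (2.0 * r_k)
        good = np.isfinite(med)
        if good.sum() < max(3, n_sectors // 4):
            break
        ang_s = (np.arange(n_sectors) + 0.5) / n_sectors * 2 * np.pi - np.pi
        gx = np.concatenate([ang_s[good] - 2 * np.pi, ang_s[good], ang_s[good] + 2 * np.pi])
        gy = np.tile(med[good], 3)
        filled = np.interp(ang_s, gx, gy)
        smoothed = gaussian_filter1d(filled, 1.0, mode="wrap")
        dv = np.interp(vang, ang_s, smoothed, period=2 * np.pi)
        rr = np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)
        rr_new = np.maximum(rr + dv, 1.0)
        verts = np.column_stack([cx + rr_new * np.cos(vang), cy + rr_new * np.sin(vang)])
        total_offset += dv
        applied_any = True

    if not applied_any:
        return replace(raw, flags=raw.flags + ("uncorrected",))
    delta = float(total_offset.mean())
    flags = list(raw.flags)
    if r_mean is not None and abs(delta) > r_mean / 2:
        flags.append("suspect_offset")
    # residual sector-level wiggle inflates the circumference quadratically
    # in its amplitude without carrying shape; low-pass the radius profile,
    # keeping angular harmonics down to ~250 nm of arc (the ellipse-scale
    # harmonics pass untouched)
    verts = _lowpass_star_contour(verts, (cx, cy))
    return MeshContour(verts, corrected=True, offset_nm=delta, flags=tuple(flags))


def _lowpass_star_contour(
    verts: np.ndarray, center: tuple[float, float], min_arc: float = 250.0, n_out: int = 360
) -> np.ndarray:
    """Fourier low-pass of a star-shaped contour's radius-vs-angle profile."""
    cx, cy = center
    ang = np.arctan2(verts[:, 1] - cy, verts[:, 0] - cx)
    rad = np.hypot(verts[:, 0] - cx, verts[:, 1] - cy)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    ang_u, idx = np.unique(ang, return_index=True)
    rad = rad[idx]
    if len(ang_u) < 8:
        return verts
    grid = (np.arange(n_out) + 0.5) / n_out * 2 * np.pi - np.pi
    gx = np.concatenate([ang_u - 2 * np.pi, ang_u, ang_u + 2 * np.pi])
    gy = np.tile(rad, 3)
    r_grid = np.interp(grid, gx, gy)
    r_mean = r_grid.mean()
    kmax = max(3, int(2 * np.pi * r_mean / min_arc))
    spec = np.fft.rfft(r_grid)
    spec[kmax + 1 :] = 0.0
    r_smooth = np.fft.irfft(spec, n=n_out)
    return np.column_stack([cx + r_smooth * np.cos(grid), cy + r_smooth * np.sin(grid)])


def diameter_from_circumference(circumference: float) -> float:
    """Mesh diameter under the circular-shape approximation: d = C/π."""
    if circumference <= 0:
        raise ValueError("circumference must be > 0")
    return circumference / np.pi


# ---------------------------------------------------------------------------
# band / interior regions and densities


@dataclass
class BandRegions:
    """Strand band (annular region around the contour) and eroded interior."""

    band: shapely.Geometry
    interior: shapely.Geometry | None
    outer: shapely.Geometry
    band_half_width: float

    @property
    def band_area_um2(self) -> float:
        return self.band.area / 1e6

    @property
    def interior_area_um2(self) -> float | None:
        return None if self.interior is None else self.interior.area / 1e6


def strand_band_and_interior(contour: MeshContour, band_half_width: float) -> BandRegions:
    """Morphological band of half-width h around the contour, plus interior.

    band = dilation(h) − erosion(h); interior = erosion(h).  An erosion that
    empties the polygon (tiny mesh) leaves the interior absent.
    """
    if band_half_width <= 0:
        raise ValueError("band_half_width must be > 0")
    poly = contour.polygon
    outer = poly.buffer(band_half_width, quad_segs=32)
    inner = poly.buffer(-band_half_width, quad_segs=32)
    if inner.is_empty or inner.area <= 0:
        inner = None
        band = outer
    else:
        band = outer.difference(inner)
    return BandRegions(band, inner, outer, band_half_width)


def partition_counts(
    regions: BandRegions, table: LocalizationTable
) -> tuple[int, int, int]:
    """(band, interior, exterior) record counts — an exact partition.

    Membership is decided on the outer and inner polygons only, so the
    three counts always sum to the table size.
    """
    x, y = table.x, table.y
    in_outer = shapely.contains_xy(regions.outer, x, y)
    if regions.interior is not None:
        in_inner = shapely.contains_xy(regions.interior, x, y)
    else:
        in_inner = np.zeros(len(table), dtype=bool)
    n_interior = int(in_inner.sum())
    n_band = int((in_outer & ~in_inner).sum())
    return n_band, n_interior, len(table) - n_band - n_interior


def strand_density(table: LocalizationTable, regions: BandRegions) -> float:
    """Detections per µm² inside the strand band."""
    n_band, _, _ = partition_counts(regions, table)
    return n_band / regions.band_area_um2


def interior_density(table: LocalizationTable, regions: BandRegions) -> float | None:
    """Detections per µm² in the eroded interior; None when absent.

    Zero counts over a positive area are a valid density of 0.
    """
    if regions.interior is None:
        return None
    _, n_int, _ = partition_counts(regions, table)
    return n_int / regions.interior_area_um2


# ---------------------------------------------------------------------------
# shape descriptors


def _caliper_widths(vertices: np.ndarray, angle_step_deg: float = 1.0) -> np.ndarray:
    """Caliper extent of the convex hull for angles 0..180° (exclusive)."""
    if len(vertices) < 3:
        raise ValueError("need at least 3 vertices")
    try:
        hull = vertices[ConvexHull(vertices).vertices]
    except Exception as exc:  # collinear input
        raise ValueError(f"degenerate contour: {exc}") from exc
    theta = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = hull @ dirs.T
    return proj.max(axis=0) - proj.min(axis=0)


def feret_ratio(contour: MeshContour, angle_step_deg: float = 1.0) -> float:
    """Minimum diameter over the perpendicular diameter, in (0, 1].

    Caliper widths are scanned on a 1° grid; the reported ratio is the
    minimum over orientations of width(θ)/width(θ+90°), which for an
    ellipse is the minor/major axis ratio and 1 for a circle.
    """
    per_quarter = int(round(90.0 / angle_step_deg))
    w = _caliper_widths(contour.vertices, angle_step_deg)
    if w.min() <= 0:
        raise ValueError("degenerate (zero-width) contour")
    ratios = w / w[(np.arange(len(w)) + per_quarter) % len(w)]
    return float(ratios.min())


@dataclass
class NetworkAxis:
    """Principal direction of the whole strand network."""

    direction: np.ndarray  # unit vector
    eigenvalue_ratio: float
    reliable: bool


def network_axis(table: LocalizationTable, min_eig_ratio: float = 1.05) -> NetworkAxis:
    """First principal direction of the centred localization coordinates."""
    if len(table) < 10:
        raise ValueError("network axis needs at least 10 records")
    xy = table.xy - table.xy.mean(axis=0)
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    ratio = float(evals[-1] / max(evals[0], 1e-300))
    return NetworkAxis(v, ratio, ratio >= min_eig_ratio)


def orientation_ratio(contour: MeshContour, axis: NetworkAxis | np.ndarray) -> float:
    """Caliper extent along the network axis over the perpendicular extent."""
    v = axis.direction if isinstance(axis, NetworkAxis) else np.asarray(axis, dtype=float)
    v = v / np.hypot(*v)
    perp = np.array([-v[1], v[0]])
    verts = contour.vertices
    along = float(np.ptp(verts @ v))
    across = float(np.ptp(verts @ perp))
    if across <= 0:
        raise ValueError("degenerate contour")
    return along / across


# ---------------------------------------------------------------------------
# per-mesh orchestration


#: meshes at or below this diameter are too close to the structural
#: resolution for a reliable orientation measurement
ORIENTATION_MIN_DIAMETER = 200.0


@dataclass
class MeshMeasurement:
    """All morphometric quantities for one measured mesh."""

    label: str
    seed: tuple[float, float]
    mean_radius_nm: float
    contour: MeshContour
    circumference_nm: float
    diameter_nm: float
    area_um2: float
    feret_ratio: float
    orientation_ratio: float | None
    on_strand_density_um2: float
    interior_density_um2: float | None
    band_area_um2: float
    interior_area_um2: float | None
    counts: tuple[int, int, int]  # band, interior, exterior (in-ROI)
    n_localizations_roi: int
    flags: tuple[str, ...]

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "cx_nm": self.seed[0],
            "cy_nm": self.seed[1],
            "mean_radius_nm": self.mean_radius_nm,
            "circumference_nm": self.circumference_nm,
            "diameter_nm": self.diameter_nm,
            "area_um2": self.area_um2,
            "feret_ratio": self.feret_ratio,
            "orientation_ratio": np.nan if self.orientation_ratio is None else self.orientation_ratio,
            "on_strand_density_um2": self.on_strand_density_um2,
            "interior_density_um2": np.nan if self.interior_density_um2 is None else self.interior_density_um2,
            "band_area_um2": self.band_area_um2,
            "interior_area_um2": np.nan if self.interior_area_um2 is None else self.interior_area_um2,
            "correction_offset_nm": self.contour.offset_nm,
            "n_localizations_roi": self.n_localizations_roi,
            "flags": ";".join(self.flags) if self.flags else "ok",
        }


def measure_mesh(
    table: LocalizationTable,
    seed: tuple[float, float],
    label: str = "mesh",
    pixel_size: float = 2.0,
    axis: NetworkAxis | None = None,
    r_max: float = 800.0,
    band_half_width: float | None = None,
    profile_bin_width: float = 4.0,
    roi_factor: float = 2.0,
    k_neighbors: int = 4,
    canny_low: float = 0.04,
    canny_high: float = 0.1,
    canny_sigma_nm: float = 10.0,
) -> MeshMeasurement:
    """Measure one mesh around a seed centre.

    Renders a local window, estimates the mean radius from the radial
    profile, extracts and corrects the contour, and derives the scalar
    morphometrics.  Raises :class:`MeshAnalysisError` when the mesh cannot
    be measured (seed outside the data, open contour, no radial maximum).
    """
    cx, cy = seed
    xmin, xmax, ymin, ymax = table.extent
    if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
        raise MeshAnalysisError("seed_outside", f"seed ({cx:.0f}, {cy:.0f}) outside table extent")

    margin = 50.0
    win = r_max + margin
    sub = table.select_box(cx - win, cx + win, cy - win, cy + win)
    if len(sub) < k_neighbors + 1:
        raise MeshAnalysisError("too_few_points", f"only {len(sub)} localizations near the seed")
    # analysis raster: local point density as grey values — every record has
    # unit mass and the kernel width is floored at the localization
    # accuracy, so blinking hot spots do not dominate the intensity scale
    flat = LocalizationTable.from_arrays(sub.x, sub.y, sigma_loc=sub.sigma_loc)
    floor = max(0.5 * float(sub.sigma_loc.mean()), 1.0)
    image = adaptive_blur_render(
        flat,
        pixel_size=pixel_size,
        k_neighbors=k_neighbors,
        sigma_floor=floor,
        bounds=(cx - win, cx + win, cy - win, cy + win),
    )

    profile = radial_profile(image, seed, bin_width=profile_bin_width, r_max=r_max)
    r_mean = estimate_mean_radius(profile)

    raw = extract_contour(
        image,
        seed,
        r_mean,
        canny_low=canny_low,
        canny_high=canny_high,
        canny_sigma_nm=canny_sigma_nm,
        roi_factor=roi_factor,
        norm_scale=profile_peak_intensity(profile),
    )
    half = max(roi_factor * r_mean, r_mean + 100.0)
    roi_table = sub.select_box(cx - half, cx + half, cy - half, cy + half)
    contour = correct_contour(raw, roi_table, center=seed, r_mean=r_mean)
    flags = list(contour.flags)

    circumference = contour.circumference
    diameter = diameter_from_circumference(circumference)

    h = band_half_width
    if h is None:
        h = float(roi_table.sigma_loc.mean()) if len(roi_table) else 20.0
    regions = strand_band_and_interior(contour, h)
    n_band, n_int, n_ext = partition_counts(regions, roi_table)
    on_density = n_band / regions.band_area_um2
    if regions.interior is None:
        int_density = None
        int_area = None
        flags.append("interior_absent")
    else:
        int_density = n_int / regions.interior_area_um2
        int_area = regions.interior_area_um2

    fr = feret_ratio(contour)

    orient: float | None = None
    if diameter <= ORIENTATION_MIN_DIAMETER:
        flags.append("orientation_skipped_small")
    elif axis is None:
        flags.append("orientation_no_axis")
    elif not axis.reliable:
        flags.append("axis_unreliable")
    else:
        orient = orientation_ratio(contour, axis)

    return MeshMeasurement(
        label=label,
        seed=(cx, cy),
        mean_radius_nm=r_mean,
        contour=contour,
        circumference_nm=circumference,
        diameter_nm=diameter,
        area_um2=contour.polygon.area / 1e6,
        feret_ratio=fr,
        orientation_ratio=orient,
        on_strand_density_um2=on_density,
        interior_density_um2=int_density,
        band_area_um2=regions.band_area_um2,
        interior_area_um2=int_area,
        counts=(n_band, n_int, n_ext),
        n_localizations_roi=len(roi_table),
        flags=tuple(flags),
    )


def measure_all(
    table: LocalizationTable,
    seeds: pd.DataFrame,
    axis: NetworkAxis | str | None = "auto",
    log: list | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Measure every seeded mesh; failures become flagged NaN rows.

    ``axis='auto'`` estimates the network axis from all localizations.
    ``log`` (optional list) collects one ``(label, reason)`` tuple per
    failed mesh.
    """
    if axis == "auto":
        axis = network_axis(table) if len(table) >= 10 else None
    rows = []
    for _, s in seeds.iterrows():
        label = str(s["label"])
        try:
            m = measure_mesh(table, (float(s["cx_nm"]), float(s["cy_nm"])), label=label,
                             axis=axis, **kwargs)
            rows.append(m.to_row())
        except MeshAnalysisError as exc:
            if log is not None:
                log.append((label, f"{exc.reason}: {exc}"))
            rows.append(
                {
                    "label": label,
                    "cx_nm": float(s["cx_nm"]),
                    "cy_nm": float(s["cy_nm"]),
                    **{c: np.nan for c in MEASUREMENT_COLUMNS[3:-1]},
                    "flags": exc.reason,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
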