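"""Ground-truth simulator for tight-junction strand-network point clouds.

Synthetic networks emulate the statistical structure of reconstituted
claudin strand networks seen by localization microscopy: a quasi-linear
belt of elliptical meshes whose diameters follow a two-component Gaussian
mixture, slightly elongated (axis-ratio mode ~0.7) and preferentially
oriented along the network axis (mean along/perpendicular extent ratio
~1.21); strands are 10 nm wide; each detection scatters around its
molecule by an isotropic 20 nm Gaussian; ~88% of molecules are detected
once and the rest several times; a diffuse background of ~400 points/µm²
surrounds the network.

Density semantics: the on-strand, interior and background densities are
*expected detected densities in the regions the morphometry pipeline
measures* — the strand band of half-width equal to the localization
scatter, and the interior eroded by the same amount.  Placement
intensities are calibrated analytically for the scatter (capture fraction
of the strand cloud inside the band; spill of the interior/background
fields into the band; strand leakage into the interior), so the generator
parameters are directly recoverable by measurement.  Absolute molecule
counts are intentionally not modelled: the detection efficiency of the
fluorophores is unknowable, so all densities are detected-molecule
densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import norm
from shapely.geometry import Polygon

from .io import FRAME, PHOTONS, SIGMA, X, Y, LocalizationTable
from .localize import FrameStack
from .stats import FWHM_PER_SIGMA


@dataclass(frozen=True)
class GaussianMixture1D:
    """Two-component Gaussian mixture parameterized by means and FWHMs.

    When ``weights`` is None the component masses follow equal fitted peak
    amplitudes (histogram fits report amplitudes, not masses; equal peak
    heights mean mass proportional to sigma).
    """

    means: tuple[float, float]
    fwhms: tuple[float, float]
    weights: tuple[float, float] | None = None

    def __post_init__(self):
        if self.weights is None:
            s1, s2 = self.fwhms
            object.__setattr__(self, "weights", (s1 / (s1 + s2), s2 / (s1 + s2)))
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def sigmas(self) -> tuple[float, float]:
        return tuple(f / FWHM_PER_SIGMA for f in self.fwhms)

    def sample(self, n: int, rng: np.random.Generator, lower: float | None = None) -> np.ndarray:
        """Draw n values; with ``lower`` set, rejection-sample the truncation."""
        out = np.empty(0)
        sigmas = self.sigmas
        while out.size < n:
            comp = rng.random(n) < self.weights[1]
            draw = np.where(
                comp,
                rng.normal(self.means[1], sigmas[1], n),
                rng.normal(self.means[0], sigmas[0], n),
            )
            if lower is not None:
                draw = draw[draw >= lower]
            out = np.concatenate([out, draw])
        return out[:n]


#: mesh-diameter mixtures fitted to the two claudin subtypes (nm); both
#: populations are given equal mass — the published histograms resolve the
#: two components well enough to fit both, which a vanishing small
#: component would not allow
CLD3_DIAMETER_MIXTURE = GaussianMixture1D(
    means=(105.0, 364.0), fwhms=(132.0, 444.0), weights=(0.5, 0.5)
)
CLD5_DIAMETER_MIXTURE = GaussianMixture1D(
    means=(61.0, 482.0), fwhms=(174.0, 442.0), weights=(0.5, 0.5)
)


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters for one synthetic network scene.

    Defaults reproduce the measured conditions of claudin-3 networks:
    diameter mixture 105/364 nm (FWHM 132/444 nm), axis-ratio mode 0.7,
    along-axis elongation 1.21 ± 0.38, 10 nm strands, 20 nm localization
    scatter, detected densities 3700 (strand band) / 780 (interior) /
    400 (far field) µm⁻², and 88% of molecules detected exactly once.
    """

    n_meshes: int = 100
    diameter_mixture: GaussianMixture1D = field(default_factory=lambda: CLD3_DIAMETER_MIXTURE)
    min_diameter: float = 50.0  # below the structural resolution no mesh exists
    axis_ratio_mode: float = 0.7
    axis_ratio_sd: float = 0.08
    axis_ratio_range: tuple[float, float] = (0.45, 0.95)
    orientation_mode: str = "aligned"  # "aligned" (elongation model) or "random"
    elongation_mean: float = 1.21
    elongation_sd: float = 0.38
    network_axis_deg: float = 0.0
    strand_width: float = 10.0
    mesh_spacing: float = 100.0  # nm between neighbouring mesh boundaries
    gaps_per_um: float = 0.0  # strand interruptions (resolution studies)
    gap_range: tuple[float, float] = (10.0, 100.0)
    on_strand_density: float = 3700.0  # detections/µm² in the strand band
    interior_density: float = 780.0  # detections/µm² in the eroded interior
    background_density: float = 400.0  # detections/µm² far from the network
    background_margin: float = 400.0  # nm of background around the belt
    scatter_sigma: float = 20.0  # nm localization scatter (= recorded accuracy)
    frac_single: float = 0.88  # molecules detected exactly once
    multi_mean: float = 2.5  # mean detections among re-detected molecules
    photon_mean: float = 800.0
    photon_sigma_log: float = 0.5
    n_frames: int = 8000
    seed: int = 0

    @property
    def mean_detections(self) -> float:
        return self.frac_single + (1.0 - self.frac_single) * self.multi_mean


@dataclass
class MeshTruth:
    """Ground truth for one synthetic elliptical mesh."""

    center: tuple[float, float]
    a: float  # semi-major, nm
    b: float  # semi-minor, nm
    theta: float  # major-axis angle to the x axis, rad
    diameter: float  # perimeter/π, the pipeline's reporting convention
    axis_ratio: float  # b/a
    orientation_ratio: float  # extent along network axis / perpendicular

    def boundary(self, n: int = 720) -> np.ndarray:
        """Closed boundary polyline, (n+1, 2) nm."""
        t = np.linspace(0.0, 2.0 * np.pi, n + 1)
        ex = self.a * np.cos(t)
        ey = self.b * np.sin(t)
        c, s = math.cos(self.theta), math.sin(self.theta)
        x = self.center[0] + c * ex - s * ey
        y = self.center[1] + s * ex + c * ey
        return np.column_stack([x, y])

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.boundary(360)[:-1])


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (relative error < 1e-9 for b/a > 0.4)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def _extent_ratio(a: float, b: float, theta: float) -> float:
    ex = 2.0 * math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
    ey = 2.0 * math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
    return ex / ey


def _theta_for_extent_ratio(a: float, b: float, rho: float) -> float:
    """Major-axis angle at which the along/perp caliper-extent ratio is rho.

    rho is attainable in [b/a, a/b]; values outside are clamped.
    """
    lo, hi = b / a, a / b
    rho = min(max(rho, lo), hi)
    if abs(a - b) < 1e-12:
        return 0.0
    r2 = rho * rho
    t = (r2 * a * a - b * b) / ((a * a - b * b) * (1.0 + r2))
    t = min(max(t, 0.0), 1.0)
    return math.acos(math.sqrt(t))


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """E[clip(N(mu, sd), lo, hi)] in closed form."""
    zl, zh = (lo - mu) / sd, (hi - mu) / sd
    Fl, Fh = norm.cdf(zl), norm.cdf(zh)
    fl, fh = norm.pdf(zl), norm.pdf(zh)
    return lo * Fl + hi * (1.0 - Fh) + mu * (Fh - Fl) - sd * (fh - fl)


def _elongation_draw_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Raw-draw mean whose clipped expectation equals the target.

    A mesh's along/perpendicular extent ratio is bounded by its axis ratio
    (rho in [q, 1/q]); clipping into that range drags the realized mean
    below the configured value, so the draw mean is shifted to compensate.
    Unattainable targets saturate at the bound.
    """
    if target >= hi:
        return hi + 3.0 * sd
    if target <= lo:
        return lo - 3.0 * sd
    a, b = lo - 4.0 * sd, hi + 4.0 * sd
    for _ in range(60):
        m = 0.5 * (a + b)
        if _clipped_normal_mean(m, sd, lo, hi) < target:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _sample_axis_ratio(params: SceneParams, rng: np.random.Generator) -> float:
    lo, hi = params.axis_ratio_range
    while True:
        q = rng.normal(params.axis_ratio_mode, params.axis_ratio_sd)
        if lo <= q <= hi:
            return q


def generate_network_geometry(
    params: SceneParams, rng: np.random.Generator
) -> tuple[list[MeshTruth], tuple[float, float, float, float]]:
    """Lay out the mesh ellipses along a belt; return meshes and region bounds.

    Diameters (perimeter/π) come from the two-Gaussian mixture truncated at
    ``min_diameter``; axis ratios peak at the configured mode; major axes
    are oriented so each mesh realizes an along/perpendicular extent ratio
    drawn from the elongation distribution ("aligned" mode) or uniformly at
    random ("random" mode).  Meshes are packed without overlap along the
    axis, separated by ``mesh_spacing``, then the belt is rotated to the
    requested network direction and shifted so all coordinates are >= 0.
    """
    diams = params.diameter_mixture.sample(params.n_meshes, rng, lower=params.min_diameter)
    meshes: list[MeshTruth] = []
    cursor = 0.0
    for d in diams:
        q = _sample_axis_ratio(params, rng)
        a = math.pi * d / ellipse_perimeter(1.0, q)
        b = q * a
        if params.orientation_mode == "random":
            theta = rng.uniform(0.0, math.pi)
        elif params.orientation_mode == "aligned":
            mu = _elongation_draw_mean(
                params.elongation_mean, params.elongation_sd, b / a, a / b
            )
            rho = rng.normal(mu, params.elongation_sd)
            theta = _theta_for_extent_ratio(a, b, rho)
            if rng.random() < 0.5:
                theta = -theta
        else:
            raise ValueError(f"unknown orientation_mode {params.orientation_mode!r}")
        ext_x = 2.0 * math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        cx = cursor + ext_x / 2.0
        cursor += ext_x + params.mesh_spacing
        meshes.append(
            MeshTruth(
                center=(cx, 0.0),
                a=a,
                b=b,
                theta=theta,
                diameter=ellipse_perimeter(a, b) / math.pi,
                axis_ratio=q,
                orientation_ratio=_extent_ratio(a, b, theta),
            )
        )

    margin = params.background_margin
    max_half = max(max(m.a for m in meshes), 1.0)
    x0, x1 = -margin, cursor - params.mesh_spacing + margin
    y0, y1 = -max_half - margin, max_half + margin

    phi = math.radians(params.network_axis_deg)
    if phi:
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        corners = np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]) @ rot.T
        for m in meshes:
            m.center = tuple(rot @ np.asarray(m.center))
            m.theta += phi
        x0, y0 = corners.min(axis=0)
        x1, y1 = corners.max(axis=0)
    for m in meshes:
        m.center = (m.center[0] - x0, m.center[1] - y0)
    return meshes, (0.0, x1 - x0, 0.0, y1 - y0)


def strand_polylines_for_mesh(
    mesh: MeshTruth, params: SceneParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Strand centreline segments for one mesh boundary, with optional gaps
    of 10–100 nm (strand-continuity / resolution studies)."""
    ring = mesh.boundary(720)
    if params.gaps_per_um <= 0:
        return [ring]
    seg = np.hypot(*np.diff(ring, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n_gaps = rng.poisson(params.gaps_per_um * total / 1000.0)
    if n_gaps == 0:
        return [ring]
    gap_starts = np.sort(rng.uniform(0.0, total, n_gaps))
    gap_lens = rng.uniform(*params.gap_range, n_gaps)
    keep_from = 0.0
    pieces: list[tuple[float, float]] = []
    for g0, gl in zip(gap_starts, gap_lens):
        if g0 > keep_from:
            pieces.append((keep_from, g0))
        keep_from = max(keep_from, g0 + gl)
    if keep_from < total:
        pieces.append((keep_from, total))
    out = []
    for s0, s1 in pieces:
        ss = np.linspace(s0, s1, max(int((s1 - s0) / 5.0), 2))
        xs = np.interp(ss, arclen, ring[:, 0])
        ys = np.interp(ss, arclen, ring[:, 1])
        out.append(np.column_stack([xs, ys]))
    return out


# -- scatter-calibration helpers -------------------------------------------


def _capture_fraction(sigma: float, width: float, half: float, n: int = 201) -> float:
    """P(|U + ε| <= half) for U ~ Uniform(−width/2, width/2), ε ~ N(0, σ)."""
    u = np.linspace(-width / 2.0, width / 2.0, n)
    return float(np.mean(norm.cdf((half - u) / sigma) - norm.cdf((-half - u) / sigma)))


def _leak_fraction(sigma: float, width: float, half: float, n: int = 201) -> float:
    """P(U + ε < −half): strand detections landing beyond the interior margin."""
    u = np.linspace(-width / 2.0, width / 2.0, n)
    return float(np.mean(norm.cdf((-half - u) / sigma)))


def _side_spill(sigma: float, width: float, half: float, n: int = 401) -> float:
    """Band intake per unit strand length from a unit-density half-plane
    field starting width/2 beyond the centreline:
    ∫_{−h}^{h} Φ((−w/2 − t)/σ) dt."""
    t = np.linspace(-half, half, n)
    return float(np.trapezoid(norm.cdf((-width / 2.0 - t) / sigma), t))


def _sample_on_polyline(
    polyline: np.ndarray, n: int, width: float, rng: np.random.Generator
) -> np.ndarray:
    """n positions uniform along the polyline, offset uniformly across the
    strand width."""
    seg = np.diff(polyline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    s = rng.uniform(0.0, arclen[-1], n)
    idx = np.clip(np.searchsorted(arclen, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - arclen[idx]) / np.maximum(seglen[idx], 1e-12)
    base = polyline[idx] + frac[:, None] * seg[idx]
    tangent = seg[idx] / np.maximum(seglen[idx], 1e-12)[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    return base + rng.uniform(-width / 2.0, width / 2.0, n)[:, None] * normal


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a shapely polygon (rejection from the bbox)."""
    if n == 0 or poly.is_empty:
        return np.empty((0, 2))
    x0, y0, x1, y1 = poly.bounds
    bbox_area = (x1 - x0) * (y1 - y0)
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(int((n - got) * max(1.5, bbox_area / max(poly.area, 1e-12))), 32)
        m = min(m, 200000)
        pts = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        pts = pts[shapely.contains_xy(poly, pts[:, 0], pts[:, 1])]
        take = pts[: n - got]
        out.append(take)
        got += len(take)
    return np.vstack(out)


@dataclass
class NetworkScene:
    """A generated network: geometry, ground truth and the sampled table."""

    params: SceneParams
    meshes: list[MeshTruth]
    strands: list[list[np.ndarray]]  # per mesh, one or more centreline segments
    bounds: tuple[float, float, float, float]
    table: LocalizationTable
    molecules: np.ndarray  # ground-truth molecule positions, (M, 2)

    def seeds(self) -> pd.DataFrame:
        """Mesh centres in the seed-table layout expected by the pipeline."""
        return pd.DataFrame(
            {
                "label": [f"mesh-{i:04d}" for i in range(len(self.meshes))],
                "cx_nm": [m.center[0] for m in self.meshes],
                "cy_nm": [m.center[1] for m in self.meshes],
            }
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [f"mesh-{i:04d}" for i in range(len(self.meshes))],
                "diameter_nm": [m.diameter for m in self.meshes],
                "axis_ratio": [m.axis_ratio for m in self.meshes],
                "orientation_ratio": [m.orientation_ratio for m in self.meshes],
                "cx_nm": [m.center[0] for m in self.meshes],
                "cy_nm": [m.center[1] for m in self.meshes],
                "semi_major_nm": [m.a for m in self.meshes],
                "semi_minor_nm": [m.b for m in self.meshes],
                "theta_rad": [m.theta for m in self.meshes],
            }
        )

    def truth_dict(self) -> dict:
        return {
            "bounds_nm": list(self.bounds),
            "meshes": self.truth_table().to_dict(orient="records"),
            "n_molecules": int(len(self.molecules)),
            "n_detections": len(self.table),
        }


def sample_localizations(
    meshes: list[MeshTruth],
    strands: list[list[np.ndarray]],
    bounds: tuple[float, float, float, float],
    params: SceneParams,
    rng: np.random.Generator,
) -> tuple[LocalizationTable, np.ndarray]:
    """Sample the detected-molecule table for a generated geometry.

    Molecule ground-truth positions are homogeneous Poisson processes on
    the strands, in the mesh interiors and in the far field; each molecule
    emits one detection with probability ``frac_single`` and otherwise
    2 + geometric extra events (mean ``multi_mean``); every detection is
    displaced by the isotropic localization scatter; photons are
    log-normal; the recorded accuracy equals the scatter width.
    """
    sig = params.scatter_sigma
    w = params.strand_width
    mean_det = params.mean_detections
    molecules: list[np.ndarray] = []

    if sig > 0:
        h = sig  # measurement band half-width equals the recorded accuracy
        f_cap = _capture_fraction(sig, w, h)
        g_leak = _leak_fraction(sig, w, h)
        c_spill = _side_spill(sig, w, h)
        band_width = 2.0 * h
    else:  # no scatter: densities are literal areal densities
        f_cap, g_leak, c_spill, band_width = 1.0, 0.0, 0.0, w
        h = w / 2.0

    for mesh, segs in zip(meshes, strands):
        total_len = sum(float(np.hypot(*np.diff(s, axis=0).T).sum()) for s in segs)
        poly = mesh.polygon
        a_int = poly.buffer(-h).area  # nm², the measured interior region
        # joint calibration: the strand cloud leaks inward, the interior and
        # outside fields spill into the band; two fixed-point sweeps settle
        # far below the Monte-Carlo noise
        d_int_place = params.interior_density * 1e-6  # nm⁻²
        lam = params.on_strand_density * 1e-6 * band_width / max(f_cap, 1e-9)
        for _ in range(3):
            spill = c_spill * (d_int_place + params.background_density * 1e-6)
            lam = max((params.on_strand_density * 1e-6 * band_width - spill) / max(f_cap, 1e-9), 0.0)
            if a_int > 0 and total_len > 0:
                leak = lam * g_leak * total_len / a_int
                d_int_place = max(params.interior_density * 1e-6 - leak, 0.0)
        for s in segs:
            seg_len = float(np.hypot(*np.diff(s, axis=0).T).sum())
            n_mol = rng.poisson(lam * seg_len / mean_det)
            if n_mol:
                molecules.append(_sample_on_polyline(s, n_mol, w, rng))
        inner_region = poly.buffer(-w / 2.0)
        if not inner_region.is_empty and d_int_place > 0:
            n_mol = rng.poisson(d_int_place * inner_region.area / mean_det)
            if n_mol:
                molecules.append(_sample_in_polygon(inner_region, n_mol, rng))

    # far-field background outside the (strand-width dilated) meshes
    x0, x1, y0, y1 = bounds
    area = (x1 - x0) * (y1 - y0)
    n_bg = rng.poisson(params.background_density * 1e-6 * area / mean_det)
    if n_bg:
        pts = np.column_stack([rng.uniform(x0, x1, n_bg), rng.uniform(y0, y1, n_bg)])
        if meshes:
            union = shapely.unary_union(
                [m.polygon.buffer(params.strand_width / 2.0) for m in meshes]
            )
            pts = pts[~shapely.contains_xy(union, pts[:, 0], pts[:, 1])]
        molecules.append(pts)

    mols = np.vstack(molecules) if molecules else np.empty((0, 2))

    # blinking: 1 detection with probability frac_single, else 2 + geometric
    n_mol = len(mols)
    k = np.ones(n_mol, dtype=int)
    multi = rng.random(n_mol) >= params.frac_single
    if multi.any():
        extra_mean = max(params.multi_mean - 2.0, 0.0)
        p = 1.0 / (1.0 + extra_mean)
        k[multi] = 2 + rng.geometric(p, multi.sum()) - 1
    idx = np.repeat(np.arange(n_mol), k)
    truth = mols[idx]
    n_det = len(truth)
    scatter = rng.normal(0.0, sig, (n_det, 2)) if sig > 0 else 0.0
    pos = truth + scatter
    photons = rng.lognormal(math.log(params.photon_mean), params.photon_sigma_log, n_det)
    frames = rng.integers(0, params.n_frames, n_det)
    df = pd.DataFrame(
        {
            X: pos[:, 0],
            Y: pos[:, 1],
            FRAME: frames,
            PHOTONS: photons,
            SIGMA: np.full(n_det, sig if sig > 0 else 1e-3),
        }
    )
    return LocalizationTable(df), mols


def make_scene(params: SceneParams) -> NetworkScene:
    """Generate a full scene (geometry + localization table) from parameters.

    All randomness flows from ``params.seed``; identical parameters give
    byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    meshes, bounds = generate_network_geometry(params, rng)
    strands = [strand_polylines_for_mesh(m, params, rng) for m in meshes]
    table, mols = sample_localizations(meshes, strands, bounds, params, rng)
    # detections near the region edge can scatter to negative coordinates;
    # shift the whole scene so every coordinate is >= 0
    if len(table):
        dx = max(0.0, -float(table.x.min()))
        dy = max(0.0, -float(table.y.min()))
        if dx or dy:
            shift = np.array([dx, dy])
            table = LocalizationTable.from_arrays(
                table.x + dx, table.y + dy, frame=table.frame,
                photons=table.photons, sigma_loc=table.sigma_loc,
            )
            mols = mols + shift if len(mols) else mols
            strands = [[seg + shift for seg in segs] for segs in strands]
            for m in meshes:
                m.center = (m.center[0] + dx, m.center[1] + dy)
            bounds = (0.0, bounds[1] + dx, 0.0, bounds[3] + dy)
    return NetworkScene(params, meshes, strands, bounds, table, mols)


# ---------------------------------------------------------------------------
# camera-frame simulation


def simulate_frames(
    table: LocalizationTable,
    pixel_size: float = 100.0,
    psf_sigma: float = 130.0,
    background: float = 50.0,
    n_frames: int | None = None,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
) -> tuple[FrameStack, LocalizationTable]:
    """Render detections into noisy camera frames.

    Each detection becomes a Gaussian point-spread blob (σ ``psf_sigma``
    nm) carrying its photon count on top of a constant background, with
    Poisson shot noise.  Detections keep their frame assignment unless
    ``n_frames`` is given, in which case frames are re-drawn uniformly.
    Returns the stack and the (possibly re-framed) ground-truth table.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    df = table.df.copy()
    if n_frames is not None:
        df[FRAME] = rng.integers(0, n_frames, len(df))
    t_max = int(df[FRAME].max()) + 1 if len(df) else (n_frames or 1)
    if shape is None:
        if len(df) == 0:
            raise ValueError("cannot infer frame shape from an empty table")
        nx = int(np.ceil(df[X].max() / pixel_size)) + 4
        ny = int(np.ceil(df[Y].max() / pixel_size)) + 4
        shape = (ny, nx)
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    clean = np.full((t_max, ny, nx), float(background))
    for x, y, fr, q in zip(df[X], df[Y], df[FRAME], df[PHOTONS]):
        gx = np.exp(-0.5 * ((xs - x) / psf_sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / psf_sigma) ** 2)
        patch = np.outer(gy, gx)
        s = patch.sum()
        if s > 0:
            clean[int(fr)] += q * patch / s
    noisy = rng.poisson(clean).astype(float)
    return FrameStack(noisy, pixel_size), LocalizationTable(df)


# ---------------------------------------------------------------------------
# configuration plumbing


def params_from_config(cfg: dict) -> SceneParams:
    """Build SceneParams from a (YAML) mapping; mixture given as means/fwhms/weights."""
    cfg = dict(cfg)
    mix = cfg.pop("diameter_mixture", None)
    if isinstance(mix, dict):
        cfg["diameter_mixture"] = GaussianMixture1D(
            means=tuple(mix["means"]),
            fwhms=tuple(mix["fwhms"]),
            weights=tuple(mix.get("weights", (0.5, 0.5))),
        )
    elif isinstance(mix, str):
        cfg["diameter_mixture"] = {
            "cld3": CLD3_DIAMETER_MIXTURE,
            "cld5": CLD5_DIAMETER_MIXTURE,
        }[mix.lower()]
    for key in ("axis_ratio_range", "gap_range"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return SceneParams(**cfg)
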