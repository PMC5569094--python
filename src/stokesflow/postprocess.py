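"""Derived analytics on assimilated flow fields and their time series.

Field-level operations (statistics, streamlines, vorticity, profiles and the
Poiseuille/sigmoid fits used to characterise bleb protrusions), time-series
operations (zero-phase Butterworth smoothing, cross-correlation lags, Fourier
periodicity and the sum-of-Gaussians period histogram fit), and the 2D
out-of-plane volume bookkeeping, plus the Darcy-law pressure estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .errors import (
    DegenerateTransform,
    DomainError,
    FitError,
    UndefinedCorrelation,
)
from .fem import DivergenceSource, VelocityField
from .geometry import CellMask

__all__ = [
    "FrameSummary",
    "SigmoidParams",
    "PeriodEstimate",
    "frame_stats",
    "streamlines",
    "vorticity",
    "line_profile",
    "fit_poiseuille",
    "fit_sigmoid",
    "collapse_sigmoid",
    "cluster_sigmoid_params",
    "butterworth_lowpass",
    "ccf_lag",
    "dominant_periods",
    "fit_period_mixture",
    "out_of_plane_volumes",
    "bleb_acceleration",
    "darcy_pressure",
]


# ---------------------------------------------------------------------------
# Per-frame field statistics
# ---------------------------------------------------------------------------

@dataclass
class FrameSummary:
    """Min/max/mean field magnitudes for one frame pair.

    Units: velocity μm/s, pressure Pa, force Pa/μm; ``range_*`` is max−min.
    """

    t: float
    u_min: float
    u_max: float
    u_mean: float
    p_min: float
    p_max: float
    p_mean: float
    f_min: float
    f_max: float
    f_mean: float
    centroid_speed: float | None = None

    def range(self, fieldname: str) -> float:
        return getattr(self, f"{fieldname}_max") - getattr(self, f"{fieldname}_min")


def frame_stats(solutions, masks=None, dt: float | None = None,
                pixel_size: float | None = None) -> list[FrameSummary]:
    """Per-pair summaries of |u|, p and |f| plus the centroid speed.

    Magnitudes are evaluated at the mesh nodes of each solution; the centroid
    speed is the displacement of consecutive mask centroids over dt.
    """
    out: list[FrameSummary] = []
    for i, sol in enumerate(solutions):
        dt_i = dt if dt is not None else sol.dt
        px = pixel_size if pixel_size is not None else sol.pixel_size
        um = sol.u.magnitude()
        fm = sol.f.magnitude()
        p = sol.p.dofs
        cs = None
        if masks is not None and i + 1 < len(masks):
            c0 = masks[i].centroid(px)
            c1 = masks[i + 1].centroid(px)
            cs = float(np.linalg.norm(c1 - c0) / dt_i)
        out.append(FrameSummary(
            t=i * dt_i,
            u_min=float(um.min()), u_max=float(um.max()), u_mean=float(um.mean()),
            p_min=float(p.min()), p_max=float(p.max()), p_mean=float(p.mean()),
            f_min=float(fm.min()), f_max=float(fm.max()), f_mean=float(fm.mean()),
            centroid_speed=cs,
        ))
    return out


# ---------------------------------------------------------------------------
# Streamlines & vorticity
# ---------------------------------------------------------------------------

def streamlines(u: VelocityField, seeds, t_max: float | None = None,
                max_arc_length: float | None = None, tol: float = 1e-8,
                max_step: float | None = None) -> list[np.ndarray]:
    """Integrate dx/dt = u(x) from each seed with adaptive RK45.

    Integration stops at the domain boundary (where the interpolated field is
    extended by nearest-neighbour, velocities are frozen so lines stall) or
    after ``max_arc_length``. Seeds outside the domain are skipped with a
    warning entry (empty polyline).
    """
    import logging

    log = logging.getLogger(__name__)
    interp = u.space.interpolator(u.dofs)
    mesh = u.space.mesh
    hull_pts = mesh.nodes[np.unique(mesh.boundary_facets)]
    from shapely.geometry import Point, Polygon
    from shapely.prepared import prep

    speed_scale = max(np.linalg.norm(u.dofs, axis=0).max(), 1e-300)
    diam = np.linalg.norm(mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0))
    if max_arc_length is None:
        max_arc_length = 4 * diam
    if t_max is None:
        t_max = max_arc_length / speed_scale

    # ordered boundary polygon for inside tests (2D)
    inside = None
    if mesh.dim == 2:
        from scipy.spatial import ConvexHull

        try:
            poly = _ordered_boundary_polygon(mesh)
            inside = prep(Polygon(poly).buffer(1e-9 * diam))
        except Exception:  # fall back to convex hull
            hull = ConvexHull(hull_pts)
            inside = prep(Polygon(hull_pts[hull.vertices]))

    lines: list[np.ndarray] = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if inside is not None and not inside.contains(Point(*seed)):
            log.warning("streamline seed %s outside the domain; skipped", seed)
            lines.append(np.empty((0, mesh.dim)))
            continue

        def rhs(_t, x):
            return np.asarray(interp(x)).ravel()

        sol = solve_ivp(rhs, (0.0, t_max), seed, method="RK45",
                        rtol=tol, atol=tol * max(diam, 1.0),
                        max_step=t_max / 50 if max_step is None else max_step,
                        dense_output=True)
        ts = np.linspace(0.0, sol.t[-1], 200)
        path = sol.sol(ts).T
        # truncate where the line leaves the domain or exceeds max arc length
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        keep = arc <= max_arc_length
        if inside is not None:
            ok = np.fromiter((inside.contains(Point(*pt)) for pt in path),
                             bool, len(path))
            bad = np.flatnonzero(~ok)
            if bad.size:
                keep[bad[0]:] = False
                keep[bad[0]] = True  # keep the first crossing point
        lines.append(path[keep])
    return lines


def _ordered_boundary_polygon(mesh) -> np.ndarray:
    """Chain boundary edges into an ordered closed polygon (2D)."""
    edges = {tuple(e) for e in mesh.boundary_facets}
    nxt: dict[int, list[int]] = {}
    for a, b in edges:
        nxt.setdefault(a, []).append(b)
        nxt.setdefault(b, []).append(a)
    start = next(iter(nxt))
    order = [start]
    prev = None
    while True:
        cands = [n for n in nxt[order[-1]] if n != prev]
        prev = order[-1]
        order.append(cands[0])
        if order[-1] == start:
            break
    return mesh.nodes[order[:-1]]


def vorticity(u: VelocityField) -> np.ndarray:
    """Scalar vorticity ∂u_y/∂x − ∂u_x/∂y projected onto the vertex space.

    2D only; returns nodal values (1/s).
    """
    space = u.space
    if space.dim != 2:
        raise NotImplementedError("vorticity output is 2D only")
    _, wq, _, g2, phi1, _ = space.quad()
    # curl of the quadratic velocity at quadrature points
    ux = u.dofs[0][space.element_dofs]
    uy = u.dofs[1][space.element_dofs]
    curl = np.einsum("ei,eqi->eq", uy, g2[:, :, :, 0]) - np.einsum(
        "ei,eqi->eq", ux, g2[:, :, :, 1])
    rhs = np.zeros(space.mesh.n_nodes)
    np.add.at(rhs, space.mesh.simplices.ravel(),
              np.einsum("eq,qj->ej", wq * curl, phi1).ravel())
    from scipy.sparse.linalg import spsolve

    return spsolve(space.p1_mass.tocsc(), rhs)


# ---------------------------------------------------------------------------
# Profiles and their fits
# ---------------------------------------------------------------------------

def line_profile(field, p0, p1, n: int, normalized: bool = True):
    """Sample a field along the segment p0→p1 at n evenly spaced points.

    ``field`` is any callable on points (e.g. ``VelocityField.at`` or
    ``PressureField.at``); returns ``(s, values)`` with s the arc-length
    coordinate (normalised to [0, 1] by default). Raises
    :class:`DomainError` if a sample falls outside the field's domain hull.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    if hasattr(field, "space"):
        hull = field.space.coords
        from scipy.spatial import Delaunay

        tri = Delaunay(hull)
        outside = tri.find_simplex(pts) < 0
        if outside.any():
            k = int(np.flatnonzero(outside)[0])
            raise DomainError(
                f"sample {k} at {pts[k]} lies outside the meshed domain")
        vals = field.at(pts)
    else:
        vals = np.asarray(field(pts))
    length = np.linalg.norm(p1 - p0)
    s = ts if normalized else ts * length
    return s, np.asarray(vals)


@dataclass
class PoiseuilleFit:
    v_max: float
    width: float | None
    r_squared: float
    coeffs: np.ndarray
    width_defined: bool = True


def fit_poiseuille(s: np.ndarray, v: np.ndarray) -> PoiseuilleFit:
    """Least-squares parabola through a transverse velocity profile.

    ``width`` is the distance between the parabola's real roots (the wall
    positions for a no-slip channel); flagged undefined when the parabola has
    no real roots.
    """
    s, v = np.asarray(s, float), np.asarray(v, float)
    if len(s) < 5:
        raise ValueError("need at least 5 samples for a parabola fit")
    coeffs = np.polyfit(s, v, 2)
    fit = np.polyval(coeffs, s)
    ss_res = float(((v - fit) ** 2).sum())
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a, b, c = coeffs
    disc = b * b - 4 * a * c
    # a parabola indistinguishable from a line has no meaningful width
    span = max(float(np.ptp(s)), 1e-300)
    degenerate = abs(a) * span ** 2 < 1e-9 * max(float(np.ptp(v)), 1e-300)
    if a == 0 or degenerate or disc < 0:
        return PoiseuilleFit(float(np.max(fit)), None, r2, coeffs,
                             width_defined=False)
    roots = np.sort(np.roots(coeffs).real)
    v_max = float(np.polyval(coeffs, -b / (2 * a)))
    return PoiseuilleFit(v_max, float(roots[1] - roots[0]), r2, coeffs)


@dataclass
class SigmoidParams:
    """p(s) = d + a / (1 + exp(−b (s − c))) along normalised arc length s."""

    a: float
    b: float
    c: float
    d: float
    residual: float = 0.0

    def __iter__(self):
        return iter((self.a, self.b, self.c, self.d))

    def evaluate(self, s):
        return self.d + self.a / (1.0 + np.exp(-self.b * (np.asarray(s) - self.c)))


def _sigmoid(s, a, b, c, d):
    return d + a / (1.0 + np.exp(-b * (s - c)))


def fit_sigmoid(s: np.ndarray, p: np.ndarray) -> SigmoidParams:
    """Nonlinear least-squares sigmoid fit of a pressure profile.

    Deterministic initialisation: offset from min(p), amplitude from the
    range, position from the half-range crossing, slope from the
    inter-quartile rise.
    """
    s, p = np.asarray(s, float), np.asarray(p, float)
    if len(s) < 8:
        raise ValueError("need at least 8 samples spanning s in [0, 1]")
    rng = float(np.ptp(p))
    if rng == 0:
        raise FitError("flat profile has no sigmoid shape", init=None)
    d0, a0 = float(p.min()), rng
    half = d0 + a0 / 2
    c0 = float(s[np.argmin(np.abs(p - half))])
    q1 = d0 + 0.25 * a0
    q3 = d0 + 0.75 * a0
    s1 = float(s[np.argmin(np.abs(p - q1))])
    s3 = float(s[np.argmin(np.abs(p - q3))])
    span = abs(s3 - s1)
    b0 = np.sign(s3 - s1) * (2 * np.log(3) / span if span > 0 else 8.0)
    if b0 == 0:
        b0 = 8.0
    init = (a0, b0, c0, d0)
    try:
        popt, _ = curve_fit(_sigmoid, s, p, p0=init, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}", init=init) from exc
    resid = float(np.sqrt(np.mean((_sigmoid(s, *popt) - p) ** 2)))
    if popt[1] == 0:
        raise FitError("degenerate zero-slope sigmoid", init=init, residual=resid)
    return SigmoidParams(*[float(v) for v in popt], residual=resid)


def collapse_sigmoid(s: np.ndarray, p: np.ndarray, params: SigmoidParams):
    """Linearise a sigmoidal profile: p ↦ c − ln(a/(p−d) − 1)/b.

    For an exact sigmoid the output equals s (the identity line), so profiles
    from different cells collapse onto one unitary line. Samples outside the
    open range (d, d+a) cannot be transformed and are dropped; their count is
    returned.
    """
    s, p = np.asarray(s, float), np.asarray(p, float)
    a, b, c, d = params.a, params.b, params.c, params.d
    z = (p - d) / a
    valid = (z > 0) & (z < 1)
    n_dropped = int((~valid).sum())
    if not valid.any():
        raise DegenerateTransform("no sample lies strictly inside (d, d+a)")
    collapsed = c - np.log(1.0 / z[valid] - 1.0) / b
    return s[valid], collapsed, n_dropped


def cluster_sigmoid_params(param_sets, k: int, seed: int = 0):
    """Standardise (a, b, c, d), project on two principal components, k-means.

    Returns ``(pca_scores, labels, diagnostics)``; clustering is flagged
    degenerate when fewer than k distinct parameter sets exist.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    X = np.array([[p.a, p.b, p.c, p.d] for p in param_sets], dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    Xs = StandardScaler().fit_transform(X)
    n_comp = min(2, n, X.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(Xs)
    n_distinct = len(np.unique(Xs.round(12), axis=0))
    degenerate = n_distinct < k
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xs)
    return scores, km.labels_, {"degenerate": degenerate,
                                "inertia": float(km.inertia_)}


# ---------------------------------------------------------------------------
# Time-series analytics
# ---------------------------------------------------------------------------

def butterworth_lowpass(series: np.ndarray, cutoff: float, dt: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of a uniformly sampled series.

    Forward-backward filtering keeps peaks in place (causal filtering would
    bias the cross-correlation lags measured downstream) at the cost of
    doubling the effective order.
    """
    nyquist = 0.5 / dt
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist {nyquist} Hz")
    series = np.asarray(series, float)
    b, a = signal.butter(order, cutoff / nyquist)
    padlen = min(3 * max(len(a), len(b)), len(series) - 1)
    return signal.filtfilt(b, a, series, padlen=padlen)


def ccf_lag(x: np.ndarray, y: np.ndarray, dt: float,
            max_lag: float | None = None):
    """Lag of the cross-correlation peak between two series.

    Sign convention: a positive lag means x precedes y (y is a delayed copy
    of x). Returns ``(lag_seconds, peak_correlation)``; the peak value may be
    negative for anti-correlated series.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("constant series have undefined correlation")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    n = len(x)
    cc = np.correlate(ys, xs, mode="full") / n  # index n-1 is zero lag
    lags = np.arange(-(n - 1), n)
    if max_lag is not None:
        keep = np.abs(lags) * dt <= max_lag
        cc, lags = cc[keep], lags[keep]
    i = int(np.argmax(cc))
    return float(lags[i] * dt), float(cc[i])


@dataclass
class PeriodEstimate:
    """Dominant Fourier periods of a series, sorted by amplitude."""

    periods: np.ndarray      # s
    amplitudes: np.ndarray
    mean_level: float
    frequencies: np.ndarray  # Hz
    phases: np.ndarray

    def reconstruction(self, t: np.ndarray) -> np.ndarray:
        """Mean plus the selected cosine components (cf. partial Fourier sum)."""
        out = np.full_like(np.asarray(t, float), self.mean_level)
        for A, f, ph in zip(self.amplitudes, self.frequencies, self.phases):
            out = out + A * np.cos(2 * np.pi * f * np.asarray(t) + ph)
        return out


def dominant_periods(series: np.ndarray, dt: float,
                     n_components: int = 2) -> PeriodEstimate:
    """The strongest positive-frequency components of the series spectrum.

    The mean is removed, the discrete Fourier transform taken, and the
    ``n_components`` largest-amplitude bins returned as periods (amplitude
    ordering). Invariant to adding a constant.
    """
    series = np.asarray(series, float)
    n = len(series)
    if n < 4:
        raise ValueError("need at least 4 samples")
    spec = np.fft.rfft(series - series.mean())
    freqs = np.fft.rfftfreq(n, dt)
    amps = 2 * np.abs(spec) / n
    amps[0] = 0.0
    if n % 2 == 0 and len(amps) > 1:
        amps[-1] /= 2  # Nyquist bin is not doubled
    n_avail = int((amps > 0).sum())
    if n_components > len(amps) - 1:
        raise ValueError(
            f"requested {n_components} components but only {len(amps) - 1} "
            "positive-frequency bins exist")
    if n_avail == 0:
        return PeriodEstimate(np.array([]), np.array([]),
                              float(series.mean()), np.array([]), np.array([]))
    # select distinct spectral peaks (local maxima) by amplitude, so leakage
    # sidelobes of one strong component do not mask a weaker second one
    padded = np.concatenate([[0.0], amps, [0.0]])
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] >= padded[2:]) & (amps > 0)
    candidates = np.flatnonzero(is_peak)
    if len(candidates) < min(n_components, n_avail):
        candidates = np.flatnonzero(amps > 0)
    order = candidates[np.argsort(amps[candidates])[::-1]]
    order = order[: min(n_components, n_avail)]
    return PeriodEstimate(
        periods=1.0 / freqs[order],
        amplitudes=amps[order],
        mean_level=float(series.mean()),
        frequencies=freqs[order],
        phases=np.angle(spec[order]),
    )


def _gauss_mixture(x, *params):
    out = np.zeros_like(x)
    for i in range(len(params) // 3):
        w, m, s = params[3 * i : 3 * i + 3]
        out = out + w * np.exp(-((x - m) ** 2) / (2 * s ** 2))
    return out


def fit_period_mixture(periods, n_gaussians: int = 2, n_bins: int = 20):
    """Fit a sum of Gaussians to the histogram density of period estimates.

    Initialisation is deterministic, from the top histogram modes. Returns
    ``(means, sds, weights, residual, diagnostics)`` with components sorted
    by mean; overlapping components (separation below one joint s.d.) are
    flagged in the diagnostics.
    """
    periods = np.asarray(periods, float)
    if len(periods) < 3 * n_gaussians:
        raise ValueError("need at least 3 samples per Gaussian component")
    density, edges = np.histogram(periods, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # deterministic initialisation from local maxima of the histogram
    order = np.argsort(density)[::-1]
    peaks: list[int] = []
    for i in order:
        if all(abs(centers[i] - centers[j]) > 2 * (edges[1] - edges[0])
               for j in peaks):
            peaks.append(int(i))
        if len(peaks) == n_gaussians:
            break
    while len(peaks) < n_gaussians:
        peaks.append(int(order[len(peaks)]))
    sd0 = max(np.std(periods) / n_gaussians, (edges[1] - edges[0]))
    p0 = []
    for i in peaks:
        p0 += [max(density[i], 1e-3), centers[i], sd0]
    try:
        popt, _ = curve_fit(_gauss_mixture, centers, density, p0=p0,
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"period mixture fit did not converge: {exc}",
                       init=p0) from exc
    resid = float(np.sqrt(np.mean((_gauss_mixture(centers, *popt) - density) ** 2)))
    comps = sorted(
        [(popt[3 * i + 1], abs(popt[3 * i + 2]), popt[3 * i]) for i in range(n_gaussians)]
    )
    means = np.array([c[0] for c in comps])
    sds = np.array([c[1] for c in comps])
    weights = np.array([c[2] for c in comps])
    # unimodal data fitted with extra components shows up either as two
    # overlapping Gaussians or as one with negligible mass (weight x sd)
    masses = weights * sds
    overlapping = bool(
        any(means[i + 1] - means[i] < max(sds[i], sds[i + 1])
            for i in range(len(means) - 1))
        or (len(masses) > 1 and masses.min() < 0.05 * masses.max())
    )
    return means, sds, weights, resid, {"overlapping": overlapping}


# ---------------------------------------------------------------------------
# Out-of-plane bookkeeping, protrusion acceleration, Darcy estimate
# ---------------------------------------------------------------------------

def out_of_plane_volumes(r: DivergenceSource, dt: float):
    """Volumes entering/leaving the focal plane over one frame interval.

    With the unit-μm slab convention, V_in = Δt ∫_{r>0} r dΩ and
    V_out = −Δt ∫_{r<0} r dΩ (μm³); the visible area change is
    Δt ∫Ω r dΩ (μm²), so V_in − V_out = net_area_change × 1 μm exactly at
    quadrature level.
    """
    space = r.space
    if space.dim != 2:
        raise ValueError("out-of-plane bookkeeping applies to 2D solutions")
    _, wq, _, _, phi1, _ = space.quad()
    rq = np.einsum("qi,ei->eq", phi1, r.dofs[space.mesh.simplices])
    pos = float((wq * np.clip(rq, 0, None)).sum())
    neg = float((wq * np.clip(rq, None, 0)).sum())
    v_in = dt * pos
    v_out = -dt * neg
    net_area = dt * (pos + neg)
    return v_out, v_in, net_area


def bleb_acceleration(mean_speed: np.ndarray, dt: float) -> np.ndarray:
    """Frame-to-frame acceleration: forward difference of the speed series."""
    mean_speed = np.asarray(mean_speed, float)
    if len(mean_speed) < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(mean_speed) / dt


def darcy_pressure(u: float, nu: float, h: float, l: float) -> float:
    """Pressure drop u·ν·h/l² across a porous cortex layer (Darcy scaling).

    Parameters: flow speed u (μm/s), fluid viscosity ν (Pa·s), layer
    thickness h (μm), pore size l (μm). Returns Pa (the μm factors cancel).
    """
    if min(u, nu, h, l) <= 0:
        raise ValueError("all Darcy parameters must be positive")
    return u * nu * h / l ** 2
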