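"""Automated equatorial-slice GUV membrane tracing and curvature statistics.

The tracer walks around a bright thin-ring membrane signal in a confocal
slice.  Starting from a user-supplied (or automatically estimated) centre of
mass ``x0`` and a seed pixel on the membrane, each step

1. computes an adaptive intensity threshold from a square region centred on
   ``x0`` whose side is the seed's distance to the origin plus a fixed strip,
2. collects the above-threshold pixels in a small ROI around the current
   seed, rotates them into a local frame in which the membrane runs
   approximately horizontally, and fits a second-order polynomial
   ``y(x) = a + b x + c x**2`` through their coordinates,
3. takes the above-threshold pixel closest to the parabola vertex as the
   membrane point, and obtains the next seed by rotating that point about
   ``x0`` by the step angle.

A full revolution at step angle ``s`` yields ``360/s`` ordered membrane
points.  A reference circle is fitted through all points (algebraic
least-squares), each point's normalized local curvature is ``k_i = R0/R_i``
with ``R_i`` the distance from the fitted centre, and the deformation
statistic is the standard deviation ``SD_k`` of all ``k_i``.  A vesicle is
classified deformed when ``SD_k`` exceeds the bare-vesicle baseline
(default 0.026).

Coordinates are 0-based pixel indices in ``(row, col)`` order with the origin
at the top-left; angles are measured from the +row axis towards the +col
axis.  The traced membrane points are pixel coordinates (as selected by the
vertex-snapping rule); the sub-pixel parabola vertices are retained alongside
and are used for curvature by default, since pixel quantization alone adds a
radial noise floor of ~0.3 px that would dominate ``SD_k`` for small vesicles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "TraceSettings",
    "TraceStepFit",
    "ContourTrace",
    "ReferenceCircle",
    "CurvatureProfile",
    "PopulationShapeStats",
    "TraceError",
    "find_center",
    "adaptive_threshold",
    "trace_contour",
    "fit_circle_kasa",
    "fit_reference_circle",
    "curvature_profile",
    "population_stats",
    "calibrate_baseline",
    "trace_guv",
    "DEFORMATION_THRESHOLD",
]

#: Mean SD_k of bare vesicles, the default deformation threshold.
DEFORMATION_THRESHOLD = 0.026


class TraceError(RuntimeError):
    """Raised when the membrane trace cannot be completed."""


@dataclass(frozen=True)
class TraceSettings:
    """Parameters of the rotation-stepping membrane tracer.

    Parameters
    ----------
    roi_size:
        Odd side length (px) of the square ROI centred on the current seed.
    step_deg:
        Angular step of the rotation; 360 must be divisible by it.
    threshold_strip_extra:
        Extra width (px) added to the seed-origin distance when sizing the
        adaptive-threshold region (the ``+ 20`` of ``d = |x_i| + 20``).
    max_radius_factor:
        A traced point farther than this multiple of the initial radius from
        the origin aborts the trace as non-convergent wandering.
    fit_weighting:
        "intensity" (default) weights the parabola fit by how much each ROI
        pixel exceeds the threshold, so the vertex estimates the bright
        membrane ridge; "none" fits the binarized pixel coordinates
        unweighted, which estimates the above-threshold band mid-line and
        carries ~0.25 px of quantization noise.
    """

    roi_size: int = 21
    step_deg: float = 3.0
    threshold_strip_extra: int = 20
    max_radius_factor: float = 3.0
    fit_weighting: Literal["intensity", "none"] = "intensity"
    vertex_clamp_px: float = 2.0

    def __post_init__(self) -> None:
        if self.roi_size % 2 == 0 or not (5 <= self.roi_size <= 101):
            raise ValueError("roi_size must be odd and within [5, 101]")
        if self.step_deg <= 0 or abs(360.0 / self.step_deg - round(360.0 / self.step_deg)) > 1e-9:
            raise ValueError("360 must be divisible by step_deg")
        if self.threshold_strip_extra < 0:
            raise ValueError("threshold_strip_extra must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(360.0 / self.step_deg))


@dataclass(frozen=True)
class TraceStepFit:
    """Per-step record of the local parabola fit."""

    coefficients: tuple[float, float, float]  # (a, b, c) of y = a + b x + c x^2
    vertex: tuple[float, float]  # (row, col), sub-pixel
    pixel: tuple[int, int]  # chosen membrane pixel (row, col)
    threshold: float
    n_roi_pixels: int


@dataclass
class ContourTrace:
    """Ordered membrane point set produced by the rotation-stepping tracer."""

    origin: np.ndarray  # (row, col) centre of mass, defined as the origin
    step_deg: float
    points: np.ndarray  # (n, 2) integer pixel coordinates (row, col)
    vertices: np.ndarray  # (n, 2) sub-pixel parabola vertices (row, col)
    step_fits: list[TraceStepFit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ReferenceCircle:
    """Least-squares circle through all trace points."""

    center: tuple[float, float]  # (row, col)
    radius: float


@dataclass
class CurvatureProfile:
    """Per-point normalized local curvatures and the SD_k statistic."""

    radii: np.ndarray  # R_i, distance fitted centre -> point
    k: np.ndarray  # k_i = R0 / R_i
    sd_k: float
    threshold: float
    deformed: bool


@dataclass
class PopulationShapeStats:
    """Population-level deformation summary over many vesicles."""

    sd_k_values: np.ndarray
    efficiency: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


# ---------------------------------------------------------------------------
# centre estimation and adaptive threshold


def find_center(image: np.ndarray) -> np.ndarray:
    """Intensity-weighted centroid of the above-Otsu pixels, (row, col).

    Stands in for the manual centre-of-mass selection of an equatorial slice;
    pass an explicit centre to override.
    """
    pixels = np.asarray(image, dtype=float)
    mask = pixels > threshold_otsu(pixels)
    if not mask.any():
        raise TraceError("no foreground pixels above the Otsu threshold")
    rows, cols = np.nonzero(mask)
    w = pixels[rows, cols]
    return np.array([np.average(rows, weights=w), np.average(cols, weights=w)])


def adaptive_threshold(
    image: np.ndarray,
    x0: Sequence[float],
    x_seed: Sequence[float],
    extra: int = 20,
) -> float:
    """Mean intensity of a square region centred on ``x0``.

    The side of the square is ``d = |x_seed - x0| + extra`` pixels (clipped to
    the frame), so the region grows with the vesicle and covers mostly its
    interior; membrane pixels are the ones brighter than this mean.
    """
    pixels = np.asarray(image, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    x_seed = np.asarray(x_seed, dtype=float)
    h, w = pixels.shape
    if not (0 <= x0[0] < h and 0 <= x0[1] < w):
        raise ValueError("x0 lies outside the frame")
    if not (0 <= x_seed[0] < h and 0 <= x_seed[1] < w):
        raise ValueError("x_seed lies outside the frame")
    d = int(round(float(np.hypot(*(x_seed - x0))))) + int(extra)
    if d < 3:
        raise ValueError(f"degenerate threshold region (side {d} px < 3 px)")
    half = d // 2
    r0, c0 = int(round(x0[0])), int(round(x0[1]))
    region = pixels[max(0, r0 - half): r0 + half + 1, max(0, c0 - half): c0 + half + 1]
    return float(region.mean())


# ---------------------------------------------------------------------------
# tracing


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def trace_contour(
    image: np.ndarray,
    x0: Sequence[float] | None = None,
    x_seed: Sequence[float] | None = None,
    settings: TraceSettings | None = None,
) -> ContourTrace:
    """Trace the membrane ring by iterative rotations about the origin.

    Parameters
    ----------
    image:
        2D intensity grid (a single equatorial slice).
    x0:
        Centre of mass (row, col); estimated with :func:`find_center` when
        omitted.
    x_seed:
        Initial membrane pixel; the brightest pixel of the frame when omitted.
    settings:
        :class:`TraceSettings`; defaults to ROI 21 px, 3-degree steps.

    Returns
    -------
    ContourTrace
        With exactly ``360/step_deg`` points on success.

    Raises
    ------
    TraceError
        If an ROI contains no above-threshold pixel (naming the step and
        angle) or the trace wanders beyond ``max_radius_factor`` times the
        initial radius.
    """
    pixels = np.asarray(image, dtype=float)
    settings = settings or TraceSettings()
    origin = np.asarray(x0, dtype=float) if x0 is not None else find_center(pixels)
    if x_seed is None:
        seed = np.array(np.unravel_index(np.argmax(pixels), pixels.shape), dtype=float)
    else:
        seed = np.asarray(x_seed, dtype=float)

    h, w = pixels.shape
    half = settings.roi_size // 2
    r_init = float(np.hypot(*(seed - origin)))
    if r_init == 0:
        raise TraceError("seed coincides with the origin")
    step_rad = np.deg2rad(settings.step_deg)
    m_step = _rotation(step_rad)

    points = np.empty((settings.n_steps, 2), dtype=int)
    vertices = np.empty((settings.n_steps, 2), dtype=float)
    fits: list[TraceStepFit] = []

    for i in range(settings.n_steps):
        thr = adaptive_threshold(pixels, origin, seed, settings.threshold_strip_extra)

        rc, cc = int(round(seed[0])), int(round(seed[1]))
        r_lo, r_hi = max(0, rc - half), min(h, rc + half + 1)
        c_lo, c_hi = max(0, cc - half), min(w, cc + half + 1)
        window = pixels[r_lo:r_hi, c_lo:c_hi]
        rows, cols = np.nonzero(window > thr)
        if rows.size == 0:
            raise TraceError(
                f"trace failure at step {i} (angle {i * settings.step_deg:.1f} deg): "
                "no ROI pixel above the adaptive threshold"
            )
        coords = np.column_stack([rows + r_lo, cols + c_lo]).astype(float)
        intensities = window[rows, cols]

        # Local frame: rotate so the radial direction maps onto the +y axis,
        # making the membrane locally horizontal and the fit well-posed at
        # every polar angle.
        alpha = float(np.arctan2(seed[1] - origin[1], seed[0] - origin[0]))
        q = _rotation(np.pi / 2 - alpha)
        local = (coords - seed) @ q.T  # columns: (xi tangential, eta radial)
        xi, eta = local[:, 0], local[:, 1]

        if np.ptp(xi) > 1e-9 and xi.size >= 3:
            if settings.fit_weighting == "intensity":
                fit_w = np.sqrt(np.clip(intensities - thr, 0.0, None) + 1e-12)
            else:
                fit_w = None
            c2, b, a = np.polyfit(xi, eta, 2, w=fit_w)
        else:  # membrane segment degenerate along the tangent; fall back
            a, b, c2 = float(eta.mean()), 0.0, 0.0
        # The parabola vertex estimates the membrane point only where the
        # membrane runs nearly normal to the radial ray; on tilted sections
        # the vertex slides tangentially by ~ -tan(tilt)/curvature, which is
        # unbounded and would stall the angular stepping.  Keep the vertex
        # when it is close to the ray, otherwise take the ray crossing xi=0.
        if abs(c2) > 1e-12 and abs(-b / (2.0 * c2)) <= settings.vertex_clamp_px:
            xi_v = float(-b / (2.0 * c2))
        else:
            xi_v = 0.0
        eta_v = a + b * xi_v + c2 * xi_v**2
        vertex = seed + np.array([xi_v, eta_v]) @ q  # rotate back: q.T @ v

        d2 = np.sum((coords - vertex) ** 2, axis=1)
        # nearest pixel; ties broken by higher intensity, then lower row/col
        order = np.lexsort((coords[:, 1], coords[:, 0], -intensities, np.round(d2, 9)))
        best = order[0]
        point = coords[best]

        if float(np.hypot(*(point - origin))) > settings.max_radius_factor * r_init:
            raise TraceError(
                f"trace wandered at step {i}: point {tuple(point)} farther than "
                f"{settings.max_radius_factor}x the initial radius from the origin"
            )

        points[i] = point.astype(int)
        vertices[i] = vertex
        fits.append(
            TraceStepFit(
                coefficients=(float(a), float(b), float(c2)),
                vertex=(float(vertex[0]), float(vertex[1])),
                pixel=(int(point[0]), int(point[1])),
                threshold=thr,
                n_roi_pixels=int(rows.size),
            )
        )
        seed = origin + m_step @ (point - origin)

    return ContourTrace(
        origin=origin,
        step_deg=settings.step_deg,
        points=points,
        vertices=vertices,
        step_fits=fits,
    )


# ---------------------------------------------------------------------------
# circle fit and curvature


def fit_circle_kasa(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle through a 2D point set.

    Solves ``min sum (|p|^2 - 2 u.p - v)^2`` in closed form; exact on exact
    circles and deterministic.  Returns ``(center, radius)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 2)")
    a_mat = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b_vec = np.sum(pts**2, axis=1)
    sol, _, rank, sv = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    if rank < 3 or sv[-1] < 1e-12 * sv[0]:
        raise ValueError("points are collinear; circle fit is degenerate")
    center = sol[:2]
    radius = float(np.sqrt(sol[2] + center @ center))
    return center, radius


def fit_reference_circle(trace: ContourTrace | np.ndarray, points: Literal["vertex", "pixel"] = "vertex") -> ReferenceCircle:
    """Fit the reference circle ``R0`` through all trace points."""
    pts = _select_points(trace, points)
    center, radius = fit_circle_kasa(pts)
    return ReferenceCircle(center=(float(center[0]), float(center[1])), radius=radius)


def _select_points(trace: ContourTrace | np.ndarray, points: str) -> np.ndarray:
    if isinstance(trace, ContourTrace):
        return trace.vertices if points == "vertex" else trace.points.astype(float)
    return np.asarray(trace, dtype=float)


def curvature_profile(
    trace: ContourTrace | np.ndarray,
    circle: ReferenceCircle | None = None,
    threshold: float = DEFORMATION_THRESHOLD,
    points: Literal["vertex", "pixel"] = "vertex",
) -> CurvatureProfile:
    """Normalized local curvatures ``k_i = R0/R_i`` and the SD_k statistic.

    ``SD_k`` is the population (divide-by-n) standard deviation of all
    ``k_i``; the vesicle is classified deformed when ``SD_k`` strictly
    exceeds ``threshold``.
    """
    pts = _select_points(trace, points)
    if circle is None:
        circle = fit_reference_circle(pts)
    center = np.asarray(circle.center)
    radii = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    if np.any(radii == 0):
        raise ValueError("a trace point coincides with the fitted centre (R_i = 0)")
    k = circle.radius / radii
    sd_k = float(np.std(k))
    return CurvatureProfile(radii=radii, k=k, sd_k=sd_k, threshold=threshold, deformed=bool(sd_k > threshold))


def population_stats(
    profiles: Sequence[CurvatureProfile],
    bins: int | np.ndarray = 60,
    k_range: tuple[float, float] | None = (0.7, 1.3),
) -> PopulationShapeStats:
    """Deformation efficiency and pooled k_i histogram over many vesicles.

    Efficiency is the fraction of analysed vesicles classified deformed.
    """
    if len(profiles) == 0:
        raise ValueError("population_stats needs at least one profile")
    sd_values = np.array([p.sd_k for p in profiles])
    efficiency = float(np.mean([p.deformed for p in profiles]))
    pooled = np.concatenate([p.k for p in profiles])
    counts, edges = np.histogram(pooled, bins=bins, range=k_range)
    return PopulationShapeStats(
        sd_k_values=sd_values, efficiency=efficiency, hist_counts=counts, hist_edges=edges
    )


def calibrate_baseline(profiles: Sequence[CurvatureProfile]) -> float:
    """Mean SD_k over a bare-vesicle set: the recalibrated deformation threshold."""
    if len(profiles) == 0:
        raise ValueError("baseline calibration needs at least one profile")
    return float(np.mean([p.sd_k for p in profiles]))


def trace_guv(
    image: np.ndarray,
    x0: Sequence[float] | None = None,
    x_seed: Sequence[float] | None = None,
    settings: TraceSettings | None = None,
    threshold: float = DEFORMATION_THRESHOLD,
    points: Literal["vertex", "pixel"] = "vertex",
) -> tuple[ContourTrace, ReferenceCircle, CurvatureProfile]:
    """Convenience pipeline: trace, fit the reference circle, profile curvature."""
    trace = trace_contour(image, x0=x0, x_seed=x_seed, settings=settings)
    circle = fit_reference_circle(trace, points=points)
    profile = curvature_profile(trace, circle, threshold=threshold, points=points)
    return trace, circle, profile
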