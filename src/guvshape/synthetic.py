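"""Synthetic confocal-style data with known ground truth.

Every analysis stage in this package is exercised against data from this
module: equatorial vesicle slices (a bright thin membrane ring over
interior/exterior dye levels with Poisson-Gaussian noise), influx
time-lapses driven by a membrane-permeability scenario, FRAP series,
analytic FCS autocorrelation curves and exponential binding series.  All
generators are deterministic for a fixed seed.

The vesicle outline is an analytic star-convex contour

    r(theta) = R * (1 + sum_n amp_n * cos(n * theta + phase_n))

whose exact curvature statistic (the SD of k_i = R0/R_i over a dense
angular grid, with the reference circle fitted exactly as in the analysis
module) serves as the ground-truth oracle for the tracer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .fcs import FcsCurve, g_2d
from .kinetics import BindingSeries, FluxSeries
from .tracing import fit_circle_kasa

__all__ = [
    "ContourShape",
    "OpticsModel",
    "NoiseModel",
    "ImageFrame",
    "PermeabilityScenario",
    "make_contour",
    "render_guv_slice",
    "interior_level_at",
    "simulate_influx_stack",
    "generate_fcs_curve",
    "generate_binding_series",
    "generate_fret_spectra",
    "save_tiff_stack",
    "load_tiff_stack",
]


@dataclass(frozen=True)
class ContourShape:
    """Analytic star-convex vesicle outline.

    ``center`` is in microns in the frame's physical coordinates (x = column
    direction, y = row direction); ``modes`` are (order n >= 2, amplitude as
    a fraction of R, phase in radians).  An empty mode list is an exact
    circle.
    """

    center: tuple[float, float]
    radius_um: float
    modes: tuple[tuple[int, float, float], ...] = ()

    def r(self, theta: np.ndarray | float) -> np.ndarray | float:
        theta = np.asarray(theta, dtype=float)
        r = np.ones_like(theta)
        for n, amp, phase in self.modes:
            r = r + amp * np.cos(n * theta + phase)
        return self.radius_um * r

    def points(self, theta: np.ndarray) -> np.ndarray:
        """(n, 2) physical (x, y) points in microns."""
        r = self.r(theta)
        return np.column_stack(
            [self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta)]
        )

    def ground_truth_sd_k(self, n_theta: int = 3600) -> float:
        """Exact SD_k of the analytic outline on a dense angular grid.

        Uses the same least-squares circle definition as the tracing module
        so that oracle comparisons test the tracing, not circle conventions.
        """
        theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        pts = self.points(theta)
        center, r0 = fit_circle_kasa(pts)
        radii = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
        return float(np.std(r0 / radii))


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model of one channel: ring cross-section and dye levels.

    The membrane signal is a Gaussian of the signed distance to the contour
    (confocal blur of a thin ring); soluble dye contributes a uniform
    interior or exterior level on top of a constant background.
    """

    pixel_size_um: float = 0.1
    membrane_sigma_um: float = 0.15
    membrane_peak: float = 200.0
    interior_level: float = 10.0
    exterior_level: float = 10.0
    background: float = 5.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.membrane_sigma_um <= 0:
            raise ValueError("pixel_size_um and membrane_sigma_um must be positive")
        for name in ("membrane_peak", "interior_level", "exterior_level", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise followed by additive Gaussian read noise.

    ``poisson_gain`` is photons per intensity unit (0 disables shot noise);
    ``gaussian_sd`` is in intensity units.  Identical seed and parameters
    give bit-identical images.
    """

    poisson_gain: float = 0.0
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, pixels: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        out = pixels.astype(float)
        if self.poisson_gain > 0:
            out = rng.poisson(out * self.poisson_gain).astype(float) / self.poisson_gain
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class ImageFrame:
    """A 2D non-negative intensity grid with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""
    time: float | None = None  # minutes for time-lapse stacks

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 2 or min(pixels.shape) < 64:
            raise ValueError("frames must be 2D with both sides >= 64 px")
        if not np.all(np.isfinite(pixels)) or np.any(pixels < 0):
            raise ValueError("pixel values must be finite and >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class PermeabilityScenario:
    """Membrane equilibration scenario for influx/FRAP emulation.

    After ``onset_min`` the interior dye level relaxes exponentially towards
    the exterior level with ``rate_per_min`` (0 = non-permeable).  Each
    bleach event ``(time_min, multiplier)`` instantaneously multiplies the
    interior level; relaxation then continues from the post-bleach value.
    """

    rate_per_min: float = 0.0
    onset_min: float = 0.0
    bleach_events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("equilibration rate must be >= 0")
        for t, m in self.bleach_events:
            if m < 0:
                raise ValueError("bleach multipliers must be >= 0")


def make_contour(
    radius_um: float,
    modes: Sequence[tuple[int, float, float]] = (),
    center_um: tuple[float, float] | None = None,
    seed: int | None = None,
    frame_size_px: int = 512,
    pixel_size_um: float = 0.1,
) -> ContourShape:
    """Build an analytic vesicle outline, optionally with random mode phases.

    ``seed`` randomizes the phases of modes whose phase is given as None;
    amplitudes must satisfy sum(|amp|) < 0.5 to guarantee r(theta) > 0 and a
    self-intersection-free outline.  The default centre is the middle of a
    ``frame_size_px`` frame.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    resolved = []
    for n, amp, phase in modes:
        if n < 2 or int(n) != n:
            raise ValueError("mode orders must be integers >= 2")
        resolved.append((int(n), float(amp), float(phase) if phase is not None else float(rng.uniform(0, 2 * np.pi))))
    if sum(abs(a) for _, a, _ in resolved) >= 0.5:
        raise ValueError("sum of |amplitudes| must be < 0.5 (self-intersection risk)")
    if center_um is None:
        half = frame_size_px * pixel_size_um / 2.0
        center_um = (half, half)
    return ContourShape(center=center_um, radius_um=radius_um, modes=tuple(resolved))


def _contour_distance_and_inside(
    shape: ContourShape, xx: np.ndarray, yy: np.ndarray, n_theta: int = 3600
) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned distance to the contour polyline and point-in-contour mask.

    Dense polyline sampling (0.1 degree) plus nearest-segment distance; at
    sub-pixel chord spacing this is exact to well below the pixel scale.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    poly = shape.points(theta)
    tree = cKDTree(poly)
    q = np.column_stack([xx.ravel(), yy.ravel()])
    _, idx = tree.query(q)

    def seg_dist(i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
        a, b = poly[i0], poly[i1]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        tpar = np.clip(np.einsum("ij,ij->i", q - a, ab) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
        proj = a + tpar[:, None] * ab
        return np.hypot(q[:, 0] - proj[:, 0], q[:, 1] - proj[:, 1])

    d = np.minimum(seg_dist((idx - 1) % n_theta, idx), seg_dist(idx, (idx + 1) % n_theta))
    inside = MplPath(poly).contains_points(q)
    return d.reshape(xx.shape), inside.reshape(xx.shape)


def render_guv_slice(
    shape: ContourShape,
    optics: OpticsModel | None = None,
    noise: NoiseModel | None = None,
    size_px: int = 512,
    channel: str = "membrane",
    time_min: float | None = None,
    rng: np.random.Generator | None = None,
) -> ImageFrame:
    """Render one equatorial slice: ring + interior/exterior dye + noise.

    Pixel value = background + (interior or exterior level by point-in-
    contour test) + membrane_peak * exp(-d^2 / (2 sigma^2)) with ``d`` the
    distance to the contour, then the noise model is applied.

    Raises when the contour does not fit the frame with a 5 px margin,
    naming the required frame size.
    """
    optics = optics or OpticsModel()
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = shape.points(theta) / optics.pixel_size_um  # now in px
    margin = 5.0
    lo, hi = pts.min(), pts.max()
    if lo < margin or hi > size_px - 1 - margin:
        needed = int(np.ceil(2 * max(hi - size_px / 2, size_px / 2 - lo) + 2 * margin + 1))
        raise ValueError(
            f"contour exceeds the {size_px} px frame (5 px margin); needs >= {needed} px"
        )

    # physical coordinates of pixel centres: x along columns, y along rows
    coords = (np.arange(size_px) + 0.0) * optics.pixel_size_um
    xx, yy = np.meshgrid(coords, coords, indexing="xy")  # xx varies along columns
    d, inside = _contour_distance_and_inside(shape, xx, yy)
    levels = np.where(inside, optics.interior_level, optics.exterior_level)
    pixels = optics.background + levels + optics.membrane_peak * np.exp(
        -(d**2) / (2.0 * optics.membrane_sigma_um**2)
    )
    if noise is not None:
        pixels = noise.apply(pixels, rng=rng)
    return ImageFrame(pixels=pixels, pixel_size_um=optics.pixel_size_um, channel=channel, time=time_min)


# ---------------------------------------------------------------------------
# influx time-lapse


def interior_level_at(
    times_min: np.ndarray,
    scenario: PermeabilityScenario,
    exterior_level: float,
    interior_level_0: float = 0.0,
) -> np.ndarray:
    """Analytic interior dye level under a permeability scenario.

    Between events the interior relaxes as
    ``I(t) = I_ext - (I_ext - I_current) * exp(-rate * dt)`` once past the
    onset; bleach events rescale the interior level instantaneously.
    """
    times = np.asarray(times_min, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    events = sorted(scenario.bleach_events)
    out = np.empty_like(times)

    def relax(level: float, t_from: float, t_to: float) -> float:
        if scenario.rate_per_min == 0:
            return level
        t_eff_from = max(t_from, scenario.onset_min)
        t_eff_to = max(t_to, scenario.onset_min)
        dt = t_eff_to - t_eff_from
        if dt <= 0:
            return level
        return exterior_level - (exterior_level - level) * np.exp(-scenario.rate_per_min * dt)

    for i, t in enumerate(times):
        level, t_cur = interior_level_0, 0.0
        for ev_t, ev_m in events:
            if ev_t > t:
                break
            level = relax(level, t_cur, ev_t) * ev_m
            t_cur = ev_t
        out[i] = relax(level, t_cur, t)
    return out


def simulate_influx_stack(
    shape: ContourShape,
    optics: OpticsModel,
    scenario: PermeabilityScenario,
    times_min: Sequence[float],
    noise: NoiseModel | None = None,
    size_px: int = 512,
    interior_level_0: float | None = None,
    exterior_roi_value: float | None = None,
) -> tuple[list[ImageFrame], FluxSeries]:
    """Dye-channel time-lapse of cargo influx plus its analytic ground truth.

    The frames use ``optics`` with the interior level evolved per the
    scenario; the returned :class:`FluxSeries` is the exact (noise-free)
    interior/exterior level pair, i.e. the ground-truth relative import
    level.  Per-frame noise streams are spawned from ``noise.seed`` so the
    stack is reproducible as a whole.
    """
    times = np.asarray(list(times_min), dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    i0 = interior_level_0 if interior_level_0 is not None else optics.interior_level
    levels = interior_level_at(times, scenario, optics.exterior_level, i0)

    frames: list[ImageFrame] = []
    child_seeds = (
        np.random.SeedSequence(noise.seed).spawn(len(times)) if noise is not None else [None] * len(times)
    )
    for t, level, ss in zip(times, levels, child_seeds):
        frame_optics = OpticsModel(
            pixel_size_um=optics.pixel_size_um,
            membrane_sigma_um=optics.membrane_sigma_um,
            membrane_peak=optics.membrane_peak,
            interior_level=float(level),
            exterior_level=optics.exterior_level,
            background=optics.background,
        )
        rng = np.random.default_rng(ss) if ss is not None else None
        frames.append(
            render_guv_slice(shape, frame_optics, noise=noise, size_px=size_px, channel="dye", time_min=float(t), rng=rng)
        )
    ext = optics.exterior_level + optics.background
    truth = FluxSeries(
        times_min=times,
        i_in=levels + optics.background,
        i_out=np.full_like(times, ext if exterior_roi_value is None else exterior_roi_value),
    )
    return frames, truth


# ---------------------------------------------------------------------------
# FCS and binding curves


def generate_fcs_curve(
    n: float,
    tau_d_s: float,
    lags_s: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FcsCurve:
    """Analytic one-component 2D diffusion curve plus optional Gaussian noise.

    Defaults to 64 log-spaced lags between 1 us and 1 s.
    """
    if n <= 0 or tau_d_s <= 0:
        raise ValueError("N and tau_D must be positive")
    lags = np.asarray(lags_s, dtype=float) if lags_s is not None else np.logspace(-6, 0, 64)
    g = g_2d(lags, n, tau_d_s)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, size=lags.shape)
    return FcsCurve(lags=lags, g=g)


def generate_binding_series(
    i_max: float,
    rate_per_min: float,
    times_min: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BindingSeries:
    """Saturating binding series I(t) = I_max (1 - exp(-a t)) plus noise."""
    if i_max <= 0 or rate_per_min <= 0:
        raise ValueError("I_max and the binding rate must be positive")
    times = np.asarray(list(times_min), dtype=float)
    i = i_max * (1.0 - np.exp(-rate_per_min * times))
    if noise_sd > 0:
        i = i + np.random.default_rng(seed).normal(0.0, noise_sd, size=times.shape)
    return BindingSeries(times_min=times, intensity=i)


def generate_fret_spectra(
    distances_nm: dict[str, float],
    forster_radius_nm: float = 5.4,
    wavelengths_nm: np.ndarray | None = None,
    donor_peak_nm: float = 570.0,
    acceptor_peak_nm: float = 670.0,
    band_sigma_nm: float = 15.0,
    total: float = 1000.0,
) -> pd.DataFrame:
    """Forward-model ensemble emission spectra of dye pairs at given distances.

    FRET efficiency E = 1 / (1 + (r/R0)^6); the donor band carries (1-E) of
    the emission, the acceptor band E, each as a Gaussian emission band.
    Used to exercise the proximity-ratio analysis with known state ordering.
    """
    wl = wavelengths_nm if wavelengths_nm is not None else np.arange(540.0, 721.0, 1.0)
    rows = []
    for state, r in distances_nm.items():
        e = 1.0 / (1.0 + (r / forster_radius_nm) ** 6)
        inten = total * (
            (1.0 - e) * np.exp(-((wl - donor_peak_nm) ** 2) / (2 * band_sigma_nm**2))
            + e * np.exp(-((wl - acceptor_peak_nm) ** 2) / (2 * band_sigma_nm**2))
        )
        rows.append(pd.DataFrame({"wavelength_nm": wl, "intensity": inten, "state": state}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O


def save_tiff_stack(frames: Sequence[ImageFrame], path: str | Path, ground_truth: dict | None = None) -> None:
    """Write a (multi-frame) TIFF with pixel size and frame times in metadata.

    An optional ground-truth dict goes to a ``.json`` sidecar next to it.
    """
    path = Path(path)
    stack = np.stack([f.pixels for f in frames]).astype(np.float32)
    meta = {
        "pixel_size_um": frames[0].pixel_size_um,
        "times_min": [f.time for f in frames],
        "channel": frames[0].channel,
    }
    tifffile.imwrite(path, stack, metadata=meta)
    if ground_truth is not None:
        path.with_suffix(".json").write_text(json.dumps(ground_truth, indent=2))


def load_tiff_stack(path: str | Path) -> list[ImageFrame]:
    """Read a TIFF written by :func:`save_tiff_stack` back into frames."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    times = meta.get("times_min") or [None] * len(stack)
    channel = meta.get("channel", "")
    return [
        ImageFrame(pixels=frame, pixel_size_um=pixel_size, channel=channel, time=t)
        for frame, t in zip(stack, times)
    ]
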