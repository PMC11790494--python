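"""Raft-binding kinetics, cargo-flux statistics, FRAP gating and FRET ratios.

Binding of labelled rafts to a vesicle membrane follows saturating
first-order kinetics ``I(t) = I_max (1 - exp(-a t))``.  Cargo exchange
across the membrane is quantified by the relative import level

    (<I_out> - <I_in>) / <I_out>

with ``<I_in>`` the mean intensity of a small ROI inside the vesicle and
``<I_out>`` the mean of two exterior ROIs: 1 for fully excluded cargo, 0 at
complete equilibration.  FRAP of the vesicle lumen gives a binary
open/sealed channel readout through the recovery fraction after the bleach,
and a probe ladder of increasing molecular weight yields the channel's
molecular-weight cut-off.  FRET proximity ratios (acceptor share of summed
donor+acceptor emission) report the raft conformation state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.optimize import curve_fit

__all__ = [
    "BindingSeries",
    "BindingFit",
    "FluxSeries",
    "FrapResult",
    "CutoffSummary",
    "ProximityRatio",
    "fit_binding",
    "flux_statistic",
    "frap_analysis",
    "cutoff_summary",
    "fret_proximity",
    "fret_ordering_flags",
]


@dataclass(frozen=True)
class BindingSeries:
    """Integrated membrane intensity versus time (minutes)."""

    times_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensity", i)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and intensities must be 1D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class BindingFit:
    """Fitted plateau intensity and binding rate constant."""

    i_max: float
    rate_per_min: float
    cov: np.ndarray

    def model(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.i_max * (1.0 - np.exp(-self.rate_per_min * np.asarray(t, dtype=float)))


def fit_binding(series: BindingSeries) -> BindingFit:
    """Nonlinear least squares of I(t) = I_max (1 - exp(-a t)).

    Initialization: I_max from the series maximum, the rate from the
    log-linearized early points.  Raises for constant series, fewer than 5
    points, or a non-converged fit.
    """
    t, i = series.times_min, series.intensity
    if t.size < 5:
        raise ValueError("binding fit needs at least 5 points")
    if np.ptp(i) == 0:
        raise ValueError("binding series is constant; nothing to fit")
    i_max0 = float(i.max())
    # log-linearize 1 - I/Imax on the early rising points for the rate seed
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - i / (i_max0 * 1.05)
        valid = (frac > 0) & (t > 0)
        a0 = float(-np.polyfit(t[valid], np.log(frac[valid]), 1)[0]) if valid.sum() >= 2 else 1.0 / t[t.size // 2]
    a0 = a0 if np.isfinite(a0) and a0 > 0 else 1.0 / float(t[t.size // 2])

    def model(tt: np.ndarray, i_max: float, a: float) -> np.ndarray:
        return i_max * (1.0 - np.exp(-a * tt))

    try:
        popt, pcov = curve_fit(
            model, t, i, p0=[i_max0, a0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"binding fit did not converge: {exc}") from exc
    return BindingFit(i_max=float(popt[0]), rate_per_min=float(popt[1]), cov=pcov)


# ---------------------------------------------------------------------------
# flux statistic


@dataclass(frozen=True)
class FluxSeries:
    """Interior/exterior intensity means and the relative import level."""

    times_min: np.ndarray
    i_in: np.ndarray
    i_out: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        iin = np.asarray(self.i_in, dtype=float)
        iout = np.asarray(self.i_out, dtype=float)
        for name, arr in (("times_min", t), ("i_in", iin), ("i_out", iout)):
            object.__setattr__(self, name, arr)
        if not (t.shape == iin.shape == iout.shape):
            raise ValueError("times, i_in and i_out must have equal shapes")
        if np.any(iout <= 0):
            raise ValueError("exterior intensity must be positive")

    @property
    def relative_import(self) -> np.ndarray:
        """(<I_out> - <I_in>) / <I_out>: 1 = excluded cargo, 0 = equilibrated."""
        return (self.i_out - self.i_in) / self.i_out


def _patch_mean(pixels: np.ndarray, center_rc: tuple[int, int], size: int) -> tuple[float, np.ndarray]:
    h, w = pixels.shape
    half = size // 2
    r, c = int(round(center_rc[0])), int(round(center_rc[1]))
    r_lo, r_hi = max(0, r - half), min(h, r + half + size % 2)
    c_lo, c_hi = max(0, c - half), min(w, c + half + size % 2)
    if r_hi <= r_lo or c_hi <= c_lo:
        raise ValueError(f"ROI centred at {center_rc} lies outside the frame")
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    return float(pixels[r_lo:r_hi, c_lo:c_hi].mean()), coords


def _default_exterior_positions(shape: tuple[int, int], center_rc: Sequence[float], roi: int) -> list[tuple[int, int]]:
    """Two exterior ROI centres at the frame corners farthest from the vesicle."""
    h, w = shape
    margin = roi // 2 + 2
    corners = [
        (margin, margin),
        (margin, w - 1 - margin),
        (h - 1 - margin, margin),
        (h - 1 - margin, w - 1 - margin),
    ]
    corners.sort(key=lambda p: -np.hypot(p[0] - center_rc[0], p[1] - center_rc[1]))
    return corners[:2]


def flux_statistic(
    frames: Sequence,
    center_rc: Sequence[float],
    roi_in: int = 30,
    roi_out: int = 50,
    roi_out_positions: Sequence[tuple[int, int]] | None = None,
    contour: np.ndarray | None = None,
    times_min: Sequence[float] | None = None,
    combine: str = "mean_of_means",
) -> FluxSeries:
    """Per-frame relative import level from interior/exterior ROI means.

    Parameters
    ----------
    frames:
        Sequence of 2D arrays or objects with ``pixels`` and ``time``
        attributes (e.g. :class:`guvshape.synthetic.ImageFrame`).
    center_rc:
        Vesicle centre (row, col); the interior ROI (default 30x30 px) is
        centred there.
    roi_out_positions:
        Centres of the two exterior ROIs (default ~50x50 px each); when
        omitted they are placed at the two frame corners farthest from the
        vesicle centre.
    contour:
        Optional (n, 2) membrane polygon in (row, col); exterior ROIs
        overlapping the enclosed region raise a ``ValueError``.
    combine:
        "mean_of_means" (default) averages the two exterior ROI means;
        "pooled" averages all exterior pixels together.
    """
    if combine not in ("mean_of_means", "pooled"):
        raise ValueError("combine must be 'mean_of_means' or 'pooled'")
    arrays = []
    times = []
    for idx, fr in enumerate(frames):
        pixels = np.asarray(getattr(fr, "pixels", fr), dtype=float)
        arrays.append(pixels)
        t = getattr(fr, "time", None)
        times.append(float(t) if t is not None else float(idx))
    if times_min is not None:
        times = [float(t) for t in times_min]
    shape = arrays[0].shape
    if roi_out_positions is None:
        roi_out_positions = _default_exterior_positions(shape, center_rc, roi_out)
    if len(roi_out_positions) < 1:
        raise ValueError("at least one exterior ROI is required")

    inside = None
    if contour is not None:
        inside = MplPath(np.asarray(contour, dtype=float))

    i_in, i_out = [], []
    for pixels in arrays:
        mean_in, _ = _patch_mean(pixels, tuple(center_rc), roi_in)
        means, pools = [], []
        for pos in roi_out_positions:
            mean_o, coords = _patch_mean(pixels, pos, roi_out)
            if inside is not None and inside.contains_points(coords + 0.0).any():
                raise ValueError(f"exterior ROI at {tuple(pos)} overlaps the vesicle contour")
            means.append(mean_o)
            pools.append(pixels[coords[:, 0], coords[:, 1]])
        i_in.append(mean_in)
        if combine == "mean_of_means":
            i_out.append(float(np.mean(means)))
        else:
            i_out.append(float(np.concatenate(pools).mean()))
    return FluxSeries(times_min=np.array(times), i_in=np.array(i_in), i_out=np.array(i_out))


# ---------------------------------------------------------------------------
# FRAP


@dataclass(frozen=True)
class FrapResult:
    """Recovery fraction after an interior bleach and the open/sealed verdict."""

    bleach_time_min: float
    i_prebleach: float
    i_postbleach: float
    i_end: float
    recovery_fraction: float
    cutoff: float
    recovered: bool


def frap_analysis(
    series: FluxSeries,
    bleach_time_min: float,
    horizon_min: float | None = None,
    cutoff: float = 0.2,
) -> FrapResult:
    """Recovery fraction (I_end - I_post)/(I_pre - I_post) of the lumen signal.

    ``I_pre`` is the last interior mean before the bleach, ``I_post`` the
    first one at/after it, and ``I_end`` the last one within the horizon
    (default: end of series).  Channels are scored open (``recovered``) when
    the fraction exceeds ``cutoff``.  A bleach drop of less than 10% of the
    pre-bleach level raises an error.
    """
    t, iin = series.times_min, series.i_in
    pre_mask = t < bleach_time_min
    post_mask = t >= bleach_time_min
    if not pre_mask.any() or post_mask.sum() < 3:
        raise ValueError("need at least one pre-bleach and three post-bleach points")
    i_pre = float(iin[pre_mask][-1])
    i_post = float(iin[post_mask][0])
    if i_pre <= 0 or (i_pre - i_post) / i_pre < 0.10:
        raise ValueError("no detectable bleach event (drop < 10% of pre-bleach level)")
    horizon = horizon_min if horizon_min is not None else float(t[-1] - bleach_time_min)
    end_mask = post_mask & (t <= bleach_time_min + horizon)
    if not end_mask.any():
        raise ValueError("horizon excludes all post-bleach points")
    i_end = float(iin[end_mask][-1])
    fraction = (i_end - i_post) / (i_pre - i_post)
    if not -0.5 <= fraction <= 1.5:
        raise ValueError(f"recovery fraction {fraction:.2f} outside the sanity band [-0.5, 1.5]")
    return FrapResult(
        bleach_time_min=float(bleach_time_min),
        i_prebleach=i_pre,
        i_postbleach=i_post,
        i_end=i_end,
        recovery_fraction=float(fraction),
        cutoff=cutoff,
        recovered=bool(fraction > cutoff),
    )


# ---------------------------------------------------------------------------
# molecular-weight cut-off


@dataclass(frozen=True)
class CutoffSummary:
    """Per-probe relative import summary across a molecular-weight ladder."""

    table: pd.DataFrame  # columns: mw_kda, mean, sem, n
    crossing_pair_kda: tuple[float, float] | None

    @property
    def crossed(self) -> bool:
        return self.crossing_pair_kda is not None


def cutoff_summary(per_probe: Mapping[float, Sequence[float]], level: float = 0.5) -> CutoffSummary:
    """Mean +/- s.e.m. relative import per probe and the cut-off bracket.

    Probes are sorted by molecular weight; the crossing pair is the first
    adjacent (MW_low, MW_high) for which the mean import level reaches
    ``level`` (the partial-permeability midpoint) at MW_high.  ``None`` when
    no probe reaches it.
    """
    if len(per_probe) < 2:
        raise ValueError("cutoff summary needs at least two probes")
    rows = []
    for mw in sorted(per_probe):
        vals = np.asarray(per_probe[mw], dtype=float)
        if vals.size == 0:
            raise ValueError(f"probe {mw} kDa has no measurements")
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append({"mw_kda": float(mw), "mean": float(vals.mean()), "sem": sem, "n": int(vals.size)})
    table = pd.DataFrame(rows)
    crossing = None
    means = table["mean"].to_numpy()
    mws = table["mw_kda"].to_numpy()
    for j in range(1, len(table)):
        if means[j - 1] < level <= means[j]:
            crossing = (float(mws[j - 1]), float(mws[j]))
            break
    if crossing is None and means[0] >= level:
        crossing = (float(mws[0]), float(mws[0]))
    return CutoffSummary(table=table, crossing_pair_kda=crossing)


# ---------------------------------------------------------------------------
# FRET proximity ratio


@dataclass(frozen=True)
class ProximityRatio:
    """Acceptor share of summed donor+acceptor emission for one state."""

    state: str
    donor_intensity: float
    acceptor_intensity: float

    @property
    def ratio(self) -> float:
        return self.acceptor_intensity / (self.donor_intensity + self.acceptor_intensity)


def fret_proximity(
    spectra: pd.DataFrame,
    donor_band_nm: tuple[float, float] = (560.0, 580.0),
    acceptor_band_nm: tuple[float, float] = (660.0, 680.0),
) -> dict[str, ProximityRatio]:
    """Per-state proximity ratios from ensemble emission spectra.

    ``spectra`` is tidy with columns ``wavelength_nm``, ``intensity``,
    ``state``.  Band intensities are trapezoid integrals over the donor and
    acceptor windows; an empty window raises an error.
    """
    required = {"wavelength_nm", "intensity", "state"}
    if not required.issubset(spectra.columns):
        raise ValueError(f"spectra must have columns {sorted(required)}")
    out: dict[str, ProximityRatio] = {}
    for state, grp in spectra.groupby("state"):
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        inten = grp["intensity"].to_numpy(dtype=float)
        bands = []
        for lo, hi in (donor_band_nm, acceptor_band_nm):
            mask = (wl >= lo) & (wl <= hi)
            if mask.sum() < 2:
                raise ValueError(f"state {state!r}: no spectral coverage of band {lo}-{hi} nm")
            bands.append(float(np.trapezoid(inten[mask], wl[mask])))
        out[str(state)] = ProximityRatio(state=str(state), donor_intensity=bands[0], acceptor_intensity=bands[1])
    return out


def fret_ordering_flags(
    ratios: Mapping[str, ProximityRatio],
    elongated: str = "e-DR",
    compact: Sequence[str] = ("s-DR", "R-s-DR"),
) -> dict[str, bool]:
    """Check the expected ordering: the elongated (close-dye) state has the
    highest proximity ratio.  Returns ``{state: ratio(elongated) > ratio(state)}``."""
    if elongated not in ratios:
        raise ValueError(f"missing state {elongated!r}")
    r_e = ratios[elongated].ratio
    flags = {}
    for state in compact:
        if state not in ratios:
            raise ValueError(f"missing state {state!r}")
        flags[state] = bool(r_e > ratios[state].ratio)
    return flags
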