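"""One-component 2D diffusion FCS fitting, waist calibration and surface density.

For a fluorescent species diffusing in a membrane plane probed by a 2D
Gaussian detection area of waist radius ``r0``, the normalized intensity
autocorrelation is

    G(tau) = (1/N) * 1 / (1 + tau/tau_D),        tau_D = r0**2 / (4 D)

where ``N`` is the mean particle number in the detection area and ``tau_D``
the diffusion time.  Fitting ``(N, tau_D)`` to a measured curve, calibrating
``r0`` with a free dye of known diffusion coefficient, and converting to a
surface density ``sigma = N / (pi r0**2)`` and coverage ``phi = sigma L W``
(raft footprint L x W) are the three operations of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FcsCurve",
    "FcsFit",
    "WaistCalibration",
    "DensityResult",
    "FcsFitError",
    "g_2d",
    "fit_fcs_2d",
    "calibrate_waist",
    "surface_density",
]

#: Default raft footprint for surface coverage, nm (near-square conformation).
DEFAULT_RAFT_L_NM = 70.0
DEFAULT_RAFT_W_NM = 55.0


class FcsFitError(RuntimeError):
    """Raised when the autocorrelation fit cannot be performed or fails."""


def g_2d(tau: np.ndarray | float, n: float, tau_d: float) -> np.ndarray | float:
    """The one-component 2D diffusion autocorrelation model."""
    return (1.0 / n) / (1.0 + np.asarray(tau, dtype=float) / tau_d)


@dataclass(frozen=True)
class FcsCurve:
    """Lag–autocorrelation pairs, optionally with per-point weights.

    ``lags`` are in seconds, strictly increasing and positive; ``weights``
    multiply the fit residuals (e.g. inverse per-point standard errors).
    """

    lags: np.ndarray
    g: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if lags.ndim != 1 or lags.shape != g.shape:
            raise ValueError("lags and G must be 1D arrays of equal length")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != lags.shape or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per lag")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class FcsFit:
    """Fitted (N, tau_D) with covariance; model identities G(0)=1/N, G(tau_D)=1/(2N)."""

    n: float
    tau_d: float
    cov: np.ndarray  # 2x2 covariance of (N, tau_D)

    @property
    def n_stderr(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def tau_d_stderr(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def model(self, tau: np.ndarray | float) -> np.ndarray | float:
        return g_2d(tau, self.n, self.tau_d)

    def diffusion_coefficient(self, r0_nm: float) -> float:
        """D in um^2/s from a known waist radius via tau_D = r0^2/(4D)."""
        return (r0_nm / 1000.0) ** 2 / (4.0 * self.tau_d)


@dataclass(frozen=True)
class WaistCalibration:
    """Detection-area waist from a dye of known diffusion coefficient."""

    r0_nm: float
    r0_stderr_nm: float
    fit: FcsFit


@dataclass(frozen=True)
class DensityResult:
    """Surface density sigma (um^-2) and coverage phi = sigma * L * W."""

    sigma_per_um2: float
    phi: float
    n: float
    r0_nm: float
    length_nm: float
    width_nm: float


def _validate_for_fit(curve: FcsCurve) -> None:
    if curve.lags.size < 8:
        raise FcsFitError("need at least 8 points to fit the 2D diffusion model")
    if curve.lags[-1] / curve.lags[0] < 100.0:
        raise FcsFitError("lags must span at least two decades for a stable fit")
    if np.ptp(curve.g) == 0:
        raise FcsFitError("curve shows no decay (all G values equal)")


def fit_fcs_2d(curve: FcsCurve, init: tuple[float, float] | None = None) -> FcsFit:
    """Weighted least-squares fit of G(tau) = (1/N)/(1 + tau/tau_D).

    Parameters are log-parameterized internally, which keeps N and tau_D
    strictly positive without active bounds.  When ``init`` is omitted, N is
    seeded from the smallest-lag amplitude and tau_D from the half-amplitude
    lag.

    Raises
    ------
    FcsFitError
        For degenerate curves (no decay, too few points, < 2 decades of lag)
        or a non-converged optimizer.
    """
    _validate_for_fit(curve)
    g0 = float(curve.g[0])
    if init is None:
        n0 = 1.0 / g0 if g0 > 0 else 1.0
        half_idx = int(np.argmin(np.abs(curve.g - g0 / 2.0)))
        tau0 = float(curve.lags[half_idx])
        init = (max(n0, 1e-6), max(tau0, curve.lags[0]))
    if init[0] <= 0 or init[1] <= 0:
        raise FcsFitError("initial N and tau_D must be positive")
    w = curve.weights if curve.weights is not None else np.ones_like(curve.lags)

    def residuals(p: np.ndarray) -> np.ndarray:
        n, tau_d = np.exp(p)
        return w * (g_2d(curve.lags, n, tau_d) - curve.g)

    result = least_squares(residuals, x0=np.log(init), method="lm", xtol=1e-14, ftol=1e-14)
    if not result.success:
        raise FcsFitError(f"FCS fit did not converge: {result.message}")
    n_fit, tau_fit = np.exp(result.x)

    # covariance in log space via the Gauss-Newton approximation, then the
    # delta method back to (N, tau_D)
    dof = max(curve.lags.size - 2, 1)
    s2 = 2.0 * result.cost / dof
    jtj = result.jac.T @ result.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - near-singular fit
        raise FcsFitError("singular Jacobian; parameters not identifiable") from exc
    scale = np.diag([n_fit, tau_fit])
    cov = scale @ cov_log @ scale
    return FcsFit(n=float(n_fit), tau_d=float(tau_fit), cov=cov)


def calibrate_waist(curve: FcsCurve, d_known_um2_s: float) -> WaistCalibration:
    """Waist radius r0 = sqrt(4 D tau_D) from a calibration curve.

    ``d_known_um2_s`` is the dye's diffusion coefficient in um^2/s (already
    corrected to the working temperature); the fitted tau_D uncertainty is
    propagated to r0.  Returns r0 in nm.
    """
    if d_known_um2_s <= 0:
        raise ValueError("the calibration diffusion coefficient must be positive")
    fit = fit_fcs_2d(curve)
    r0_um = float(np.sqrt(4.0 * d_known_um2_s * fit.tau_d))
    r0_stderr_um = r0_um * fit.tau_d_stderr / (2.0 * fit.tau_d)
    return WaistCalibration(r0_nm=r0_um * 1000.0, r0_stderr_nm=r0_stderr_um * 1000.0, fit=fit)


def surface_density(
    n: float,
    r0_nm: float,
    length_nm: float = DEFAULT_RAFT_L_NM,
    width_nm: float = DEFAULT_RAFT_W_NM,
) -> DensityResult:
    """Particle surface density and coverage from the fitted particle number.

    sigma = N / (pi r0^2) in particles per um^2; phi = sigma * L * W with the
    raft footprint in nm.  phi > 1 is unphysical for a monolayer and raises a
    warning.
    """
    if n <= 0 or r0_nm <= 0 or length_nm <= 0 or width_nm <= 0:
        raise ValueError("all inputs to surface_density must be positive")
    r0_um = r0_nm / 1000.0
    sigma = n / (np.pi * r0_um**2)
    phi = sigma * (length_nm / 1000.0) * (width_nm / 1000.0)
    if phi > 1.0:
        warnings.warn(f"surface coverage phi = {phi:.3f} exceeds 1; check N or r0", stacklevel=2)
    return DensityResult(
        sigma_per_um2=float(sigma),
        phi=float(phi),
        n=float(n),
        r0_nm=float(r0_nm),
        length_nm=float(length_nm),
        width_nm=float(width_nm),
    )
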