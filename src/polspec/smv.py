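"""Spectral modulation vectors (SMVs) and instrument-response mapping.

An SMV generalises the spectral phasor: given N orthogonal spectral
modulation functions P_k(nu), the k-th component of the (normalised) SMV of a
spectrum I(nu) is

    V_k = integral(I * P_k dnu) / integral(I dnu).

Mixtures combine linearly — the SMV of a sum of spectra is the power-weighted
mean of the component SMVs — which is what makes gating and reference-based
unmixing work in SMV space. The mosaic-camera configuration realises the
function pair {cos(Lambda nu), sin^2(Lambda nu)}; a monochromatic sweep of
its SMV traces the parabola V2 = 1 - V1^2 (the "rainbow response curve").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.constants import c as SPEED_OF_LIGHT

from .optics import (
    ChannelImages,
    RawMosaicFrame,
    demosaic,
    modulation_phase,
)
from .spectra import SpectralGrid, Spectrum

__all__ = [
    "ModulationSet",
    "SMVImage",
    "ResponseCurve",
    "RetardanceFitResult",
    "compute_smv",
    "check_orthogonality",
    "smv_from_polarsens",
    "smv_from_four_detector",
    "theoretical_irf",
    "measure_irf",
    "fit_retardance",
]

_FAMILIES = ("cos_harmonics", "polarsens_pair", "phasor_pair")


@dataclass(frozen=True)
class ModulationSet:
    """A named family of N spectral modulation functions with base phase
    Lambda*nu = 2*pi*lambda0/lambda.

    Families: ``cos_harmonics`` -> cos(k * Lambda nu), k = 1..N;
    ``polarsens_pair`` -> (cos(Lambda nu), sin^2(Lambda nu));
    ``phasor_pair`` -> (cos(Lambda nu), sin(Lambda nu)).
    """

    family: str = "polarsens_pair"
    retardance_nm: float = 335.0
    n: int = 2

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.retardance_nm <= 0:
            raise ValueError("retardance must be positive")
        if self.family in ("polarsens_pair", "phasor_pair") and self.n != 2:
            raise ValueError(f"{self.family} has exactly 2 functions")
        if self.n < 1:
            raise ValueError("need at least one modulation function")

    @property
    def base_frequency(self) -> float:
        """Lambda = 2*pi*lambda0/c in seconds (phase per unit optical frequency)."""
        return 2.0 * np.pi * self.retardance_nm * 1e-9 / SPEED_OF_LIGHT

    @property
    def period_hz(self) -> float:
        """Full period of the base modulation in optical frequency."""
        return 2.0 * np.pi / self.base_frequency

    def evaluate_phase(self, delta: np.ndarray) -> np.ndarray:
        """(N, ...) function values at base phase delta = Lambda*nu."""
        delta = np.asarray(delta, dtype=float)
        if self.family == "cos_harmonics":
            ks = np.arange(1, self.n + 1).reshape((-1,) + (1,) * delta.ndim)
            return np.cos(ks * delta)
        if self.family == "polarsens_pair":
            return np.stack([np.cos(delta), np.sin(delta) ** 2])
        return np.stack([np.cos(delta), np.sin(delta)])

    def evaluate_frequency(self, nu_hz: np.ndarray) -> np.ndarray:
        return self.evaluate_phase(self.base_frequency * np.asarray(nu_hz, dtype=float))

    def evaluate_wavelength(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        return self.evaluate_phase(modulation_phase(self.retardance_nm, wavelengths_nm))


@dataclass
class SMVImage:
    """Per-pixel SMV plus total intensity and validity mask.

    Components are dimensionless and bounded by [-1, 1] for any non-negative
    spectrum (each modulation function is bounded by [-1, 1]). Pixels whose
    total intensity falls below the validity threshold are masked rather than
    clamped: the SMV ratio is undefined at zero power.
    """

    v: np.ndarray  # (H, W, N)
    total_intensity: np.ndarray  # (H, W)
    valid: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        if self.v.ndim != 3:
            raise ValueError("v must be (H, W, N)")
        if self.total_intensity.shape != self.v.shape[:2]:
            raise ValueError("total_intensity shape mismatch")
        if self.valid.shape != self.v.shape[:2]:
            raise ValueError("valid mask shape mismatch")

    @property
    def n_components(self) -> int:
        return self.v.shape[2]

    def valid_points(self) -> np.ndarray:
        """(M, N) SMVs of the valid pixels."""
        return self.v[self.valid]

    def mean_smv(self) -> np.ndarray:
        pts = self.valid_points()
        if pts.size == 0:
            raise ValueError("no valid pixels")
        return pts.mean(axis=0)


@dataclass
class ResponseCurve:
    """Instrument response: SMV as a function of narrowband centre wavelength."""

    wavelengths_nm: np.ndarray
    smv: np.ndarray  # (M, N)
    retardance_nm: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.smv = np.atleast_2d(np.asarray(self.smv, dtype=float))
        if self.smv.shape[0] != self.wavelengths_nm.size:
            raise ValueError("one SMV per wavelength required")

    def parabola_residuals(self) -> np.ndarray:
        """V2 - (1 - V1^2): zero on the ideal mosaic-pair response curve."""
        return self.smv[:, 1] - (1.0 - self.smv[:, 0] ** 2)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"V{k + 1}": self.smv[:, k] for k in range(self.smv.shape[1])}
        return pd.DataFrame({"wavelength_nm": self.wavelengths_nm, **cols})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, retardance_nm: float | None = None) -> "ResponseCurve":
        vcols = [c for c in df.columns if c.startswith("V")]
        return cls(df["wavelength_nm"].to_numpy(), df[vcols].to_numpy(), retardance_nm)


# ---------------------------------------------------------------------------
# SMV computation


def compute_smv(spectrum: Spectrum, mods: ModulationSet) -> np.ndarray:
    """Normalised projection of a spectrum onto the modulation functions.

    The frequency-domain integrals are evaluated by the substitution
    nu = c/lambda onto the wavelength grid (the Jacobian cancels between
    numerator and denominator), using trapezoidal quadrature.
    """
    w = spectrum.grid.trapezoid_weights * spectrum.intensity
    power = w.sum()
    if power <= 0:
        raise ValueError("SMV undefined for a zero-power spectrum")
    p = mods.evaluate_wavelength(spectrum.grid.wavelengths_nm)  # (N, L)
    return p @ w / power


def check_orthogonality(
    mods: ModulationSet,
    window_hz: tuple[float, float] | None = None,
    n_periods: int = 1,
) -> tuple[np.ndarray, bool]:
    """Window-mean pairwise inner products of the modulation functions.

    Entry (l, m) is ``mean over the window of P_l(nu) * P_m(nu)`` — the
    frequency integral divided by the window width, so the numbers are O(1)
    regardless of the (huge) Hz scale. Off-diagonal entries vanish when the
    window spans an integer number of base periods 2*pi/Lambda. Returns
    ``(matrix, exact_window)``; for a non-integer-period window the matrix is
    still returned with ``exact_window=False`` (orthogonality then only
    approximate — the instrument's finite band never covers exact periods).
    Integration runs in base-phase units with adaptive quadrature.
    """
    if window_hz is None:
        nu0 = SPEED_OF_LIGHT / 550e-9
        window_hz = (nu0, nu0 + n_periods * mods.period_hz)
    lo, hi = window_hz
    if hi <= lo:
        raise ValueError("empty frequency window")
    periods = (hi - lo) / mods.period_hz
    exact = bool(abs(periods - round(periods)) < 1e-9)

    from scipy.integrate import quad

    # substitute x = Lambda*nu: mean = (1/(x_hi-x_lo)) * int P_l(x) P_m(x) dx
    x_lo, x_hi = mods.base_frequency * lo, mods.base_frequency * hi
    n = mods.n
    mat = np.zeros((n, n))
    for l in range(n):
        for m in range(l, n):
            def integrand(x, l=l, m=m):
                vals = mods.evaluate_phase(np.array([x]))
                return vals[l, 0] * vals[m, 0]

            val, _ = quad(integrand, x_lo, x_hi, limit=200)
            mat[l, m] = mat[m, l] = val / (x_hi - x_lo)
    return mat, exact


def _ratio_image(num: np.ndarray, den: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=valid & (den != 0))
    return out


def _validity(total: np.ndarray, abs_threshold: float, rel_threshold: float) -> np.ndarray:
    thresh = max(abs_threshold, rel_threshold * float(total.max(initial=0.0)))
    return total > thresh


def smv_from_polarsens(
    channels: ChannelImages,
    abs_threshold: float = 0.0,
    rel_threshold: float = 1e-3,
) -> SMVImage:
    """SMV image from the mosaic-camera channel quartet.

    V1 = (I0 - I90)/(I0 + I90) and V2 = (I45 - I135)/(I45 + I135) per pixel;
    the total-intensity image is I0 + I90. Pixels below the validity
    threshold, or with a vanishing ratio denominator (possible under noise),
    are masked — never propagated as non-finite values.
    """
    ch = {k: np.atleast_2d(v) for k, v in channels.channels.items()}
    if set(ch) != {"I0", "I45", "I90", "I135"}:
        raise ValueError("polarsens channel quartet required")
    total = ch["I0"] + ch["I90"]
    den2 = ch["I45"] + ch["I135"]
    valid = _validity(total, abs_threshold, rel_threshold) & (den2 > 0)
    v1 = _ratio_image(ch["I0"] - ch["I90"], total, valid)
    v2 = _ratio_image(ch["I45"] - ch["I135"], den2, valid)
    return SMVImage(v=np.stack([v1, v2], axis=-1), total_intensity=total, valid=valid)


def smv_from_four_detector(
    channels: ChannelImages,
    abs_threshold: float = 0.0,
    rel_threshold: float = 1e-3,
) -> SMVImage:
    """SMV image from the four-detector quartet.

    V1 = (I0_0 - I0_90)/(I0_0 + I0_90) from the lambda0 arm and
    V2 = (I90_90 - I90_0)/(I90_90 + I90_0) from the 2*lambda0 arm: the
    cos(Lambda nu) / cos(2 Lambda nu) pair, one component per polarisation
    arm. A pixel with a dead arm is masked.
    """
    ch = {k: np.atleast_2d(v) for k, v in channels.channels.items()}
    if set(ch) != {"I0_0", "I0_90", "I90_0", "I90_90"}:
        raise ValueError("four-detector channel quartet required")
    den1 = ch["I0_0"] + ch["I0_90"]
    den2 = ch["I90_90"] + ch["I90_0"]
    total = den1 + den2
    valid = _validity(total, abs_threshold, rel_threshold) & (den1 > 0) & (den2 > 0)
    v1 = _ratio_image(ch["I0_0"] - ch["I0_90"], den1, valid)
    v2 = _ratio_image(ch["I90_90"] - ch["I90_0"], den2, valid)
    return SMVImage(v=np.stack([v1, v2], axis=-1), total_intensity=total, valid=valid)


# ---------------------------------------------------------------------------
# Instrument response


def theoretical_irf(mods: ModulationSet, wavelengths_nm: np.ndarray) -> ResponseCurve:
    """Monochromatic-limit response curve: P_k evaluated at each wavelength.

    For the mosaic pair the points lie on V2 = 1 - V1^2; for the first two
    cosine harmonics on the Chebyshev relation V2 = 2*V1^2 - 1.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    smv = mods.evaluate_wavelength(wavelengths_nm).T
    return ResponseCurve(wavelengths_nm, smv, retardance_nm=mods.retardance_nm)


def measure_irf(
    sweep_frames: list[tuple[float, ChannelImages | RawMosaicFrame]],
    abs_threshold: float = 0.0,
    rel_threshold: float = 1e-3,
) -> ResponseCurve:
    """Response curve from a narrowband wavelength sweep.

    Each frame (raw mosaic or pre-split channels) is reduced to the mean SMV
    over its valid pixels; the curve is stored at sweep resolution with no
    smoothing. Mosaic frames are demosaicked by exact superpixel extraction.
    """
    if not sweep_frames:
        raise ValueError("empty sweep")
    lams, points = [], []
    retardance = None
    for lam, frame in sweep_frames:
        if isinstance(frame, RawMosaicFrame):
            frame = demosaic(frame)
        retardance = frame.config.retardance_nm
        smv = smv_from_polarsens(frame, abs_threshold, rel_threshold)
        lams.append(lam)
        points.append(smv.mean_smv())
    return ResponseCurve(np.array(lams), np.array(points), retardance_nm=retardance)


@dataclass
class RetardanceFitResult:
    """Least-squares calibration of the retardance from a response curve."""

    retardance_nm: float
    stderr_nm: float
    residual_norm: float
    n_points: int

    def summary(self) -> str:
        return (
            "Retardance calibration (V1 = cos(2*pi*lambda0/lambda))\n"
            f"  points:          {self.n_points}\n"
            f"  retardance (nm): {self.retardance_nm:.4f} +/- {self.stderr_nm:.4f}\n"
            f"  residual norm:   {self.residual_norm:.3e}\n"
        )


def fit_retardance(curve: ResponseCurve, search_nm: tuple[float, float] = (50.0, 2000.0)) -> RetardanceFitResult:
    """Estimate the retardance lambda0 from the V1 branch of a sweep.

    Fits V1(lambda) = cos(2*pi*lambda0/lambda) by least squares. The cosine
    is oscillatory in lambda0, so a coarse grid scan over ``search_nm`` seeds
    a local refinement. The standard error comes from the Gauss-Newton
    covariance at the optimum.
    """
    lam = curve.wavelengths_nm
    v1 = curve.smv[:, 0]
    if np.unique(lam).size < 5:
        raise ValueError("need at least 5 distinct sweep wavelengths")

    def residuals(p):
        return np.cos(2.0 * np.pi * p[0] / lam) - v1

    grid = np.arange(search_nm[0], search_nm[1], 1.0)
    costs = [0.5 * np.sum(residuals([g]) ** 2) for g in grid]
    x0 = grid[int(np.argmin(costs))]
    sol = optimize.least_squares(residuals, x0=[x0], method="lm")
    dof = max(lam.size - 1, 1)
    jac = sol.jac
    s2 = 2.0 * sol.cost / dof
    cov = s2 * np.linalg.inv(jac.T @ jac)
    return RetardanceFitResult(
        retardance_nm=float(sol.x[0]),
        stderr_nm=float(np.sqrt(cov[0, 0])),
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points=int(lam.size),
    )
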