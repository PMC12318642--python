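"""Spectral data types and seeded synthetic scene generators.

Wavelength is the native sampling axis (what instruments provide); all
modulation-function integrals are defined in optical frequency ``nu = c / lambda``
and evaluated by exact change of variables onto the wavelength grid, so the
frequency-domain ratios of the spectral-modulation-vector definition are
computed without an explicit Jacobian (it cancels under the substitution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT  # m/s

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "HyperspectralScene",
    "default_grid",
    "make_narrowband",
    "make_gaussian_emitter",
    "make_frequency_gaussian",
    "make_flat_spectrum",
    "make_two_fluorophore_scene",
    "make_absorption_scene",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength sample points in nanometres.

    The implied optical frequencies are ``nu = c / lambda``. Conversion both
    ways is an exact involution because it is the same reciprocal map.
    """

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        if lam.ndim != 1 or lam.size < 8:
            raise ValueError("grid needs at least 8 one-dimensional samples")
        if not np.all(lam > 0):
            raise ValueError("wavelengths must be positive")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n(self) -> int:
        return self.wavelengths_nm.size

    @property
    def frequencies_hz(self) -> np.ndarray:
        return SPEED_OF_LIGHT / (self.wavelengths_nm * 1e-9)

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    @property
    def trapezoid_weights(self) -> np.ndarray:
        """Quadrature weights such that ``w @ f == trapezoid(f, wavelengths)``."""
        lam = self.wavelengths_nm
        w = np.zeros_like(lam)
        d = np.diff(lam)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.wavelengths_nm, other.wavelengths_nm
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.wavelengths_nm.tobytes(),))


def default_grid(start_nm: float = 450.0, stop_nm: float = 650.0, step_nm: float = 0.5) -> SpectralGrid:
    """The instrument's demonstrated visible band, 450-650 nm at 0.5 nm."""
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    return SpectralGrid(np.linspace(start_nm, stop_nm, n))


@dataclass(frozen=True)
class Spectrum:
    """Non-negative spectral photon flux per wavelength sample (a.u. / nm)."""

    grid: SpectralGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", inten)
        if inten.shape != self.grid.wavelengths_nm.shape:
            raise ValueError("intensity shape does not match grid")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensity must be finite")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def total_power(self) -> float:
        """Integrated flux, trapezoidal over wavelength."""
        return float(self.grid.trapezoid_weights @ self.intensity)

    def normalised(self) -> "Spectrum":
        p = self.total_power
        if p <= 0:
            raise ValueError("cannot normalise a zero-power spectrum")
        return Spectrum(self.grid, self.intensity / p)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.intensity * factor)


@dataclass
class HyperspectralScene:
    """Per-pixel spectra: a (height, width, n_wavelengths) cube on one grid.

    ``labels`` (integer class map) and ``abundances`` (per-pixel photon
    fractions of each component, summing to 1) hold the generator's ground
    truth when the scene is synthetic.
    """

    grid: SpectralGrid
    cube: np.ndarray
    labels: np.ndarray | None = None
    abundances: np.ndarray | None = None
    component_names: list[str] | None = None
    white_region: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3 or self.cube.shape[2] != self.grid.n:
            raise ValueError("cube must be (height, width, n_wavelengths)")
        if np.any(self.cube < 0):
            raise ValueError("cube must be non-negative")
        h, w = self.cube.shape[:2]
        if self.labels is not None and self.labels.shape != (h, w):
            raise ValueError("label map shape mismatch")
        if self.abundances is not None:
            if self.abundances.shape[:2] != (h, w):
                raise ValueError("abundance map shape mismatch")
            if np.any(self.abundances < -1e-12):
                raise ValueError("abundances must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def pixel_spectrum(self, y: int, x: int) -> Spectrum:
        return Spectrum(self.grid, self.cube[y, x])

    def total_power_image(self) -> np.ndarray:
        return self.cube @ self.grid.trapezoid_weights


# ---------------------------------------------------------------------------
# Sources


def make_narrowband(center_nm: float, fwhm_nm: float, grid: SpectralGrid) -> Spectrum:
    """Narrowband (tuneable-source) line: Gaussian profile, unit total power.

    Emulates a supercontinuum + spectral-selection unit delivering < 3 nm
    bandwidth across the band. An ``fwhm_nm`` at or below the grid step
    degenerates to a single-sample, delta-like line.
    """
    lo, hi = grid.span_nm
    if not (lo <= center_nm <= hi):
        raise ValueError(
            f"centre wavelength {center_nm} nm outside grid span {lo}-{hi} nm"
        )
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    lam = grid.wavelengths_nm
    step = np.min(np.diff(lam))
    if fwhm_nm <= step:
        inten = np.zeros_like(lam)
        inten[np.argmin(np.abs(lam - center_nm))] = 1.0
        # unit power under trapezoidal quadrature
        s = Spectrum(grid, inten)
        return s.normalised()
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    inten = np.exp(-0.5 * ((lam - center_nm) / sigma) ** 2)
    return Spectrum(grid, inten).normalised()


def make_gaussian_emitter(mean_nm: float, sigma_nm: float, grid: SpectralGrid) -> Spectrum:
    """Smooth Gaussian emission band (fluorophore stand-in), unit power."""
    if sigma_nm <= 0:
        raise ValueError("sigma must be positive")
    lam = grid.wavelengths_nm
    inten = np.exp(-0.5 * ((lam - mean_nm) / sigma_nm) ** 2)
    return Spectrum(grid, inten).normalised()


def make_frequency_gaussian(mean_hz: float, sigma_hz: float, grid: SpectralGrid) -> Spectrum:
    """Spectrum Gaussian in optical frequency, sampled per-wavelength.

    The per-wavelength density carries the c/lambda^2 Jacobian so that the
    frequency-domain profile is exactly Gaussian — the case with a closed-form
    modulation-vector answer via the Gaussian characteristic function.
    """
    if sigma_hz <= 0:
        raise ValueError("sigma must be positive")
    lam_m = grid.wavelengths_nm * 1e-9
    nu = SPEED_OF_LIGHT / lam_m
    density = np.exp(-0.5 * ((nu - mean_hz) / sigma_hz) ** 2) * SPEED_OF_LIGHT / lam_m**2
    return Spectrum(grid, density).normalised()


def make_flat_spectrum(grid: SpectralGrid, power: float = 1.0) -> Spectrum:
    """Spectrally flat (white) illuminant with the given total power."""
    inten = np.ones(grid.n)
    return Spectrum(grid, inten).normalised().scaled(power)


# ---------------------------------------------------------------------------
# Scenes

#: Default fluorophore stand-ins: two emitters separable in SMV space plus a
#: broad dim background (mounting-medium autofluorescence stand-in).
FLUOR_A = (540.0, 15.0)
FLUOR_B = (600.0, 15.0)
BACKGROUND = (500.0, 40.0)
BACKGROUND_FRACTION = 0.05  # of the blob photon budget


def _place_blobs(
    rng: np.random.Generator,
    height: int,
    width: int,
    n_blobs: int,
    occupied: np.ndarray,
    r_range: tuple[float, float],
) -> np.ndarray:
    """Disk/ellipse masks, rejection-sampled to avoid overlap where possible."""
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_blobs and attempts < 200 * max(n_blobs, 1):
        attempts += 1
        r = rng.uniform(*r_range)
        cy = rng.uniform(r, height - r)
        cx = rng.uniform(r, width - r)
        ar = rng.uniform(0.7, 1.3)  # mild ellipticity
        blob = ((yy - cy) / r) ** 2 + ((xx - cx) / (r * ar)) ** 2 <= 1.0
        if np.any(blob & occupied):
            continue
        mask |= blob
        occupied |= blob
        placed += 1
    if placed < n_blobs:
        raise RuntimeError("could not place all blobs without overlap")
    return mask


def make_two_fluorophore_scene(
    seed: int,
    n_blobs_per_class: int = 5,
    photon_budget: float = 1e4,
    grid: SpectralGrid | None = None,
    height: int = 128,
    width: int = 128,
) -> HyperspectralScene:
    """Pollen-grain-style fluorescence scene: two emitter classes + background.

    Blobs of two spectrally distinct Gaussian emitters sit on a spatially
    uniform dim background. ``photon_budget`` is the expected photon count per
    blob pixel; the background carries ``BACKGROUND_FRACTION`` of that budget
    everywhere. Fully reproducible from the seed. With ``n_blobs_per_class=0``
    the scene is background only (valid).
    """
    if photon_budget <= 0:
        raise ValueError("photon budget must be positive")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    occupied = np.zeros((height, width), dtype=bool)
    m = min(height, width)  # blob radii scale with the field of view
    r_range = (max(2.0, 0.05 * m), max(3.0, 0.11 * m))
    mask_a = _place_blobs(rng, height, width, n_blobs_per_class, occupied, r_range)
    mask_b = _place_blobs(rng, height, width, n_blobs_per_class, occupied, r_range)

    spec_a = make_gaussian_emitter(*FLUOR_A, grid).intensity
    spec_b = make_gaussian_emitter(*FLUOR_B, grid).intensity
    spec_bg = make_gaussian_emitter(*BACKGROUND, grid).intensity

    bg_budget = BACKGROUND_FRACTION * photon_budget
    intensity = np.zeros((height, width, 3))  # photon budgets per component
    intensity[..., 2] = bg_budget
    intensity[mask_a, 0] = photon_budget
    intensity[mask_b, 1] = photon_budget

    cube = (
        intensity[..., 0:1] * spec_a
        + intensity[..., 1:2] * spec_b
        + intensity[..., 2:3] * spec_bg
    )

    labels = np.zeros((height, width), dtype=np.int32)
    labels[mask_a] = 1
    labels[mask_b] = 2

    totals = intensity.sum(axis=2, keepdims=True)
    abundances = intensity / totals

    return HyperspectralScene(
        grid=grid,
        cube=cube,
        labels=labels,
        abundances=abundances,
        component_names=["fluorophore_a", "fluorophore_b", "background"],
        meta={
            "seed": seed,
            "photon_budget": photon_budget,
            "n_blobs_per_class": n_blobs_per_class,
            "emitters": {"a": FLUOR_A, "b": FLUOR_B, "background": BACKGROUND},
            "background_fraction": BACKGROUND_FRACTION,
        },
    )


#: Synthetic chromophore absorption bands (peak-normalised Gaussians), chosen
#: to mimic transmitted-light histology staining with three dyes.
CHROMOPHORES = ((470.0, 35.0), (545.0, 30.0), (610.0, 30.0))


def make_absorption_scene(
    seed: int,
    grid: SpectralGrid | None = None,
    height: int = 96,
    width: int = 96,
    illuminant_power: float = 1e4,
    white_margin: int = 12,
) -> HyperspectralScene:
    """Transmitted-light scene: flat illuminant x Beer-Lambert attenuation.

    Three synthetic chromophores with spatially varying optical densities
    (smooth random blobs) absorb a flat white illuminant; a left-edge strip of
    width ``white_margin`` is unstained (illuminant only) and serves as the
    white-balance reference. Ground-truth OD maps are stored in ``meta``.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    lam = grid.wavelengths_nm

    absorb = np.stack(
        [np.exp(-0.5 * ((lam - c) / s) ** 2) for c, s in CHROMOPHORES]
    )  # (3, L), peak OD contribution 1

    # smooth random OD fields from low-frequency cosines, zeroed in the margin
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    od = np.zeros((height, width, 3))
    for k in range(3):
        f = np.zeros((height, width))
        for _ in range(4):
            ky, kx = rng.uniform(0.5, 2.5, size=2)
            ph_y, ph_x = rng.uniform(0, 2 * np.pi, size=2)
            f += np.cos(2 * np.pi * ky * yy / height + ph_y) * np.cos(
                2 * np.pi * kx * xx / width + ph_x
            )
        f = np.clip(f, 0, None)
        od[..., k] = 1.5 * f / max(f.max(), 1e-12)
    od[:, :white_margin, :] = 0.0

    illum = make_flat_spectrum(grid, illuminant_power)
    transmission = np.exp(-np.einsum("yxk,kl->yxl", od, absorb))
    cube = transmission * illum.intensity

    white = np.zeros((height, width), dtype=bool)
    white[:, :white_margin] = True

    return HyperspectralScene(
        grid=grid,
        cube=cube,
        component_names=[f"chromophore_{i}" for i in range(3)],
        white_region=white,
        meta={
            "seed": seed,
            "optical_density": od,
            "chromophores": CHROMOPHORES,
            "illuminant_power": illuminant_power,
        },
    )
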