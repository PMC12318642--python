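"""Physics forward model of the polarisation-based spectral modulator.

A birefringent retarder of retardance lambda0 between polarisers (a Lyot
interferometer) transmits cos^2(pi*lambda0/lambda) — a cosine in optical
frequency, T(nu) ∝ 1 + cos(Lambda*nu) with Lambda = 2*pi*lambda0/c. Two
single-shot readout configurations are modelled:

* ``polarsens_single_shot`` — one input polariser, two cascaded retarders
  (axes at 45 deg and 0 deg) and a polarisation-mosaic camera whose 2x2
  superpixels analyse at 0/45/90/135 deg, giving the channel quartet
  I0, I45, I90, I135 with cos(Lambda*nu) and cos(2*Lambda*nu) kernels.
* ``four_detector`` — a polarising beamsplitter feeds two parallel Lyot
  arms with retardances lambda0 and 2*lambda0; both outputs of each arm are
  detected, so the configuration is in principle lossless.

``jones_oracle_channels`` propagates the field through explicit 2x2 Jones
matrices per wavelength and is the independent brute-force check of the
closed-form channel integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import HyperspectralScene, SpectralGrid, Spectrum

__all__ = [
    "Retarder",
    "InstrumentConfig",
    "ChannelImages",
    "RawMosaicFrame",
    "POLARSENS_CHANNELS",
    "FOUR_DETECTOR_CHANNELS",
    "DEFAULT_RETARDANCE_NM",
    "lyot_transmission",
    "modulation_phase",
    "polarsens_kernels",
    "polarsens_channels",
    "four_detector_channels",
    "jones_oracle_channels",
    "render_scene",
    "mosaic_and_noise",
    "demosaic",
    "analyser_intensities",
    "superpixel_detection_efficiency",
]

#: Retardance of a half-wave plate cut for 670 nm: lambda0 = 670/2 nm.
DEFAULT_RETARDANCE_NM = 335.0

POLARSENS_CHANNELS = ("I0", "I45", "I90", "I135")
FOUR_DETECTOR_CHANNELS = ("I0_0", "I0_90", "I90_0", "I90_90")


@dataclass(frozen=True)
class Retarder:
    """Birefringent retarder: optical path difference delta_n * d, axis angle."""

    retardance_nm: float
    axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.retardance_nm <= 0:
            raise ValueError("retardance must be positive")

    def phase(self, wavelength_nm: np.ndarray | float) -> np.ndarray | float:
        """Retardation phase delta = 2*pi*lambda0/lambda = Lambda*nu."""
        return modulation_phase(self.retardance_nm, wavelength_nm)


def modulation_phase(retardance_nm: float, wavelength_nm: np.ndarray | float):
    """delta(lambda) = 2*pi*lambda0/lambda, the Lyot phase Lambda*nu."""
    return 2.0 * np.pi * retardance_nm / np.asarray(wavelength_nm, dtype=float)


def lyot_transmission(retardance_nm: float, wavelength_nm: np.ndarray | float):
    """Lyot filter transmission cos^2(pi * lambda0 / lambda), in [0, 1]."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if retardance_nm <= 0 or np.any(lam <= 0):
        raise ValueError("retardance and wavelength must be positive")
    t = np.cos(np.pi * retardance_nm / lam) ** 2
    return float(t) if np.isscalar(wavelength_nm) else t


@dataclass(frozen=True)
class InstrumentConfig:
    """Configuration of one single-shot acquisition geometry.

    ``extinction_ratio`` is the analyser contrast (aligned/crossed); infinity
    means ideal analysers. ``mosaic_layout`` is the 2x2 superpixel assignment
    of analyser angles, row-major.
    """

    config_kind: str = "polarsens_single_shot"
    retardance_nm: float = DEFAULT_RETARDANCE_NM
    extinction_ratio: float = math.inf
    mosaic_layout: tuple[tuple[int, int], tuple[int, int]] = ((90, 45), (135, 0))

    def __post_init__(self) -> None:
        if self.config_kind not in ("polarsens_single_shot", "four_detector"):
            raise ValueError(f"unknown config_kind {self.config_kind!r}")
        if self.retardance_nm <= 0:
            raise ValueError("retardance must be positive")
        if not self.extinction_ratio > 1:
            raise ValueError("extinction ratio must exceed 1")
        flat = tuple(a for row in self.mosaic_layout for a in row)
        if sorted(flat) != [0, 45, 90, 135]:
            raise ValueError("mosaic layout must be a permutation of 0/45/90/135")


@dataclass
class ChannelImages:
    """Polarisation-analysed intensities keyed by analyser label.

    Values may be scalars (single spectrum) or images; shapes must agree.
    """

    channels: dict[str, np.ndarray]
    config: InstrumentConfig

    def __post_init__(self) -> None:
        expected = (
            POLARSENS_CHANNELS
            if self.config.config_kind == "polarsens_single_shot"
            else FOUR_DETECTOR_CHANNELS
        )
        if set(self.channels) != set(expected):
            raise ValueError(f"channel keys must be {expected}")
        shapes = {np.shape(v) for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channel shapes disagree")
        for k, v in self.channels.items():
            arr = np.asarray(v, dtype=float)
            if np.any(arr < -1e-12):
                raise ValueError(f"negative intensity in channel {k}")
            self.channels[k] = arr

    def __getitem__(self, key: str) -> np.ndarray:
        return self.channels[key]

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def stack(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        order = order or tuple(sorted(self.channels))
        return np.stack([self.channels[k] for k in order])


@dataclass
class RawMosaicFrame:
    """Single sensor frame with the four channels interleaved in 2x2 superpixels."""

    frame: np.ndarray
    layout: tuple[tuple[int, int], tuple[int, int]]
    config: InstrumentConfig
    seed: int | None = None
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        if self.frame.ndim != 2 or self.frame.shape[0] % 2 or self.frame.shape[1] % 2:
            raise ValueError("mosaic frame must be 2-D with even dimensions")


# ---------------------------------------------------------------------------
# Channel models


def polarsens_kernels(retardance_nm: float, wavelengths_nm: np.ndarray) -> dict[str, np.ndarray]:
    """Spectral kernels of the four mosaic channels.

    I0, I90 carry (1 +- cos delta)/2; I45, I135 carry (3 - cos 2delta)/4 and
    (1 + cos 2delta)/4, where delta = 2*pi*lambda0/lambda.
    """
    d = modulation_phase(retardance_nm, wavelengths_nm)
    return {
        "I0": 0.5 * (1.0 + np.cos(d)),
        "I90": 0.5 * (1.0 - np.cos(d)),
        "I45": 0.25 * (3.0 - np.cos(2.0 * d)),
        "I135": 0.25 * (1.0 + np.cos(2.0 * d)),
    }


def polarsens_channels(spectrum: Spectrum, config: InstrumentConfig) -> ChannelImages:
    """Channel quartet of the mosaic-camera configuration for one spectrum.

    The input spectrum is the *polarised* flux entering the retarder pair
    (i.e. after the input polariser). Conservation: I0 + I90 = I45 + I135 =
    total power, to quadrature precision.
    """
    if config.config_kind != "polarsens_single_shot":
        raise ValueError("config is not polarsens_single_shot")
    w = spectrum.grid.trapezoid_weights * spectrum.intensity
    kernels = polarsens_kernels(config.retardance_nm, spectrum.grid.wavelengths_nm)
    channels = {k: float(w @ kern) for k, kern in kernels.items()}
    return ChannelImages(channels=channels, config=config)


def four_detector_channels(
    spectrum_0deg: Spectrum, spectrum_90deg: Spectrum, config: InstrumentConfig
) -> ChannelImages:
    """Channel quartet of the lossless four-detector configuration.

    The 0-deg polarisation arm passes a retarder of retardance lambda0
    (kernel cos delta); the 90-deg arm passes 2*lambda0 (kernel cos 2delta).
    Each complement pair sums to its arm's input power.
    """
    if config.config_kind != "four_detector":
        raise ValueError("config is not four_detector")
    if spectrum_0deg.grid != spectrum_90deg.grid:
        raise ValueError("arm spectra must share a grid")
    grid = spectrum_0deg.grid
    d = modulation_phase(config.retardance_nm, grid.wavelengths_nm)
    w = grid.trapezoid_weights
    i0 = w * spectrum_0deg.intensity
    i90 = w * spectrum_90deg.intensity
    channels = {
        "I0_0": float(i0 @ (0.5 * (1.0 + np.cos(d)))),
        "I0_90": float(i0 @ (0.5 * (1.0 - np.cos(d)))),
        "I90_0": float(i90 @ (0.5 * (1.0 - np.cos(2.0 * d)))),
        "I90_90": float(i90 @ (0.5 * (1.0 + np.cos(2.0 * d)))),
    }
    return ChannelImages(channels=channels, config=config)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _retarder_jones(theta_rad: float, delta: np.ndarray) -> np.ndarray:
    """(L, 2, 2) Jones matrices of a retarder, fast axis at theta, phase delta."""
    half = delta / 2.0
    core = np.zeros((delta.size, 2, 2), dtype=complex)
    core[:, 0, 0] = np.exp(-1j * half)
    core[:, 1, 1] = np.exp(1j * half)
    r = _rotation(theta_rad)
    return np.einsum("ij,ljk,km->lim", r, core, r.T)


def jones_oracle_channels(spectrum: Spectrum, config: InstrumentConfig) -> ChannelImages:
    """Brute-force Jones-calculus propagation through the optical train.

    Input polariser at 0 deg, then retarders with extraordinary axes at
    45 deg and 0 deg (both of retardance lambda0), then ideal analysers at
    0/45/90/135 deg, integrated over the spectrum. Agrees with
    ``polarsens_channels`` to numerical precision; kept deliberately
    matrix-based so the two routes share no algebra.
    """
    if config.config_kind != "polarsens_single_shot":
        raise ValueError("config is not polarsens_single_shot")
    grid = spectrum.grid
    delta = np.atleast_1d(modulation_phase(config.retardance_nm, grid.wavelengths_nm))
    j45 = _retarder_jones(np.pi / 4.0, delta)
    j0 = _retarder_jones(0.0, delta)
    e_in = np.array([1.0, 0.0], dtype=complex)  # after the input polariser
    e_out = np.einsum("lij,ljk,k->li", j0, j45, e_in)

    w = grid.trapezoid_weights * spectrum.intensity
    channels = {}
    for name, angle in zip(POLARSENS_CHANNELS, (0.0, 45.0, 90.0, 135.0)):
        a = np.deg2rad(angle)
        amp = e_out[:, 0] * np.cos(a) + e_out[:, 1] * np.sin(a)
        channels[name] = float(w @ np.abs(amp) ** 2)
    return ChannelImages(channels=channels, config=config)


def render_scene(
    scene: HyperspectralScene,
    config: InstrumentConfig,
    input_polarisation: str = "unpolarised",
) -> ChannelImages:
    """Noiseless per-pixel channel images of a scene.

    The input linear polariser transmits half of unpolarised light (the
    configuration's unavoidable 50% input loss) and all of light already
    polarised along its axis.
    """
    if config.config_kind != "polarsens_single_shot":
        raise ValueError("render_scene models the mosaic-camera configuration")
    factors = {"unpolarised": 0.5, "polarised_0deg": 1.0}
    if input_polarisation not in factors:
        raise ValueError(f"input_polarisation must be one of {sorted(factors)}")
    grid = scene.grid
    w = grid.trapezoid_weights
    kernels = polarsens_kernels(config.retardance_nm, grid.wavelengths_nm)
    factor = factors[input_polarisation]
    channels = {k: factor * (scene.cube @ (w * kern)) for k, kern in kernels.items()}
    return ChannelImages(channels=channels, config=config)


# ---------------------------------------------------------------------------
# Mosaic sensor

_CROSSED = {0: 90, 90: 0, 45: 135, 135: 45}
_ANGLE_KEY = {0: "I0", 45: "I45", 90: "I90", 135: "I135"}


def mosaic_and_noise(
    channels: ChannelImages,
    config: InstrumentConfig,
    photon_scale: float | None = None,
    read_noise_sd: float = 0.0,
    seed: int | None = None,
) -> RawMosaicFrame:
    """Interleave the four channels into one mosaic frame and add sensor noise.

    Each 2x2 superpixel samples each analyser channel at exactly one site, so
    the analyser mask passes half the sensor-incident light on average (the
    mean Malus factor over 0/45/90/135 deg is 1/2 for any polarisation state).
    A finite extinction ratio mixes each channel with its crossed partner,
    ``I_meas = (ER * I_par + I_cross) / (ER + 1)``. With ``photon_scale`` set,
    pixel values are Poisson draws of ``photon_scale * I`` (counts); Gaussian
    read noise of the given SD is then added. Noise requires a seed.
    """
    if config.config_kind != "polarsens_single_shot":
        raise ValueError("mosaic model applies to the mosaic-camera configuration")
    imgs = {k: np.atleast_2d(v) for k, v in channels.channels.items()}
    h, w = next(iter(imgs.values())).shape

    er = config.extinction_ratio
    if np.isfinite(er):
        mixed = {
            _ANGLE_KEY[a]: (er * imgs[_ANGLE_KEY[a]] + imgs[_ANGLE_KEY[_CROSSED[a]]])
            / (er + 1.0)
            for a in (0, 45, 90, 135)
        }
    else:
        mixed = imgs

    frame = np.zeros((2 * h, 2 * w))
    for dy, row in enumerate(config.mosaic_layout):
        for dx, angle in enumerate(row):
            frame[dy::2, dx::2] = mixed[_ANGLE_KEY[angle]]

    noise_meta: dict = {"photon_scale": photon_scale, "read_noise_sd": read_noise_sd}
    if photon_scale is not None or read_noise_sd > 0:
        if seed is None:
            raise ValueError("noisy mosaic simulation requires a seed")
        rng = np.random.default_rng(seed)
        if photon_scale is not None:
            if photon_scale <= 0:
                raise ValueError("photon_scale must be positive")
            frame = rng.poisson(photon_scale * frame).astype(float)
        if read_noise_sd > 0:
            frame = frame + rng.normal(0.0, read_noise_sd, size=frame.shape)
    return RawMosaicFrame(frame=frame, layout=config.mosaic_layout, config=config,
                          seed=seed, noise=noise_meta)


def demosaic(raw: RawMosaicFrame) -> ChannelImages:
    """Extract the four half-resolution sub-images from a mosaic frame.

    Superpixel extraction is exact (no interpolation): the inverse of
    ``mosaic_and_noise`` for noiseless, ideal-analyser frames.
    """
    if raw.layout is None:
        raise ValueError("mosaic layout metadata missing")
    channels = {}
    for dy, row in enumerate(raw.layout):
        for dx, angle in enumerate(row):
            channels[_ANGLE_KEY[angle]] = raw.frame[dy::2, dx::2]
    # values may dip below zero after read noise; clamp for the container
    channels = {k: np.clip(v, 0.0, None) for k, v in channels.items()}
    return ChannelImages(channels=channels, config=raw.config)


# ---------------------------------------------------------------------------
# Polarisation-state responses (mosaic efficiency analysis)


def analyser_intensities(stokes: np.ndarray, angles_deg=(0, 45, 90, 135)) -> np.ndarray:
    """Ideal linear-analyser responses to a (partially) polarised beam.

    ``stokes`` = (S0, S1, S2, S3); a polariser at angle a transmits
    (S0 + S1 cos 2a + S2 sin 2a) / 2.
    """
    s0, s1, s2 = stokes[0], stokes[1], stokes[2]
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return 0.5 * (s0 + s1 * np.cos(2 * a) + s2 * np.sin(2 * a))


def superpixel_detection_efficiency(stokes: np.ndarray) -> float:
    """Fraction of sensor-incident light detected across one 2x2 superpixel.

    Each analyser site sees its Malus share; averaged over the four sites the
    mask transmits exactly half of S0, for any polarisation state.
    """
    s0 = float(stokes[0])
    if s0 <= 0:
        raise ValueError("beam power S0 must be positive")
    return float(np.mean(analyser_intensities(np.asarray(stokes, dtype=float))) / s0)
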