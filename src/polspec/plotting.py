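"""Plots: SMV plane scatter and the wavelength-coloured response curve."""

from __future__ import annotations

import numpy as np

from .smv import ResponseCurve, SMVImage


def plot_response_curve(curve: ResponseCurve, ax=None, show_theory: bool = True):
    """Rainbow response curve: SMV points coloured by wavelength.

    The dashed line is the ideal monochromatic locus V2 = 1 - V1^2 of the
    mosaic-camera modulation pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(
        curve.smv[:, 0], curve.smv[:, 1], c=curve.wavelengths_nm,
        cmap="rainbow", s=12,
    )
    if show_theory:
        x = np.linspace(-1, 1, 201)
        ax.plot(x, 1 - x**2, "k--", lw=1, label="$V_2 = 1 - V_1^2$")
        ax.legend(loc="lower center")
    ax.set_xlabel("$V_1$")
    ax.set_ylabel("$V_2$")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-0.05, 1.1)
    plt.colorbar(sc, ax=ax, label="wavelength (nm)")
    return ax


def plot_smv_scatter(smv: SMVImage, ax=None, max_points: int = 20000, seed: int = 0):
    """2-D histogram-style scatter of valid pixel SMVs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = smv.valid_points()
    if pts.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(pts.shape[0], max_points, replace=False)]
    ax.scatter(pts[:, 0], pts[:, 1], s=2, alpha=0.3)
    ax.set_xlabel("$V_1$")
    ax.set_ylabel("$V_2$")
    return ax
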