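"""SMV-space classification, reference unmixing and pseudocolour synthesis.

Because an SMV is intensity-normalised and mixtures combine linearly
(power-weighted), pixels of like spectral signature cluster in the SMV plane
regardless of brightness. Classification draws closed polygonal gates around
clusters; unmixing solves the per-pixel linear system expressing the observed
SMV as a convex combination of reference SMVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import nnls

from .smv import ModulationSet, SMVImage, compute_smv
from .spectra import Spectrum

__all__ = [
    "Gate",
    "ReferenceSet",
    "classify",
    "unmix",
    "pseudocolour",
    "box_gate",
]


@dataclass(frozen=True)
class Gate:
    """A closed polygonal region of the (V1, V2) plane.

    Points on the boundary are inside. When gates overlap, the one with the
    larger ``priority`` wins; ties resolve to the earlier gate in the list.
    """

    label: str
    polygon: tuple[tuple[float, float], ...]
    priority: int = 0

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("gate polygon needs at least 3 vertices")
        poly = shapely.Polygon(self.polygon)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError("gate polygon must be simple with positive area")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for an (M, 2) array of SMV points."""
        poly = shapely.Polygon(self.polygon)
        pts = shapely.points(points[:, 0], points[:, 1])
        return shapely.covers(poly, pts)


def box_gate(label: str, center: tuple[float, float], half_width: float, priority: int = 0) -> Gate:
    """Axis-aligned square gate around an SMV cluster centre."""
    cx, cy = center
    h = half_width
    return Gate(
        label=label,
        polygon=((cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)),
        priority=priority,
    )


def classify(smv: SMVImage, gates: list[Gate]) -> tuple[np.ndarray, dict[int, str]]:
    """Assign each valid pixel to the highest-priority gate containing it.

    Returns an integer label image (0 = masked/ungated) and the mapping from
    label value to gate name. Gate values are 1..K in the given gate order.
    """
    h, w = smv.total_intensity.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if not gates:
        return labels, {}
    if smv.n_components != 2:
        raise ValueError("polygon gating operates on 2-component SMVs")
    pts = smv.v[smv.valid]
    assigned = np.zeros(len(pts), dtype=np.int32)
    best_priority = np.full(len(pts), -np.inf)
    for value, gate in enumerate(gates, start=1):
        inside = gate.contains(pts)
        take = inside & (gate.priority > best_priority)
        assigned[take] = value
        best_priority[take] = gate.priority
    labels[smv.valid] = assigned
    legend = {value: gate.label for value, gate in enumerate(gates, start=1)}
    return labels, legend


@dataclass
class ReferenceSet:
    """K reference SMVs (rows), one per pure spectral component.

    With N-component SMVs, K <= N + 1 references admit an exact decomposition
    (the references plus the sum-to-one constraint must be linearly
    independent).
    """

    vectors: np.ndarray  # (K, N)
    labels: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] != len(self.labels):
            raise ValueError("one label per reference required")

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    @property
    def design_matrix(self) -> np.ndarray:
        """(N+1, K) system matrix [R^T; 1] of the constrained decomposition."""
        return np.vstack([self.vectors.T, np.ones(self.k)])

    def assert_full_rank(self) -> None:
        a = self.design_matrix
        if np.linalg.matrix_rank(a) < self.k:
            raise ValueError(
                f"degenerate reference set {self.labels}: design matrix rank "
                f"{np.linalg.matrix_rank(a)} < {self.k}"
            )

    @classmethod
    def from_spectra(
        cls, spectra: dict[str, Spectrum], mods: ModulationSet
    ) -> "ReferenceSet":
        labels = list(spectra)
        vectors = np.array([compute_smv(spectra[name], mods) for name in labels])
        return cls(vectors=vectors, labels=labels)


def unmix(
    smv: SMVImage,
    refs: ReferenceSet,
    non_negative: str = "clip",
) -> np.ndarray:
    """Per-pixel fractions of each reference whose weighted mean is the SMV.

    Solves ``sum_k f_k R_k = V`` with ``sum_k f_k = 1`` — exactly when
    K = N + 1, in least squares otherwise. ``non_negative``: "none" keeps the
    raw (possibly negative) solution; "clip" (default) clips negatives and
    renormalises; "nnls" solves the simplex-constrained least-squares problem
    per pixel. Masked pixels get all-zero fractions. Component intensities
    are ``fractions * total_intensity[..., None]``.
    """
    if non_negative not in ("none", "clip", "nnls"):
        raise ValueError("non_negative must be 'none', 'clip' or 'nnls'")
    refs.assert_full_rank()
    a = refs.design_matrix  # (N+1, K)
    h, w = smv.total_intensity.shape
    fractions = np.zeros((h, w, refs.k))
    pts = smv.v[smv.valid]  # (M, N)
    rhs = np.hstack([pts, np.ones((pts.shape[0], 1))])  # (M, N+1)

    if non_negative == "nnls":
        sols = np.array([nnls(a, b)[0] for b in rhs])
        sums = sols.sum(axis=1, keepdims=True)
        sols = np.divide(sols, sums, out=np.zeros_like(sols), where=sums > 0)
    else:
        solver = np.linalg.solve if a.shape[0] == a.shape[1] else None
        if solver is not None:
            sols = np.linalg.solve(a, rhs.T).T
        else:
            sols = np.linalg.lstsq(a, rhs.T, rcond=None)[0].T
        if non_negative == "clip":
            sols = np.clip(sols, 0.0, None)
            sums = sols.sum(axis=1, keepdims=True)
            sols = np.divide(sols, sums, out=np.zeros_like(sols), where=sums > 0)
    fractions[smv.valid] = sols
    return fractions


def pseudocolour(
    abundances: np.ndarray,
    total_intensity: np.ndarray,
    white_region: np.ndarray,
) -> np.ndarray:
    """White-balanced RGB image from three abundance channels.

    Each channel is the component intensity (abundance x total intensity)
    divided by the mean of that product over the white-reference region, so a
    white-region pixel renders grey; the image is then jointly rescaled to
    [0, 1]. Deterministic.
    """
    if abundances.shape[-1] != 3:
        raise ValueError("pseudocolour needs exactly 3 abundance channels")
    if white_region.dtype != bool or not white_region.any():
        raise ValueError("white reference region must be a non-empty boolean mask")
    rgb = abundances * total_intensity[..., None]
    white_means = rgb[white_region].mean(axis=0)
    if np.any(white_means <= 0):
        raise ValueError("white reference region has zero mean in some channel")
    rgb = rgb / white_means
    peak = rgb.max()
    return rgb / peak if peak > 0 else rgb
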