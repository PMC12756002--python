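"""Compactness (radius of gyration) analysis and rigid-body superposition.

Rg is the mass-weighted RMS distance of atoms from the per-frame centre
of mass, Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ), reported in
Angstrom.  Series are smoothed with a valid-window rolling mean (no edge
padding) and binned into half-open histograms.  Superposition uses the
Kabsch algorithm restricted to proper rotations (molecules are chiral).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.transform import Rotation

from .errors import ParameterError, StructuralError
from .trajectory_model import Trajectory

__all__ = [
    "RgSeries",
    "radius_of_gyration",
    "rolling_mean",
    "rg_histogram",
    "analyze_rg",
    "superpose_rmsd",
]


@dataclass(frozen=True)
class RgSeries:
    """Per-frame Rg (Angstrom) with optional smoothing and histogram."""

    values: np.ndarray
    window: int | None = None
    smoothed: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.values)


def radius_of_gyration(traj: Trajectory) -> RgSeries:
    """Mass-weighted radius of gyration for every frame."""
    masses = traj.topology.masses
    total = masses.sum()
    if total <= 0:
        raise ParameterError("zero total mass")
    w = (masses / total)[None, :, None]
    com = (w * traj.coordinates).sum(axis=1, keepdims=True)
    sq = ((traj.coordinates - com) ** 2).sum(axis=2)
    rg = np.sqrt((masses[None, :] / total * sq).sum(axis=1))
    return RgSeries(values=rg)


def rolling_mean(series: np.ndarray, window: int = 50) -> np.ndarray:
    """Valid-window moving average; output length is ``F - window + 1``."""
    series = np.asarray(series, dtype=np.float64)
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window > len(series):
        raise ParameterError(
            f"window {window} exceeds series length {len(series)}"
        )
    return sliding_window_view(series, window).mean(axis=1)


def rg_histogram(
    series: np.ndarray, bin_width: float = 0.5, lo: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bins [lo, lo+w), [lo+w, lo+2w), ...; counts sum to F.

    ``lo`` defaults to the largest multiple of ``bin_width`` not above
    the series minimum, so bin edges land on round values.
    """
    series = np.asarray(series, dtype=np.float64)
    if bin_width <= 0:
        raise ParameterError(f"bin width must be > 0, got {bin_width}")
    if lo is None:
        lo = np.floor(series.min() / bin_width) * bin_width
    idx = np.floor((series - lo) / bin_width).astype(np.int64)
    if idx.min() < 0:
        raise ParameterError("histogram origin lies above the series minimum")
    counts = np.bincount(idx)
    edges = lo + bin_width * np.arange(len(counts) + 1)
    return edges, counts


def analyze_rg(
    traj: Trajectory, window: int = 50, bin_width: float = 0.5
) -> RgSeries:
    """Full compactness analysis: per-frame Rg, rolling mean, histogram."""
    rg = radius_of_gyration(traj)
    window = min(window, rg.n_frames)
    edges, counts = rg_histogram(rg.values, bin_width)
    return RgSeries(
        values=rg.values,
        window=window,
        smoothed=rolling_mean(rg.values, window),
        bin_edges=edges,
        counts=counts,
    )


def superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """RMSD after optimal rigid-body superposition of B onto A.

    The rotation is the weighted Kabsch solution constrained to proper
    rotations; translation aligns the weighted centroids.  Symmetric in
    its arguments.
    """
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise StructuralError(
            f"coordinate sets must share an (N, 3) shape, got {a.shape} vs {b.shape}"
        )
    n = a.shape[0]
    if n < 3:
        raise StructuralError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ParameterError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    ac = a - (wn[:, None] * a).sum(axis=0)
    bc = b - (wn[:, None] * b).sum(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc, weights=w)
    d = ac - rot.apply(bc)
    return float(np.sqrt((wn * (d ** 2).sum(axis=1)).sum()))
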