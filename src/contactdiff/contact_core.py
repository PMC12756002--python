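"""Residue-residue distances and per-ensemble contact statistics.

Two contact definitions are supported, matching common practice for
coarse (backbone) and fine (side-chain aware) contact maps:

* ``CA`` mode: the Calpha-Calpha distance, default cutoff 8.0 A;
* ``heavy`` mode: the *minimum* distance over all heavy-atom pairs of
  the two residues, default cutoff 4.5 A.

A pair is in contact in a frame when its distance is <= the cutoff
(inclusive boundary).  The contact probability of a pair is the
fraction of frames in contact; averaging distances over all frames
gives the mean-distance matrix used as a continuous contact-persistence
proxy.  Pairs excluded by ``min_seq_sep`` or chain scope, and the
diagonal, are NaN in exported matrices and carry a False entry in the
``defined`` mask.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CompatibilityError, ParameterError, StructuralError
from .trajectory_model import Topology, Trajectory

__all__ = [
    "ContactParams",
    "ContactMatrix",
    "ContactSeries",
    "residue_distance_matrix",
    "contact_matrix",
    "mean_distance_matrix",
    "contact_series",
]

DEFAULT_CUTOFFS = {"CA": 8.0, "heavy": 4.5}

# frames per chunk when broadcasting (F, R, R) distance blocks
_CHUNK = 512


@dataclass(frozen=True)
class ContactParams:
    """Contact definition: mode, cutoff (A), minimum sequence separation
    (1 = all i<j pairs) and chain scope (all/intra/inter)."""

    mode: str = "CA"
    cutoff: float | None = None
    min_seq_sep: int = 1
    chain_scope: str = "all"

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_CUTOFFS:
            raise ParameterError(f"unknown contact mode {self.mode!r}")
        if self.cutoff is None:
            object.__setattr__(self, "cutoff", DEFAULT_CUTOFFS[self.mode])
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be > 0, got {self.cutoff}")
        if self.min_seq_sep < 1:
            raise ParameterError(f"min_seq_sep must be >= 1, got {self.min_seq_sep}")
        if self.chain_scope not in ("all", "intra", "inter"):
            raise ParameterError(f"unknown chain scope {self.chain_scope!r}")


def residue_keys(topology: Topology) -> tuple[tuple[str, int, str], ...]:
    """(chain, resSeq, name) per residue — the identity of matrix axes."""
    return tuple((r.chain_id, r.index, r.name) for r in topology.residues)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric residue x residue matrix (probability or mean distance)
    with its parameters and residue table as provenance."""

    values: np.ndarray
    value_kind: str  # "probability" | "mean_distance"
    params: ContactParams
    condition: str
    n_frames: int
    residues: tuple[tuple[str, int, str], ...]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def check_comparable(self, other: "ContactMatrix") -> None:
        if self.residues != other.residues:
            raise CompatibilityError("residue tables differ")
        if self.params != other.params:
            raise CompatibilityError(
                f"contact parameters differ: {self.params} vs {other.params}"
            )
        if self.value_kind != other.value_kind:
            raise CompatibilityError(
                f"value kinds differ: {self.value_kind} vs {other.value_kind}"
            )


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame contact indicators (and distances) for tracked pairs,
    keyed by 0-based residue-table positions (i, j) with i < j."""

    pairs: tuple[tuple[int, int], ...]
    indicators: np.ndarray  # (n_pairs, F) bool
    distances: np.ndarray  # (n_pairs, F) float
    params: ContactParams
    condition: str
    residues: tuple[tuple[str, int, str], ...]
    _index: dict = field(default=None, compare=False, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {p: k for k, p in enumerate(self.pairs)}
        )

    @property
    def n_frames(self) -> int:
        return self.indicators.shape[1]

    def indicator(self, i: int, j: int) -> np.ndarray:
        key = (i, j) if i < j else (j, i)
        if key not in self._index:
            raise KeyError(f"pair {key} is not tracked by this series")
        return self.indicators[self._index[key]]

    def occupancy(self, i: int, j: int) -> float:
        """Fraction of frames in contact — equals the contact-probability
        matrix entry for this pair exactly."""
        return float(self.indicator(i, j).mean())


# ---------------------------------------------------------------------------
# Atom bookkeeping
# ---------------------------------------------------------------------------

def _ca_indices(topology: Topology) -> np.ndarray:
    idx = []
    for r in topology.residues:
        ca = [a for a in r.atom_indices if topology.atom_names[a] == "CA"]
        if len(ca) != 1:
            raise StructuralError(
                f"residue {r.chain_id}:{r.name}{r.index} has {len(ca)} CA atoms"
            )
        idx.append(ca[0])
    return np.asarray(idx, dtype=np.intp)


def _heavy_groups(topology: Topology) -> list[np.ndarray]:
    groups = []
    for r in topology.residues:
        heavy = np.asarray(
            [a for a in r.atom_indices if topology.elements[a] not in ("H", "D")],
            dtype=np.intp,
        )
        if heavy.size == 0:
            raise StructuralError(
                f"residue {r.chain_id}:{r.name}{r.index} has no heavy atoms"
            )
        groups.append(heavy)
    return groups


def _undefined_mask(topology: Topology, params: ContactParams) -> np.ndarray:
    """Boolean (R,R) mask of pairs excluded from the analysis."""
    res = topology.residues
    n = len(res)
    chains = np.array([r.chain_id for r in res], dtype=object)
    seq = np.array([r.index for r in res], dtype=np.int64)
    same_chain = chains[:, None] == chains[None, :]
    sep = np.abs(seq[:, None] - seq[None, :])
    mask = np.zeros((n, n), dtype=bool)
    mask |= np.eye(n, dtype=bool)
    mask |= same_chain & (sep < params.min_seq_sep)
    if params.chain_scope == "intra":
        mask |= ~same_chain
    elif params.chain_scope == "inter":
        mask |= same_chain
    return mask


def _frame_distances(
    coords: np.ndarray, topology: Topology, params: ContactParams
) -> np.ndarray:
    """(F, R, R) residue-level distance stack for a coordinate block."""
    if params.mode == "CA":
        ca = coords[:, _ca_indices(topology), :]
        diff = ca[:, :, None, :] - ca[:, None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))
    groups = _heavy_groups(topology)
    heavy = np.concatenate(groups)
    res_of = np.concatenate(
        [np.full(len(g), k, dtype=np.intp) for k, g in enumerate(groups)]
    )
    sub = coords[:, heavy, :]
    n = len(groups)
    out = np.empty((coords.shape[0], n, n))
    for f in range(coords.shape[0]):
        diff = sub[f][:, None, :] - sub[f][None, :, :]
        ad = np.sqrt((diff ** 2).sum(axis=-1))
        red = np.full((n, n), np.inf)
        np.minimum.at(red, (res_of[:, None], res_of[None, :]), ad)
        out[f] = red
    return out


def residue_distance_matrix(
    coordinates: np.ndarray, topology: Topology, params: ContactParams
) -> np.ndarray:
    """R x R residue distance matrix for a single frame (A,3)."""
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim != 2:
        raise StructuralError(f"expected a single (A, 3) frame, got {coords.shape}")
    return _frame_distances(coords[None], topology, params)[0]


def _accumulate(traj: Trajectory, params: ContactParams):
    """Stream frames in chunks; yields (F_chunk, R, R) distance stacks."""
    for start in range(0, traj.n_frames, _CHUNK):
        yield _frame_distances(
            traj.coordinates[start : start + _CHUNK], traj.topology, params
        )


def contact_matrix(
    traj: Trajectory, params: ContactParams, condition: str = ""
) -> ContactMatrix:
    """Contact-probability matrix: fraction of frames with distance <=
    cutoff, per residue pair (inclusive boundary)."""
    n = traj.topology.n_residues
    counts = np.zeros((n, n), dtype=np.int64)
    for dist in _accumulate(traj, params):
        counts += (dist <= params.cutoff).sum(axis=0)
    values = counts / traj.n_frames
    values[_undefined_mask(traj.topology, params)] = np.nan
    return ContactMatrix(
        values=values,
        value_kind="probability",
        params=params,
        condition=condition,
        n_frames=traj.n_frames,
        residues=residue_keys(traj.topology),
    )


def mean_distance_matrix(
    traj: Trajectory,
    params: ContactParams,
    contact_frames_only: bool = False,
    condition: str = "",
) -> ContactMatrix:
    """Mean residue-residue distance over all frames (default), or over
    contact frames only (pairs never in contact become NaN)."""
    n = traj.topology.n_residues
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int64)
    for dist in _accumulate(traj, params):
        if contact_frames_only:
            inside = dist <= params.cutoff
            total += np.where(inside, dist, 0.0).sum(axis=0)
            count += inside.sum(axis=0)
        else:
            total += dist.sum(axis=0)
            count += dist.shape[0]
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    values[_undefined_mask(traj.topology, params)] = np.nan
    return ContactMatrix(
        values=values,
        value_kind="mean_distance",
        params=params,
        condition=condition,
        n_frames=traj.n_frames,
        residues=residue_keys(traj.topology),
    )


def contact_series(
    traj: Trajectory,
    params: ContactParams,
    pairs: list[tuple[int, int]],
    condition: str = "",
) -> ContactSeries:
    """Per-frame contact record for selected residue pairs (0-based
    residue-table positions)."""
    n = traj.topology.n_residues
    norm_pairs = []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise KeyError(f"invalid residue pair ({i}, {j})")
        norm_pairs.append((min(i, j), max(i, j)))
    norm_pairs = tuple(norm_pairs)
    distances = np.empty((len(norm_pairs), traj.n_frames))
    offset = 0
    for dist in _accumulate(traj, params):
        for k, (i, j) in enumerate(norm_pairs):
            distances[k, offset : offset + dist.shape[0]] = dist[:, i, j]
        offset += dist.shape[0]
    indicators = distances <= params.cutoff
    return ContactSeries(
        pairs=norm_pairs,
        indicators=indicators,
        distances=distances,
        params=params,
        condition=condition,
        residues=residue_keys(traj.topology),
    )
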