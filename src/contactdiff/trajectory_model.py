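"""Molecular data model and topology/trajectory I/O.

The in-memory model is deliberately small: a :class:`Topology` holds
per-atom metadata (name, element, mass, residue, chain) plus a derived
ordered residue table, and a :class:`Trajectory` couples a topology with
an ``F x A x 3`` coordinate array in Angstrom.  Text formats only are
required (PDB topology, multi-MODEL PDB or multi-frame XYZ coordinates);
parsing is delegated to MDAnalysis, with structural contracts (atom-count
consistency per frame, non-empty systems) enforced here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    EmptySystemError,
    FormatError,
    SelectionError,
    StructuralError,
)

__all__ = [
    "Topology",
    "Trajectory",
    "SelectionSpec",
    "Residue",
    "load_topology",
    "load_trajectory",
    "strip_non_protein",
    "select_atoms",
    "write_pdb",
    "write_xyz",
    "ELEMENT_MASSES",
    "DEFAULT_EXCLUDED_RESIDUES",
]

# Standard atomic masses (amu), IUPAC 2021 abridged values.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "B": 10.81, "I": 126.904,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305, "ZN": 65.38,
    "CA": 40.078, "FE": 55.845, "MN": 54.938, "CU": 63.546, "BR": 79.904,
    "SE": 78.971,
}

# Residue names removed by strip_non_protein: waters, then common ions.
DEFAULT_EXCLUDED_RESIDUES: frozenset[str] = frozenset(
    {"HOH", "WAT", "SOL", "NA", "CL", "K", "MG", "ZN"}
)


@dataclass(frozen=True)
class Residue:
    """One residue of the ordered residue table.

    ``index`` is the author residue number (PDB resSeq, 1-based); the
    position of the residue in the table is its matrix index.
    """

    index: int
    name: str
    chain_id: str
    atom_indices: np.ndarray  # positions into the topology atom arrays

    def __repr__(self) -> str:  # pragma: no cover
        return f"Residue({self.chain_id}:{self.name}{self.index}, {len(self.atom_indices)} atoms)"


@dataclass(frozen=True)
class Topology:
    """Per-atom metadata plus the derived ordered residue table."""

    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    residues: tuple[Residue, ...] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_atoms == 0:
            raise EmptySystemError("topology has zero atoms")
        if np.any(self.masses <= 0):
            bad = np.flatnonzero(self.masses <= 0)[0]
            raise StructuralError(
                f"atom {bad} ({self.atom_names[bad]}) has non-positive mass"
            )
        for chain in dict.fromkeys(self.chain_ids.tolist()):
            idx = self.residue_indices[self.chain_ids == chain]
            if np.any(np.diff(idx) < 0):
                raise StructuralError(
                    f"residue indices decrease within chain {chain!r}"
                )
        if self.residues is None:
            object.__setattr__(self, "residues", _group_residues(self))

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_labels(self) -> list[str]:
        """Human-readable labels, e.g. ``A:GLY5``, in table order."""
        return [f"{r.chain_id}:{r.name}{r.index}" for r in self.residues]

    def residue_table(self) -> list[tuple[int, str, int, str]]:
        """(matrix index, chain, resSeq, residue name) rows, exported
        alongside every matrix so matrix positions map back to author
        numbering."""
        return [
            (pos, r.chain_id, r.index, r.name)
            for pos, r in enumerate(self.residues)
        ]

    def subset(self, atom_idx: np.ndarray) -> "Topology":
        atom_idx = np.asarray(atom_idx, dtype=np.intp)
        return Topology(
            atom_names=self.atom_names[atom_idx],
            elements=self.elements[atom_idx],
            masses=self.masses[atom_idx],
            residue_indices=self.residue_indices[atom_idx],
            residue_names=self.residue_names[atom_idx],
            chain_ids=self.chain_ids[atom_idx],
        )


def _group_residues(top: Topology) -> tuple[Residue, ...]:
    """Group consecutive atoms sharing (chain, resSeq) into residues."""
    residues: list[Residue] = []
    start = 0
    key = None
    for a in range(top.n_atoms + 1):
        if a < top.n_atoms:
            k = (top.chain_ids[a], int(top.residue_indices[a]))
        else:
            k = None
        if k != key:
            if key is not None:
                residues.append(
                    Residue(
                        index=key[1],
                        name=str(top.residue_names[start]),
                        chain_id=str(key[0]),
                        atom_indices=np.arange(start, a, dtype=np.intp),
                    )
                )
            key, start = k, a
    return tuple(residues)


@dataclass(frozen=True)
class Trajectory:
    """A topology plus F frames of coordinates (Angstrom)."""

    topology: Topology
    coordinates: np.ndarray  # (F, A, 3) float64

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructuralError(f"coordinates must be (F, A, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise FormatError("trajectory has zero frames")
        if coords.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {coords.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(coords)):
            raise StructuralError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: ``all`` | ``heavy`` | ``CA`` | ``names`` (+ optional
    chain filter). ``heavy`` excludes hydrogen/deuterium; ``CA`` keeps one
    alpha-carbon per residue."""

    mode: str = "all"
    names: tuple[str, ...] = ()
    chains: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"all", "heavy", "CA", "names"}:
            raise SelectionError(f"unknown selection mode {self.mode!r}")
        if self.mode == "names" and not self.names:
            raise SelectionError("names mode requires a non-empty name list")


def _infer_element(name: str) -> str:
    """Fallback element inference: first alphabetic character of the
    atom name (PDB convention for protein atoms)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot infer element for atom name {name!r}")


def _mass_for(element: str, atom_name: str) -> float:
    el = element.upper()
    if el in ELEMENT_MASSES:
        return ELEMENT_MASSES[el]
    el = _infer_element(atom_name)
    if el in ELEMENT_MASSES:
        return ELEMENT_MASSES[el]
    raise FormatError(f"no standard mass for element {element!r} (atom {atom_name!r})")


def load_topology(path: str) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Elements come from the PDB element column when present, otherwise
    from the atom-name first letter; masses from the standard element
    table.  The reader does not filter: waters and ions stay until
    :func:`strip_non_protein`.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except OSError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise FormatError(f"{path} contains no ATOM/HETATM records")

    names = np.array([str(n) for n in u.atoms.names], dtype=object)
    if hasattr(u.atoms, "elements"):
        raw = [str(e).strip() for e in u.atoms.elements]
    else:
        raw = [""] * len(names)
    elements = np.array(
        [e.upper() if e else _infer_element(n) for e, n in zip(raw, names)],
        dtype=object,
    )
    masses = np.array(
        [_mass_for(e, n) for e, n in zip(elements, names)], dtype=np.float64
    )
    chain_ids = np.array(
        [str(c) if str(c).strip() else "A" for c in _chain_ids(u)], dtype=object
    )
    return Topology(
        atom_names=names,
        elements=elements,
        masses=masses,
        residue_indices=np.asarray(u.atoms.resids, dtype=np.int64),
        residue_names=np.array([str(r) for r in u.atoms.resnames], dtype=object),
        chain_ids=chain_ids,
    )


def _chain_ids(u) -> list[str]:
    for attr in ("chainIDs", "segids"):
        if hasattr(u.atoms, attr):
            return [str(x) for x in getattr(u.atoms, attr)]
    return ["A"] * u.atoms.n_atoms


def _scan_xyz_frames(path: str, n_atoms: int) -> int:
    """Structural pre-check of a multi-frame XYZ file.

    Returns the frame count; raises StructuralError naming the first
    frame whose atom count disagrees with the topology (MDAnalysis
    silently truncates such files, so the check must happen up front).
    """
    n_frames = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                count = int(header.split()[0])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad XYZ frame header {header!r}"
                ) from exc
            n_frames += 1
            if count != n_atoms:
                raise StructuralError(
                    f"{path}: frame {n_frames} has {count} atoms, "
                    f"topology has {n_atoms}"
                )
            fh.readline()  # comment line
            for i in range(count):
                if not fh.readline():
                    raise FormatError(
                        f"{path}: frame {n_frames} truncated after {i} atom lines"
                    )
    if n_frames == 0:
        raise FormatError(f"{path}: no XYZ frames found")
    return n_frames


def load_trajectory(topology: Topology, path: str) -> Trajectory:
    """Read a multi-MODEL PDB or multi-frame XYZ coordinate file.

    Every frame must carry exactly ``topology.n_atoms`` atoms; a
    mismatch raises :class:`StructuralError` naming the offending frame
    (1-based).
    """
    import MDAnalysis as mda

    path = str(path)
    if path.lower().endswith(".xyz"):
        _scan_xyz_frames(path, topology.n_atoms)
    frames: list[np.ndarray] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
            if u.atoms.n_atoms != topology.n_atoms:
                raise StructuralError(
                    f"{path}: frame 1 has {u.atoms.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
            for ts in u.trajectory:
                frames.append(u.atoms.positions.astype(np.float64).copy())
    except StructuralError:
        raise
    except OSError:
        raise
    except ValueError as exc:
        raise StructuralError(
            f"{path}: frame {len(frames) + 1} is structurally inconsistent "
            f"with the topology ({exc})"
        ) from exc
    except Exception as exc:
        raise FormatError(f"cannot parse trajectory {path}: {exc}") from exc
    if not frames:
        raise FormatError(f"{path}: no coordinate frames found")
    return Trajectory(topology=topology, coordinates=np.stack(frames))


def strip_non_protein(
    traj: Trajectory,
    excluded_residues: frozenset[str] | set[str] = DEFAULT_EXCLUDED_RESIDUES,
) -> Trajectory:
    """Drop solvent/ion residues (by residue name) from topology and all
    frames.  Residue numbering of the remaining atoms is preserved.
    Idempotent."""
    excluded = {r.upper() for r in excluded_residues}
    keep = np.array(
        [str(r).upper() not in excluded for r in traj.topology.residue_names],
        dtype=bool,
    )
    if not keep.any():
        raise EmptySystemError("strip_non_protein removed every atom")
    if keep.all():
        return traj
    idx = np.flatnonzero(keep)
    return Trajectory(
        topology=traj.topology.subset(idx),
        coordinates=traj.coordinates[:, idx, :],
    )


def select_atoms(traj: Trajectory, spec: SelectionSpec) -> Trajectory:
    """Restrict a trajectory to the atoms matching ``spec``; frame count
    and residue-level grouping are preserved."""
    top = traj.topology
    if spec.mode == "all":
        mask = np.ones(top.n_atoms, dtype=bool)
    elif spec.mode == "heavy":
        mask = np.array([e not in ("H", "D") for e in top.elements], dtype=bool)
    elif spec.mode == "CA":
        mask = top.atom_names == "CA"
    else:  # names
        wanted = set(spec.names)
        mask = np.array([n in wanted for n in top.atom_names], dtype=bool)
    if spec.chains is not None:
        mask &= np.array([c in spec.chains for c in top.chain_ids], dtype=bool)
    if not mask.any():
        raise SelectionError(f"selection {spec} matched no atoms")
    idx = np.flatnonzero(mask)
    return Trajectory(
        topology=top.subset(idx), coordinates=traj.coordinates[:, idx, :]
    )


# ---------------------------------------------------------------------------
# Text writers (fixtures and exports are diffable plain text)
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:5d} {name_field}"
        f" {resname:<3s} {chain:1s}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str) -> None:
    """Write coordinates as a PDB file; multi-frame input produces
    MODEL/ENDMDL blocks, a single frame a plain record list."""
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    multi = coords.shape[0] > 1
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            if multi:
                fh.write(f"MODEL     {f + 1}\n")
            for a in range(topology.n_atoms):
                fh.write(
                    _pdb_atom_line(
                        (a % 99999) + 1,
                        str(topology.atom_names[a]),
                        str(topology.residue_names[a]),
                        str(topology.chain_ids[a])[:1],
                        int(topology.residue_indices[a]) % 10000,
                        coords[f, a],
                        str(topology.elements[a])[:2],
                    )
                )
            fh.write("ENDMDL\n" if multi else "END\n")


def write_xyz(topology: Topology, coordinates: np.ndarray, path: str) -> None:
    """Write a multi-frame XYZ file (count line, comment, atom lines)."""
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{topology.n_atoms}\nframe {f + 1}\n")
            for a in range(topology.n_atoms):
                x, y, z = coords[f, a]
                fh.write(f"{topology.atom_names[a]:<4s} {x:.3f} {y:.3f} {z:.3f}\n")
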