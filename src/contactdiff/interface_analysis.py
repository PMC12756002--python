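"""Protein-peptide interface contact statistics.

A protein residue and a peptide residue are in contact in a frame when
any heavy atom of one comes within the cutoff (default 4.5 A,
inclusive) of any heavy atom of the other.  Pair frequencies are
fractions of frames; summing a protein residue's row over all peptide
residues gives the peptide contact profile.  Contacts can additionally
be categorized by residue-class pairs (aliphatic / aromatic / polar /
charged) to separate, e.g., hydrophobically driven binding from
electrostatics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ClassificationError,
    CompatibilityError,
    ParameterError,
    StructuralError,
)
from .trajectory_model import Trajectory

__all__ = [
    "InterfaceProfile",
    "ResidueClassScheme",
    "DEFAULT_CLASS_SCHEME",
    "INTERFACE_CUTOFF",
    "interface_contacts",
    "peptide_contact_profile",
    "categorize_contacts",
    "interface_difference",
]

INTERFACE_CUTOFF = 4.5

RESIDUE_CLASSES = ("aliphatic", "aromatic", "polar", "charged")


@dataclass(frozen=True)
class ResidueClassScheme:
    """Total mapping of the 20 standard residues to four classes.  The
    default places HIS with the polar class (its protonation-dependent
    charge makes this assignment genuinely ambiguous)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values()} - set(RESIDUE_CLASSES)
        if bad:
            raise ParameterError(f"unknown residue classes: {sorted(bad)}")

    def classify(self, resname: str) -> str:
        name = resname.upper()
        if name not in self.mapping:
            raise ClassificationError(f"residue {resname!r} has no class assignment")
        return self.mapping[name]


DEFAULT_CLASS_SCHEME = ResidueClassScheme(
    mapping={
        **{r: "aliphatic" for r in ("GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "MET")},
        **{r: "aromatic" for r in ("PHE", "TRP", "TYR")},
        **{r: "polar" for r in ("SER", "THR", "CYS", "ASN", "GLN", "HIS")},
        **{r: "charged" for r in ("ASP", "GLU", "LYS", "ARG")},
    }
)


@dataclass(frozen=True)
class InterfaceProfile:
    """Pair-frequency matrix between a protein chain and a peptide
    chain.  ``granularity`` is ``residue`` (a residue pair contributes
    at most 1 per frame) or ``atom`` (mean number of atom pairs within
    the cutoff, so entries may exceed 1)."""

    pair_values: np.ndarray  # (R_protein, R_peptide)
    protein_residues: tuple[tuple[str, int, str], ...]
    peptide_residues: tuple[tuple[str, int, str], ...]
    cutoff: float
    condition: str
    granularity: str = "residue"
    n_frames: int = 0

    def check_comparable(self, other: "InterfaceProfile") -> None:
        if self.protein_residues != other.protein_residues:
            raise CompatibilityError("protein residue tables differ")
        if self.peptide_residues != other.peptide_residues:
            raise CompatibilityError("peptide residue tables differ")
        if (self.cutoff, self.granularity) != (other.cutoff, other.granularity):
            raise CompatibilityError("interface parameters differ")


def _chain_heavy_groups(traj: Trajectory, chain: str):
    top = traj.topology
    residues = [r for r in top.residues if r.chain_id == chain]
    if not residues:
        raise StructuralError(f"chain {chain!r} not found in topology")
    groups, keys = [], []
    for r in residues:
        heavy = np.asarray(
            [a for a in r.atom_indices if top.elements[a] not in ("H", "D")],
            dtype=np.intp,
        )
        if heavy.size == 0:
            raise StructuralError(
                f"residue {r.chain_id}:{r.name}{r.index} has no heavy atoms"
            )
        groups.append(heavy)
        keys.append((r.chain_id, r.index, r.name))
    return groups, tuple(keys)


def interface_contacts(
    traj: Trajectory,
    protein_chain: str = "A",
    peptide_chain: str = "P",
    cutoff: float = INTERFACE_CUTOFF,
    granularity: str = "residue",
    condition: str = "",
) -> InterfaceProfile:
    """Any-heavy-atom interface contact frequencies between two chains."""
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")
    if granularity not in ("residue", "atom"):
        raise ParameterError(f"unknown granularity {granularity!r}")
    prot_groups, prot_keys = _chain_heavy_groups(traj, protein_chain)
    pep_groups, pep_keys = _chain_heavy_groups(traj, peptide_chain)
    prot_atoms = np.concatenate(prot_groups)
    pep_atoms = np.concatenate(pep_groups)
    prot_res_of = np.concatenate(
        [np.full(len(g), k, dtype=np.intp) for k, g in enumerate(prot_groups)]
    )
    pep_res_of = np.concatenate(
        [np.full(len(g), k, dtype=np.intp) for k, g in enumerate(pep_groups)]
    )
    np_res, nq_res = len(prot_groups), len(pep_groups)
    acc = np.zeros((np_res, nq_res))
    for f in range(traj.n_frames):
        a = traj.coordinates[f, prot_atoms, :]
        b = traj.coordinates[f, pep_atoms, :]
        diff = a[:, None, :] - b[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=-1))
        inside = d <= cutoff
        if granularity == "residue":
            red = np.zeros((np_res, nq_res), dtype=bool)
            np.logical_or.at(red, (prot_res_of[:, None], pep_res_of[None, :]), inside)
            acc += red
        else:
            counts = np.zeros((np_res, nq_res))
            np.add.at(counts, (prot_res_of[:, None], pep_res_of[None, :]),
                      inside.astype(np.float64))
            acc += counts
    return InterfaceProfile(
        pair_values=acc / traj.n_frames,
        protein_residues=prot_keys,
        peptide_residues=pep_keys,
        cutoff=cutoff,
        condition=condition,
        granularity=granularity,
        n_frames=traj.n_frames,
    )


def peptide_contact_profile(profile: InterfaceProfile) -> np.ndarray:
    """Per-protein-residue summed contact profile (row sums over all
    peptide residues)."""
    return profile.pair_values.sum(axis=1)


def categorize_contacts(
    profile: InterfaceProfile,
    scheme: ResidueClassScheme = DEFAULT_CLASS_SCHEME,
) -> dict[tuple[str, str], float]:
    """Mean interface contacts per frame, broken down by unordered
    residue-class pair.  The values over all class pairs sum to the
    total of the pair matrix (partition identity)."""
    prot_classes = [scheme.classify(k[2]) for k in profile.protein_residues]
    pep_classes = [scheme.classify(k[2]) for k in profile.peptide_residues]
    out: dict[tuple[str, str], float] = {}
    for a in range(len(RESIDUE_CLASSES)):
        for b in range(a, len(RESIDUE_CLASSES)):
            key = tuple(sorted((RESIDUE_CLASSES[a], RESIDUE_CLASSES[b])))
            out[key] = 0.0
    for i, ci in enumerate(prot_classes):
        for j, cj in enumerate(pep_classes):
            key = tuple(sorted((ci, cj)))
            out[key] += float(profile.pair_values[i, j])
    return out


def interface_difference(
    profile_a: InterfaceProfile,
    profile_b: InterfaceProfile,
    scheme: ResidueClassScheme = DEFAULT_CLASS_SCHEME,
) -> tuple[np.ndarray, dict[tuple[str, str], float]]:
    """A - B of the per-protein-residue summed profile and of the
    class-pair table.  Swapping arguments negates both outputs."""
    profile_a.check_comparable(profile_b)
    delta_profile = peptide_contact_profile(profile_a) - peptide_contact_profile(
        profile_b
    )
    cat_a = categorize_contacts(profile_a, scheme)
    cat_b = categorize_contacts(profile_b, scheme)
    delta_classes = {k: cat_a[k] - cat_b[k] for k in cat_a}
    return delta_profile, delta_classes
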