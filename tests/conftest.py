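"""Shared fixtures: planted synthetic ensembles and independent
brute-force oracles used to cross-check the optimized code paths."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from contactdiff import (
    ContactParams,
    PeptideSpec,
    SyntheticSpec,
    contact_matrix,
    generate_ensemble,
    planted_truth,
)

# ---------------------------------------------------------------------------
# Study conditions: a two-condition ensemble with planted probabilities
# covering the 0.1..0.9 grid plus one strong gain (+0.6) and one strong
# loss (-0.5), leaving hundreds of null pairs.
# ---------------------------------------------------------------------------

STUDY_SEED = 20240915
STUDY_PAIRS = [
    (2, 10, {"WT": 0.1, "MUT": 0.1}),
    (4, 12, {"WT": 0.3, "MUT": 0.3}),
    (6, 14, {"WT": 0.5, "MUT": 0.5}),
    (8, 16, {"WT": 0.7, "MUT": 0.7}),
    (3, 18, {"WT": 0.9, "MUT": 0.9}),
    (5, 20, {"WT": 0.2, "MUT": 0.8}),   # gained in MUT
    (7, 22, {"WT": 0.8, "MUT": 0.3}),   # lost in MUT
]


def study_spec(n_frames: int = 10_000, seed: int = STUDY_SEED) -> SyntheticSpec:
    return SyntheticSpec(
        n_residues=40,
        n_frames=n_frames,
        seed=seed,
        planted_pairs=STUDY_PAIRS,
    )


@pytest.fixture(scope="session")
def study():
    """Two-condition 40-residue, 10,000-frame planted ensemble with its
    contact matrices and closed-form truth."""
    spec = study_spec()
    params = ContactParams(mode="CA")
    trajs, mats = {}, {}
    for c in ("WT", "MUT"):
        _, trajs[c] = generate_ensemble(spec, c)
        mats[c] = contact_matrix(trajs[c], params, condition=c)
    return {
        "spec": spec,
        "params": params,
        "trajectories": trajs,
        "matrices": mats,
        "truth": planted_truth(spec),
    }


@pytest.fixture(scope="session")
def small_complex():
    """50-residue protein + 4-residue peptide, 2 atoms/residue,
    200 frames: the oracle-equivalence fixture."""
    spec = SyntheticSpec(
        n_residues=50,
        n_frames=200,
        seed=77,
        atoms_per_residue=2,
        planted_pairs=[
            (5, 20, {"WT": 0.9, "MUT": 0.3}),
            (10, 30, {"WT": 0.4, "MUT": 0.4}),
            (15, 40, {"WT": 0.0, "MUT": 1.0}),
        ],
        peptide=PeptideSpec(
            length=4,
            anchors=(
                (25, 1, {"WT": 1.0, "MUT": 0.4}),
                (35, 3, {"WT": 0.5, "MUT": 0.5}),
            ),
        ),
        d_bound=3.5,
        contact_cutoffs=(8.0, 4.5),
        residue_names=("LEU",) * 50,
        peptide_residue_names=("VAL", "PHE", "ASP", "SER"),
    )
    trajs = {}
    topology = None
    for c in ("WT", "MUT"):
        topology, trajs[c] = generate_ensemble(spec, c)
    return {"spec": spec, "topology": topology, "trajectories": trajs,
            "truth": planted_truth(spec)}


def binomial_bound(p: float, n: int, sigmas: float = 4.0) -> float:
    """4-sigma half-width for an empirical Bernoulli(p) frequency."""
    return sigmas * np.sqrt(p * (1.0 - p) / n)


# ---------------------------------------------------------------------------
# Independent oracles (naive double loops; no shared reduction code with
# the implementation)
# ---------------------------------------------------------------------------

def oracle_residue_distances(coords, topology, mode: str) -> np.ndarray:
    """Single-frame residue distance matrix by explicit pair loops."""
    residues = topology.residues
    n = len(residues)
    out = np.zeros((n, n))
    if mode == "CA":
        ca = []
        for r in residues:
            (idx,) = [a for a in r.atom_indices if topology.atom_names[a] == "CA"]
            ca.append(coords[idx])
        for i in range(n):
            for j in range(n):
                d = ca[i] - ca[j]
                out[i, j] = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        return out
    groups = [
        [a for a in r.atom_indices if topology.elements[a] not in ("H", "D")]
        for r in residues
    ]
    ad = cdist(coords, coords)
    for i in range(n):
        for j in range(n):
            out[i, j] = ad[np.ix_(groups[i], groups[j])].min()
    return out


def oracle_contact_probability(traj, params: ContactParams) -> np.ndarray:
    """Frame-by-frame contact counting, no vectorized reduction."""
    n = traj.topology.n_residues
    counts = np.zeros((n, n))
    for f in range(traj.n_frames):
        d = oracle_residue_distances(traj.coordinates[f], traj.topology, params.mode)
        counts += d <= params.cutoff
    p = counts / traj.n_frames
    np.fill_diagonal(p, np.nan)
    return p


def oracle_interface_frequency(traj, protein_chain, peptide_chain, cutoff):
    """All-atom double loop over the two chains."""
    top = traj.topology
    prot = [r for r in top.residues if r.chain_id == protein_chain]
    pep = [r for r in top.residues if r.chain_id == peptide_chain]
    freq = np.zeros((len(prot), len(pep)))
    for f in range(traj.n_frames):
        c = traj.coordinates[f]
        for i, rp in enumerate(prot):
            ai = [a for a in rp.atom_indices if top.elements[a] not in ("H", "D")]
            for j, rq in enumerate(pep):
                aj = [a for a in rq.atom_indices if top.elements[a] not in ("H", "D")]
                if cdist(c[ai], c[aj]).min() <= cutoff:
                    freq[i, j] += 1
    return freq / traj.n_frames


def oracle_kld_bits(p, q) -> float:
    """One-line closed form sum p * log2(p/q)."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    return float(np.sum(p * np.log2(p / q)))
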