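"""Synthetic multi-condition ensembles with planted contact structure.

The generator encodes a Bernoulli contact process geometrically rather
than simulating dynamics: residues of a single chain sit on a straight
lattice with spacing larger than any contact cutoff, and each *planted*
residue pair (i, j) gets an independent per-frame coin flip with the
condition's probability p.  On a success, residue j's atoms are placed
``d_bound`` Angstrom from residue i along a lane direction unique to
that pair; on a failure they sit ``d_unbound`` away from j's own
lattice site.  Gaussian jitter is added to every coordinate.  Because
the bound/unbound distances bracket every configured cutoff with a
3-sigma jitter margin, the empirical contact probability of a planted
pair is Binomial(F, p)/F and every unplanted pair has probability
exactly zero — so contact matrices, difference maps, per-residue
frequencies, KLD profiles and interface profiles all have closed-form
expected values (:class:`PlantedTruth`).

An optional peptide chain works the same way: anchor pairs (protein
residue, peptide residue) carry per-condition contact probabilities.

Randomness: one stream per (seed, condition), derived as
``default_rng([seed, crc32(condition)])``; draw order is pair-major
(planted pairs in listed order, then anchors in listed order, F
Bernoulli draws each), followed by one Gaussian block for the jitter.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeneratorError, ParameterError
from .trajectory_model import Topology, Trajectory, write_pdb, write_xyz

__all__ = [
    "PlantedPair",
    "PeptideSpec",
    "SyntheticSpec",
    "PlantedTruth",
    "generate_ensemble",
    "planted_truth",
    "write_fixture",
    "read_manifest",
    "PROTEIN_CHAIN",
    "PEPTIDE_CHAIN",
]

PROTEIN_CHAIN = "A"
PEPTIDE_CHAIN = "P"
_CB_OFFSET = np.array([1.5, 0.0, 0.0])  # along the chain axis, so the
# minimum heavy-atom distance of a planted pair equals d_bound exactly


@dataclass(frozen=True)
class PlantedPair:
    """Intra-chain planted contact: residues i < j (1-based), with one
    contact probability per condition label.  Residue j is the mobile
    partner."""

    i: int
    j: int
    p: dict[str, float]


@dataclass(frozen=True)
class PeptideSpec:
    """Optional second chain of ``length`` residues; ``anchors`` are
    (protein residue, peptide residue, {condition: p}) contact sites."""

    length: int
    anchors: tuple = ()


@dataclass(frozen=True)
class SyntheticSpec:
    n_residues: int
    n_frames: int
    seed: int
    atoms_per_residue: int = 1
    chain_spacing: float = 12.0
    planted_pairs: tuple = ()
    peptide: PeptideSpec | None = None
    d_bound: float = 5.0
    d_unbound: float = 20.0
    jitter_sd: float = 0.2
    contact_cutoffs: tuple[float, ...] = (8.0,)
    residue_names: tuple[str, ...] | None = None
    peptide_residue_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_pairs", tuple(
            p if isinstance(p, PlantedPair) else PlantedPair(*p)
            for p in self.planted_pairs
        ))
        if self.peptide is not None and not isinstance(self.peptide, PeptideSpec):
            pep = self.peptide
            object.__setattr__(
                self, "peptide",
                PeptideSpec(length=pep["length"],
                            anchors=tuple(tuple(a) for a in pep["anchors"])),
            )
        _validate_spec(self)

    @property
    def conditions(self) -> tuple[str, ...]:
        labels: dict[str, None] = {}
        for pair in self.planted_pairs:
            labels.update(dict.fromkeys(pair.p))
        if self.peptide is not None:
            for _, _, p in self.peptide.anchors:
                labels.update(dict.fromkeys(p))
        return tuple(labels)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_pairs"] = [
            {"i": p.i, "j": p.j, "p": dict(p.p)} for p in self.planted_pairs
        ]
        if self.peptide is not None:
            d["peptide"] = {
                "length": self.peptide.length,
                "anchors": [
                    {"protein": i, "peptide": k, "p": dict(p)}
                    for i, k, p in self.peptide.anchors
                ],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["planted_pairs"] = tuple(
            PlantedPair(pp["i"], pp["j"], dict(pp["p"]))
            for pp in d.get("planted_pairs", ())
        )
        pep = d.get("peptide")
        if pep is not None:
            d["peptide"] = PeptideSpec(
                length=pep["length"],
                anchors=tuple(
                    (a["protein"], a["peptide"], dict(a["p"]))
                    for a in pep["anchors"]
                ),
            )
        for key in ("contact_cutoffs", "residue_names", "peptide_residue_names"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _validate_spec(spec: SyntheticSpec) -> None:
    if spec.n_residues < 1 or spec.n_frames < 1:
        raise ParameterError("n_residues and n_frames must be >= 1")
    if spec.atoms_per_residue not in (1, 2):
        raise ParameterError("atoms_per_residue must be 1 or 2")
    conditions = None
    used: set[int] = set()
    for pair in spec.planted_pairs:
        if abs(pair.i - pair.j) < 2:
            raise ParameterError(f"planted pair ({pair.i},{pair.j}): need |i-j| >= 2")
        if not (1 <= pair.i <= spec.n_residues and 1 <= pair.j <= spec.n_residues):
            raise ParameterError(f"planted pair ({pair.i},{pair.j}) out of range")
        for r in (pair.i, pair.j):
            if r in used:
                raise ParameterError(
                    f"residue {r} appears in more than one planted pair"
                )
            used.add(r)
        for p in pair.p.values():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0,1]")
        keys = set(pair.p)
        if conditions is None:
            conditions = keys
        elif keys != conditions:
            raise ParameterError("all planted pairs must share condition labels")
    if spec.peptide is not None:
        pep_used: set[int] = set()
        for prot, pepres, p in spec.peptide.anchors:
            if not (1 <= prot <= spec.n_residues):
                raise ParameterError(f"anchor protein residue {prot} out of range")
            if not (1 <= pepres <= spec.peptide.length):
                raise ParameterError(f"anchor peptide residue {pepres} out of range")
            if prot in used:
                raise ParameterError(
                    f"protein residue {prot} is both planted and anchored"
                )
            if pepres in pep_used:
                raise ParameterError(f"peptide residue {pepres} anchored twice")
            pep_used.add(pepres)
            for v in p.values():
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"probability {v} outside [0,1]")
        prots = [a[0] for a in spec.peptide.anchors]
        if len(prots) != len(set(prots)):
            raise ParameterError("anchor protein residues must be distinct")
    margin = 3.0 * spec.jitter_sd
    for cutoff in spec.contact_cutoffs:
        if not (spec.d_bound + margin < cutoff < spec.d_unbound - margin):
            raise ParameterError(
                f"cutoff {cutoff} violates d_bound + 3*jitter < cutoff < "
                f"d_unbound - 3*jitter ({spec.d_bound + margin}, "
                f"{spec.d_unbound - margin})"
            )
    if spec.residue_names is not None and len(spec.residue_names) != spec.n_residues:
        raise ParameterError("residue_names length != n_residues")
    if (
        spec.peptide is not None
        and spec.peptide_residue_names is not None
        and len(spec.peptide_residue_names) != spec.peptide.length
    ):
        raise ParameterError("peptide_residue_names length != peptide length")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _movers(spec: SyntheticSpec) -> list[tuple[str, int, int, dict]]:
    """Mobile entities in draw order: ('protein', i, j, p) for planted
    pairs (j moves), then ('peptide', prot, pepres, p) for anchors."""
    out = [("protein", p.i, p.j, p.p) for p in spec.planted_pairs]
    if spec.peptide is not None:
        out += [("peptide", i, k, p) for i, k, p in spec.peptide.anchors]
    return out


def _lane_direction(m: int, total: int) -> np.ndarray:
    theta = 2.0 * np.pi * m / max(total, 1)
    return np.array([0.0, np.cos(theta), np.sin(theta)])


def _base_layout(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lattice CA positions for protein (R,3) and peptide (M,3)."""
    r = np.arange(spec.n_residues, dtype=np.float64)
    protein = np.stack([r * spec.chain_spacing, np.zeros_like(r), np.zeros_like(r)], axis=1)
    if spec.peptide is None:
        return protein, np.zeros((0, 3))
    m = np.arange(spec.peptide.length, dtype=np.float64)
    pep_y = -(3.0 * spec.d_unbound + 2.0 * max(spec.contact_cutoffs))
    peptide = np.stack([m * spec.chain_spacing, np.full_like(m, pep_y), np.zeros_like(m)], axis=1)
    return protein, peptide


def _candidate_positions(spec: SyntheticSpec) -> list[list[np.ndarray]]:
    """Per residue (protein then peptide, table order): all jitter-free
    CA positions the residue can occupy across frames."""
    protein, peptide = _base_layout(spec)
    cands: list[list[np.ndarray]] = [[p] for p in protein] + [[p] for p in peptide]
    movers = _movers(spec)
    for m, (kind, i, jk, _) in enumerate(movers):
        u = _lane_direction(m, len(movers))
        if kind == "protein":
            idx = jk - 1
            home = protein[idx]
            target = protein[i - 1]
        else:
            idx = spec.n_residues + jk - 1
            home = peptide[jk - 1]
            target = protein[i - 1]
        cands[idx] = [target + spec.d_bound * u, home + spec.d_unbound * u]
    return cands


def _check_geometry(spec: SyntheticSpec) -> None:
    """Jitter-free safety check: no unplanted residue pair may come
    within the largest configured cutoff (plus the 3-sigma jitter
    margin) in any combination of bound/unbound states."""
    cands = _candidate_positions(spec)
    planted = {tuple(sorted((p.i - 1, p.j - 1))) for p in spec.planted_pairs}
    if spec.peptide is not None:
        planted |= {
            (i - 1, spec.n_residues + k - 1) for i, k, _ in spec.peptide.anchors
        }
    limit = max(spec.contact_cutoffs) + 3.0 * spec.jitter_sd + (
        2.0 * np.linalg.norm(_CB_OFFSET) if spec.atoms_per_residue == 2 else 0.0
    )
    n = len(cands)
    for a in range(n):
        for b in range(a + 1, n):
            if (a, b) in planted:
                continue
            dmin = min(
                float(np.linalg.norm(pa - pb))
                for pa in cands[a]
                for pb in cands[b]
            )
            if dmin <= limit:
                raise GeneratorError(
                    f"unplanted residue pair ({a + 1},{b + 1}) can come within "
                    f"{dmin:.2f} A (<= safety limit {limit:.2f} A)"
                )


def _build_topology(spec: SyntheticSpec) -> Topology:
    per = spec.atoms_per_residue
    default = "GLY" if per == 1 else "ALA"
    names, elements, resid, resname, chain = [], [], [], [], []

    def add_chain(n, chain_id, custom):
        for r in range(1, n + 1):
            rn = custom[r - 1] if custom is not None else default
            names.append("CA"); elements.append("C")
            resid.append(r); resname.append(rn); chain.append(chain_id)
            if per == 2:
                names.append("CB"); elements.append("C")
                resid.append(r); resname.append(rn); chain.append(chain_id)

    add_chain(spec.n_residues, PROTEIN_CHAIN, spec.residue_names)
    if spec.peptide is not None:
        add_chain(spec.peptide.length, PEPTIDE_CHAIN, spec.peptide_residue_names)
    masses = np.full(len(names), 12.011)
    return Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        masses=masses,
        residue_indices=np.array(resid, dtype=np.int64),
        residue_names=np.array(resname, dtype=object),
        chain_ids=np.array(chain, dtype=object),
    )


def _rng_for(seed: int, condition: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(condition.encode())])


def generate_ensemble(spec: SyntheticSpec, condition: str) -> tuple[Topology, Trajectory]:
    """Generate the (topology, trajectory) for one condition label.

    Deterministic for a given (spec, seed, condition).  Raises KeyError
    if the condition label is absent from a planted pair or anchor, and
    GeneratorError if the jitter-free layout could produce incidental
    contacts for any unplanted pair.
    """
    _check_geometry(spec)
    topology = _build_topology(spec)
    protein, peptide = _base_layout(spec)
    per = spec.atoms_per_residue
    F = spec.n_frames

    # residue-table order == chain A residues, then chain P residues
    ca_base = np.concatenate([protein, peptide], axis=0)
    n_res_total = ca_base.shape[0]
    ca = np.broadcast_to(ca_base, (F, n_res_total, 3)).copy()

    rng = _rng_for(spec.seed, condition)
    movers = _movers(spec)
    for m, (kind, i, jk, p) in enumerate(movers):
        prob = p[condition]  # KeyError if label missing, per contract
        u = _lane_direction(m, len(movers))
        contact = rng.random(F) < prob
        if kind == "protein":
            idx = jk - 1
            home = protein[jk - 1]
        else:
            idx = spec.n_residues + jk - 1
            home = peptide[jk - 1]
        bound = protein[i - 1] + spec.d_bound * u
        unbound = home + spec.d_unbound * u
        ca[:, idx, :] = np.where(contact[:, None], bound, unbound)

    coords = np.repeat(ca, per, axis=1)
    if per == 2:
        coords[:, 1::2, :] += _CB_OFFSET
    coords += rng.normal(0.0, spec.jitter_sd, coords.shape)
    return topology, Trajectory(topology=topology, coordinates=coords)


# ---------------------------------------------------------------------------
# Closed-form truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTruth:
    """Closed-form expectations for a spec, on the full residue table
    (protein residues first, then peptide residues if present).

    ``kld`` uses the pipeline's own pseudocount/normalization rule
    applied to the exact probability matrices, so it is the F -> inf
    limit of :func:`contactdiff.ensemble_compare.kld_profile`.
    """

    conditions: tuple[str, ...]
    contact_probability: dict[str, np.ndarray]           # (R,R) per condition
    delta: dict[tuple[str, str], np.ndarray]             # A-minus-B
    mean_contacts: dict[str, np.ndarray]                 # per residue
    kld: dict[tuple[str, str], np.ndarray]               # bits per residue
    interface: dict[str, np.ndarray] | None              # (R_protein, M)


def planted_truth(
    spec: SyntheticSpec,
    conditions: tuple[str, ...] | None = None,
    epsilon: float = 1e-4,
) -> PlantedTruth:
    if conditions is None:
        conditions = spec.conditions
    n_pep = spec.peptide.length if spec.peptide is not None else 0
    R = spec.n_residues + n_pep
    pstar: dict[str, np.ndarray] = {}
    for c in conditions:
        P = np.zeros((R, R))
        for pair in spec.planted_pairs:
            if c not in pair.p:
                raise KeyError(f"condition {c!r} absent from planted pair")
            P[pair.i - 1, pair.j - 1] = P[pair.j - 1, pair.i - 1] = pair.p[c]
        if spec.peptide is not None:
            for i, k, p in spec.peptide.anchors:
                if c not in p:
                    raise KeyError(f"condition {c!r} absent from anchor")
                a, b = i - 1, spec.n_residues + k - 1
                P[a, b] = P[b, a] = p[c]
        pstar[c] = P
    delta = {
        (a, b): pstar[a] - pstar[b]
        for a in conditions for b in conditions if a != b
    }
    mean_contacts = {c: pstar[c].sum(axis=1) for c in conditions}
    from .ensemble_compare import _kld_from_probability_matrices

    kld = {
        (a, b): _kld_from_probability_matrices(pstar[a], pstar[b], epsilon)
        for a in conditions for b in conditions if a != b
    }
    interface = None
    if spec.peptide is not None:
        interface = {
            c: pstar[c][: spec.n_residues, spec.n_residues:] for c in conditions
        }
    return PlantedTruth(
        conditions=tuple(conditions),
        contact_probability=pstar,
        delta=delta,
        mean_contacts=mean_contacts,
        kld=kld,
        interface=interface,
    )


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def write_fixture(
    topology: Topology,
    trajectories: dict[str, Trajectory],
    directory: str | Path,
    spec: SyntheticSpec | None = None,
    trajectory_format: str = "pdb",
) -> dict:
    """Write a topology PDB, one coordinate file per condition, and a
    JSON manifest recording the spec (if given), seed and file names.
    I/O failures (unwritable directory, ...) propagate as OSError."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if trajectory_format not in ("pdb", "xyz"):
        raise ParameterError(f"unknown trajectory format {trajectory_format!r}")
    top_path = directory / "topology.pdb"
    write_pdb(topology, trajectories[next(iter(trajectories))].coordinates[0], top_path)
    manifest = {
        "topology": top_path.name,
        "trajectory_format": trajectory_format,
        "conditions": {},
        "spec": spec.to_dict() if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
    }
    for label, traj in trajectories.items():
        fname = f"traj_{label}.{trajectory_format}"
        writer = write_pdb if trajectory_format == "pdb" else write_xyz
        writer(topology, traj.coordinates, directory / fname)
        manifest["conditions"][label] = fname
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_manifest(path: str | Path) -> tuple[dict, SyntheticSpec | None]:
    """Load a fixture manifest; returns (manifest dict, spec or None)."""
    with open(path) as fh:
        manifest = json.load(fh)
    spec = None
    if manifest.get("spec") is not None:
        spec = SyntheticSpec.from_dict(manifest["spec"])
    return manifest, spec
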