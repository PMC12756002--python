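"""Domain-wise aggregation of residue-level contacts.

Residues are grouped into user-defined functional domains (for Sis1:
the J-domain, the G/F-rich and G/M-rich linkers, and the C-terminal
beta-sandwich), and contacts are summed per domain pair and normalized
by the frame count.  Because averaging is linear, summing entries of
the contact-probability matrix over a domain block equals counting the
block's contacts frame by frame and dividing by F; both routes are
exposed and must agree exactly.

The shipped Sis1 map is a convenience default: the J-domain boundary
(residues 1-75) is well established, while the GF/GM/CTD boundaries
are approximate and should be overridden with system-specific values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import CompatibilityError, MappingError, ParameterError
from .contact_core import ContactMatrix, ContactParams, contact_matrix
from .trajectory_model import Trajectory

__all__ = [
    "DomainMap",
    "DomainContactTable",
    "default_sis1_domains",
    "domain_contact_table",
    "domain_difference",
    "motif_contact_profile",
]

logger = logging.getLogger("contactdiff")


@dataclass(frozen=True)
class DomainMap:
    """Ordered (label, start, end) entries, 1-based inclusive residue
    ranges in author numbering; optionally restricted to one chain."""

    entries: tuple[tuple[str, int, int], ...]
    chain_id: str | None = None

    def __post_init__(self) -> None:
        entries = tuple((str(l), int(s), int(e)) for l, s, e in self.entries)
        object.__setattr__(self, "entries", entries)
        labels = [e[0] for e in entries]
        if len(labels) != len(set(labels)):
            raise ParameterError("domain labels must be unique")
        for label, start, end in entries:
            if start > end:
                raise ParameterError(f"domain {label}: start {start} > end {end}")
        spans = sorted((s, e, l) for l, s, e in entries)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ParameterError(f"domains {l1} and {l2} overlap")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def assign(self, residues: tuple[tuple[str, int, str], ...]) -> np.ndarray:
        """Domain index per residue-table position; -1 where unmapped.
        Unmapped residues are reported via the package logger."""
        out = np.full(len(residues), -1, dtype=np.intp)
        for pos, (chain, resseq, _name) in enumerate(residues):
            if self.chain_id is not None and chain != self.chain_id:
                continue
            for d, (_label, start, end) in enumerate(self.entries):
                if start <= resseq <= end:
                    out[pos] = d
                    break
        unmapped = int((out < 0).sum())
        if unmapped:
            logger.info("%d residues fall outside the domain map", unmapped)
        return out

    def residues_of(
        self, label: str, residues: tuple[tuple[str, int, str], ...]
    ) -> np.ndarray:
        if label not in self.labels:
            raise MappingError(f"unknown domain label {label!r}")
        d = self.labels.index(label)
        return np.flatnonzero(self.assign(residues) == d)


def default_sis1_domains() -> DomainMap:
    """Approximate Sis1 domain boundaries.  J = 1-75 is well anchored;
    GF/GM/CTD splits are consistent with known sub-elements (GF helix
    ~107-119, GM stretch ~130-138, CTD client/EEVD sites 180-257) but
    should be treated as configuration, not ground truth."""
    return DomainMap(
        entries=(
            ("J", 1, 75),
            ("GF", 76, 121),
            ("GM", 122, 178),
            ("CTD", 179, 352),
        )
    )


@dataclass(frozen=True)
class DomainContactTable:
    """D x D per-frame-normalized summed contacts; diagonal entries
    count each intra-domain unordered pair once."""

    values: np.ndarray
    domain_map: DomainMap
    params: ContactParams
    condition: str

    @property
    def labels(self) -> tuple[str, ...]:
        return self.domain_map.labels

    @property
    def total(self) -> float:
        """Sum over unordered domain blocks == total mean contacts per
        frame among mapped residues (conservation identity)."""
        upper = np.triu(self.values, k=1).sum()
        return float(upper + np.trace(self.values))

    def check_comparable(self, other: "DomainContactTable") -> None:
        if self.domain_map != other.domain_map:
            raise CompatibilityError("domain maps differ")
        if self.params != other.params:
            raise CompatibilityError("contact parameters differ")


def _as_probability_matrix(
    source: Trajectory | ContactMatrix,
    params: ContactParams | None,
    condition: str,
) -> ContactMatrix:
    if isinstance(source, ContactMatrix):
        return source
    if params is None:
        raise ParameterError("params required when passing a trajectory")
    return contact_matrix(source, params, condition=condition)


def domain_contact_table(
    source: Trajectory | ContactMatrix,
    domain_map: DomainMap,
    params: ContactParams | None = None,
    condition: str = "",
) -> DomainContactTable:
    """Sum contact probabilities over domain blocks.

    Entry (d1, d2), d1 != d2, is the mean number of cross-domain
    contacts per frame; entry (d, d) the mean number of intra-domain
    contacts, each unordered pair counted once.
    """
    mat = _as_probability_matrix(source, params, condition)
    assign = domain_map.assign(mat.residues)
    if (assign < 0).all():
        raise MappingError("domain map matches no residue in the topology")
    ndom = len(domain_map.labels)
    p = np.where(mat.defined, mat.values, 0.0)
    table = np.zeros((ndom, ndom))
    n = mat.n_residues
    for i in range(n):
        di = assign[i]
        if di < 0:
            continue
        for j in range(i + 1, n):
            dj = assign[j]
            if dj < 0:
                continue
            if di == dj:
                table[di, di] += p[i, j]
            else:
                table[di, dj] += p[i, j]
                table[dj, di] += p[i, j]
    return DomainContactTable(
        values=table,
        domain_map=domain_map,
        params=mat.params,
        condition=mat.condition or condition,
    )


def domain_difference(
    table_a: DomainContactTable, table_b: DomainContactTable
) -> np.ndarray:
    """A - B on matching domain tables (antisymmetric under swap)."""
    table_a.check_comparable(table_b)
    return table_a.values - table_b.values


def motif_contact_profile(
    source: Trajectory | ContactMatrix,
    motif: set[int] | tuple[int, ...],
    target: str,
    domain_map: DomainMap,
    params: ContactParams | None = None,
    condition: str = "",
) -> float:
    """Mean contacts per frame between a motif (resSeq set, e.g. the
    HPD tripeptide 31-33) and one target domain; each unordered residue
    pair counts once."""
    if not motif:
        raise ParameterError("motif residue set is empty")
    mat = _as_probability_matrix(source, params, condition)
    resseq = {key[1] for key in mat.residues}
    missing = set(motif) - resseq
    if missing:
        raise MappingError(f"motif residues absent from topology: {sorted(missing)}")
    motif_pos = [
        pos for pos, key in enumerate(mat.residues) if key[1] in set(motif)
        and (domain_map.chain_id is None or key[0] == domain_map.chain_id)
    ]
    target_pos = set(domain_map.residues_of(target, mat.residues).tolist())
    p = np.where(mat.defined, mat.values, 0.0)
    seen: set[tuple[int, int]] = set()
    total = 0.0
    for i in motif_pos:
        for j in target_pos:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            total += p[key]
    return float(total)
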