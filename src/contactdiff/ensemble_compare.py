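"""Condition-vs-condition ensemble statistics.

Given contact matrices for two conditions A and B on the same residue
table, this module computes:

* the difference map dP = P_A - P_B (antisymmetric in its arguments),
* a significance mask |dP| >= tau_sig (default 0.2, inclusive),
* gained / lost contact calls with strict two-sided thresholds
  (gain: dP > +0.3, loss: dP < -0.3),
* a persistence rule: a called contact must be present in more than a
  given fraction (default 50%) of the frames of the condition in which
  it exists (A for gains, B for losses),
* per-residue Kullback-Leibler divergence (bits) between the two
  conditions' contact-probability distributions, with peak calling at
  0.1 bits, and
* per-residue mean contacts per frame.

The per-residue divergence (default rule) sums, over a residue's
partners, the KL divergence between the binary contact/no-contact
distributions of the two conditions, after pseudocount smoothing
p -> (p + eps)/(1 + 2 eps) with eps = 1e-4.  This registers both
redistribution of a residue's partners and outright gain or loss of
contact mass; residues with identical rows come out at exactly 0 bits.
An alternative rule ("partners") normalizes each residue's smoothed
partner vector to sum 1 within its condition and compares the resulting
categorical distributions — sensitive to redistribution only.  The
divergence is directional, KLD(A||B); by convention A is the perturbed
(mutant) condition and B the reference.  A symmetrized Jensen-Shannon
variant of either rule is available but not the default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import rel_entr

from .errors import CompatibilityError, KindError, ParameterError
from .contact_core import (
    ContactMatrix,
    ContactParams,
    ContactSeries,
    contact_matrix,
)
from .trajectory_model import Trajectory

__all__ = [
    "DifferenceMap",
    "CategoricalContactMap",
    "PersistenceResult",
    "KLDProfile",
    "ResidueContactProfile",
    "difference_map",
    "filter_significant",
    "gain_loss_map",
    "persistence_filter",
    "kld_bits",
    "kld_profile",
    "residue_contact_frequency",
]

logger = logging.getLogger("contactdiff")

TAU_SIGNIFICANT = 0.2
TAU_GAIN = 0.3
TAU_LOSS = -0.3
PERSISTENCE_FRACTION = 0.5
KLD_EPSILON = 1e-4
KLD_PEAK_BITS = 0.1

GAINED, UNCHANGED, LOST = 1, 0, -1


@dataclass(frozen=True)
class DifferenceMap:
    """A-minus-B matrix with optional significance mask."""

    values: np.ndarray
    value_kind: str
    condition_a: str
    condition_b: str
    params: ContactParams
    residues: tuple
    tau_significant: float | None = None
    significant: np.ndarray | None = None

    @property
    def orientation(self) -> str:
        return f"{self.condition_a}_minus_{self.condition_b}"

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def filtered_values(self) -> np.ndarray:
        """Copy with non-significant entries zeroed (export variant)."""
        if self.significant is None:
            raise ParameterError("no significance mask: run filter_significant first")
        return np.where(self.significant, self.values, 0.0)


@dataclass(frozen=True)
class CategoricalContactMap:
    """Gain/loss calls: +1 gained, -1 lost, 0 unchanged (per pair)."""

    categories: np.ndarray  # (R, R) int8
    tau_gain: float
    tau_loss: float
    condition_a: str
    condition_b: str
    params: ContactParams
    residues: tuple

    def pairs_in_category(self, category: int) -> list[tuple[int, int]]:
        out = []
        n = self.categories.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if self.categories[i, j] == category:
                    out.append((i, j))
        return out

    @property
    def gained_pairs(self) -> list[tuple[int, int]]:
        return self.pairs_in_category(GAINED)

    @property
    def lost_pairs(self) -> list[tuple[int, int]]:
        return self.pairs_in_category(LOST)


@dataclass(frozen=True)
class PersistenceResult:
    """Per called pair: occupancies in both conditions and whether the
    pair persists in the condition in which the contact exists."""

    fraction: float
    passed: dict[tuple[int, int], bool]
    occupancy_a: dict[tuple[int, int], float]
    occupancy_b: dict[tuple[int, int], float]

    def passing_pairs(self) -> list[tuple[int, int]]:
        return [p for p, ok in self.passed.items() if ok]


@dataclass(frozen=True)
class KLDProfile:
    """Per-residue divergence (bits) with peak calls."""

    values: np.ndarray
    epsilon: float
    tau_peak: float
    condition_a: str
    condition_b: str
    residues: tuple

    @property
    def peaks(self) -> np.ndarray:
        return np.flatnonzero(self.values > self.tau_peak)


@dataclass(frozen=True)
class ResidueContactProfile:
    """Mean number of contacts formed per frame, per residue."""

    values: np.ndarray
    params: ContactParams
    condition: str
    residues: tuple

    @property
    def mean_total_contacts_per_frame(self) -> float:
        return float(self.values.sum() / 2.0)


# ---------------------------------------------------------------------------
# Difference maps and calls
# ---------------------------------------------------------------------------

def difference_map(mat_a: ContactMatrix, mat_b: ContactMatrix) -> DifferenceMap:
    """Elementwise A - B on matrices sharing residue table, parameters
    and value kind.  For mean-distance maps a positive entry means the
    pair sits farther apart in A (contact loss in A)."""
    mat_a.check_comparable(mat_b)
    return DifferenceMap(
        values=mat_a.values - mat_b.values,
        value_kind=mat_a.value_kind,
        condition_a=mat_a.condition,
        condition_b=mat_b.condition,
        params=mat_a.params,
        residues=mat_a.residues,
    )


def filter_significant(
    diff: DifferenceMap, tau_sig: float = TAU_SIGNIFICANT
) -> DifferenceMap:
    """Mark pairs with |dP| >= tau_sig (inclusive).  Values are kept;
    the zeroed variant is available via ``filtered_values``."""
    if diff.value_kind != "probability":
        raise KindError("significance filtering applies to probability maps only")
    if not 0 < tau_sig <= 1:
        raise ParameterError(f"tau_sig must be in (0, 1], got {tau_sig}")
    with np.errstate(invalid="ignore"):
        mask = np.abs(diff.values) >= tau_sig
    mask &= diff.defined
    return replace(diff, tau_significant=tau_sig, significant=mask)


def gain_loss_map(
    diff: DifferenceMap,
    tau_gain: float = TAU_GAIN,
    tau_loss: float = TAU_LOSS,
) -> CategoricalContactMap:
    """Strict two-sided calls: gained if dP > tau_gain, lost if
    dP < tau_loss, else unchanged (boundary values are unchanged)."""
    if diff.value_kind != "probability":
        raise KindError("gain/loss calling applies to probability maps only")
    if tau_gain <= 0:
        raise ParameterError(f"tau_gain must be > 0, got {tau_gain}")
    if tau_loss >= 0:
        raise ParameterError(f"tau_loss must be < 0, got {tau_loss}")
    cats = np.zeros(diff.values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        cats[diff.values > tau_gain] = GAINED
        cats[diff.values < tau_loss] = LOST
    return CategoricalContactMap(
        categories=cats,
        tau_gain=tau_gain,
        tau_loss=tau_loss,
        condition_a=diff.condition_a,
        condition_b=diff.condition_b,
        params=diff.params,
        residues=diff.residues,
    )


def persistence_filter(
    series_a: ContactSeries,
    series_b: ContactSeries,
    categorical: CategoricalContactMap,
    fraction: float = PERSISTENCE_FRACTION,
) -> PersistenceResult:
    """A gained pair passes iff it is in contact in more than
    ``fraction`` of condition-A frames; a lost pair iff in more than
    ``fraction`` of condition-B frames (strict inequality: occupancy
    exactly at the fraction fails)."""
    if not 0 <= fraction < 1:
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    passed: dict[tuple[int, int], bool] = {}
    occ_a: dict[tuple[int, int], float] = {}
    occ_b: dict[tuple[int, int], float] = {}
    for i, j in categorical.gained_pairs + categorical.lost_pairs:
        pa = series_a.occupancy(i, j)
        pb = series_b.occupancy(i, j)
        occ_a[(i, j)], occ_b[(i, j)] = pa, pb
        if categorical.categories[i, j] == GAINED:
            passed[(i, j)] = pa > fraction
        else:
            passed[(i, j)] = pb > fraction
        if not passed[(i, j)]:
            logger.info(
                "pair %s fails persistence: occupancy A=%.3f B=%.3f (> %.2f required)",
                (i, j), pa, pb, fraction,
            )
    return PersistenceResult(
        fraction=fraction, passed=passed, occupancy_a=occ_a, occupancy_b=occ_b
    )


# ---------------------------------------------------------------------------
# KLD profile
# ---------------------------------------------------------------------------

def kld_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Categorical Kullback-Leibler divergence sum_k p_k log2(p_k/q_k)
    in bits, for two already-normalized distributions."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    return float(rel_entr(p, q).sum() / np.log(2))


def _kld_from_probability_matrices(
    pa: np.ndarray,
    pb: np.ndarray,
    epsilon: float = KLD_EPSILON,
    symmetrized: bool = False,
    method: str = "bernoulli",
) -> np.ndarray:
    """Per-residue KLD (bits) between two contact-probability matrices.

    Row i of each matrix is residue i's contact-probability vector over
    partner residues; entries undefined in either matrix (NaN) are
    dropped from both.

    ``bernoulli`` (default): each partner's contact indicator is a
    Bernoulli distribution; the residue's divergence is the sum over
    partners of KL((p, 1-p) || (q, 1-q)) after pseudocount smoothing
    p -> (p + eps) / (1 + 2 eps).  Sensitive to the magnitude of
    probability changes, so a lost or gained contact registers.

    ``partners``: each residue's vector plus eps is normalized to sum 1
    within its condition and compared categorically.  Sensitive only to
    the *relative* distribution over partners, not to overall contact
    gain/loss.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    if method not in ("bernoulli", "partners"):
        raise ParameterError(f"unknown KLD method {method!r}")
    n = pa.shape[0]
    out = np.zeros(n)
    defined = ~(np.isnan(pa) | np.isnan(pb))
    np.fill_diagonal(defined, False)
    if method == "bernoulli":
        p = (np.where(defined, pa, 0.0) + epsilon) / (1.0 + 2.0 * epsilon)
        q = (np.where(defined, pb, 0.0) + epsilon) / (1.0 + 2.0 * epsilon)
        if symmetrized:
            m = 0.5 * (p + q)
            terms = 0.5 * (
                rel_entr(p, m) + rel_entr(1 - p, 1 - m)
                + rel_entr(q, m) + rel_entr(1 - q, 1 - m)
            )
        else:
            terms = rel_entr(p, q) + rel_entr(1 - p, 1 - q)
        out = np.where(defined, terms, 0.0).sum(axis=1) / np.log(2)
        return out
    for i in range(n):
        sel = defined[i]
        if not sel.any():
            logger.info("residue %d has no defined partners; KLD set to 0", i)
            continue
        p = pa[i, sel] + epsilon
        q = pb[i, sel] + epsilon
        p = p / p.sum()
        q = q / q.sum()
        if symmetrized:
            m = 0.5 * (p + q)
            out[i] = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / np.log(2)
        else:
            out[i] = kld_bits(p, q)
    return out


def kld_profile(
    mat_a: ContactMatrix,
    mat_b: ContactMatrix,
    epsilon: float = KLD_EPSILON,
    tau_peak: float = KLD_PEAK_BITS,
    symmetrized: bool = False,
    method: str = "bernoulli",
) -> KLDProfile:
    """Per-residue KLD(A||B) in bits on two probability matrices; peaks
    are residues exceeding ``tau_peak`` bits (strict).  See
    ``_kld_from_probability_matrices`` for the two divergence rules."""
    mat_a.check_comparable(mat_b)
    if mat_a.value_kind != "probability":
        raise KindError("KLD applies to probability maps only")
    values = _kld_from_probability_matrices(
        mat_a.values, mat_b.values, epsilon, symmetrized, method
    )
    return KLDProfile(
        values=values,
        epsilon=epsilon,
        tau_peak=tau_peak,
        condition_a=mat_a.condition,
        condition_b=mat_b.condition,
        residues=mat_a.residues,
    )


# ---------------------------------------------------------------------------
# Per-residue contact frequency
# ---------------------------------------------------------------------------

def residue_contact_frequency(
    source: Trajectory | ContactMatrix,
    params: ContactParams | None = None,
    condition: str = "",
) -> ResidueContactProfile:
    """Mean number of contacts a residue forms per frame.

    By linearity of the mean this equals the row sum of the
    contact-probability matrix, so a precomputed matrix is accepted in
    place of a trajectory.
    """
    if isinstance(source, ContactMatrix):
        mat = source
        if mat.value_kind != "probability":
            raise KindError("contact frequency needs a probability matrix")
    else:
        if params is None:
            raise ParameterError("params required when passing a trajectory")
        mat = contact_matrix(source, params, condition=condition)
    values = np.where(mat.defined, mat.values, 0.0).sum(axis=1)
    return ResidueContactProfile(
        values=values,
        params=mat.params,
        condition=mat.condition or condition,
        residues=mat.residues,
    )
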