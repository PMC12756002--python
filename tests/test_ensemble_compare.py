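"""Difference maps, gain/loss calling, persistence, KLD, frequencies."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactdiff import (
    ContactMatrix,
    ContactParams,
    contact_series,
    difference_map,
    filter_significant,
    gain_loss_map,
    kld_profile,
    persistence_filter,
    residue_contact_frequency,
)
from contactdiff.ensemble_compare import GAINED, LOST, kld_bits
from contactdiff.errors import KindError, ParameterError
from conftest import binomial_bound, oracle_kld_bits


def _matrix(values, condition="A", kind="probability", params=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    vals = values.copy()
    np.fill_diagonal(vals, np.nan)
    return ContactMatrix(
        values=vals,
        value_kind=kind,
        params=params or ContactParams(mode="CA"),
        condition=condition,
        n_frames=100,
        residues=tuple(("A", k + 1, "GLY") for k in range(n)),
    )


def _sym(n, entries):
    m = np.zeros((n, n))
    for i, j, v in entries:
        m[i, j] = m[j, i] = v
    return m


class TestDifferenceMap:
    def test_self_difference_is_zero(self, study):
        d = difference_map(study["matrices"]["WT"], study["matrices"]["WT"])
        assert np.all(np.nan_to_num(d.values) == 0.0)

    def test_swap_negates_exactly(self, study):
        ab = difference_map(study["matrices"]["MUT"], study["matrices"]["WT"])
        ba = difference_map(study["matrices"]["WT"], study["matrices"]["MUT"])
        assert np.array_equal(np.nan_to_num(ab.values), -np.nan_to_num(ba.values))
        assert ab.orientation == "MUT_minus_WT"

    def test_planted_delta_recovery(self, study):
        """dP at the planted gain/loss pairs within the 4-sigma bound for
        a difference of two binomial proportions; near zero elsewhere."""
        spec = study["spec"]
        F = spec.n_frames
        d = difference_map(study["matrices"]["MUT"], study["matrices"]["WT"])
        truth = study["truth"].delta[("MUT", "WT")]
        for pair in spec.planted_pairs:
            i, j = pair.i - 1, pair.j - 1
            pa, pb = pair.p["MUT"], pair.p["WT"]
            bound = 4 * np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / F)
            assert abs(d.values[i, j] - truth[i, j]) <= max(bound, 1e-12)
        resid = np.nan_to_num(d.values - truth)
        assert np.abs(resid).max() <= 0.026

    def test_incompatible_matrices_rejected(self, study):
        other = _matrix(np.zeros((3, 3)))
        from contactdiff.errors import CompatibilityError

        with pytest.raises(CompatibilityError):
            difference_map(study["matrices"]["WT"], other)


class TestSignificanceFilter:
    def test_threshold_is_inclusive(self):
        a = _matrix(_sym(4, [(0, 2, 0.20), (1, 3, 0.19)]), "A")
        b = _matrix(np.zeros((4, 4)), "B")
        d = filter_significant(difference_map(a, b), 0.2)
        assert d.significant[0, 2]
        assert not d.significant[1, 3]
        assert d.filtered_values()[1, 3] == 0.0
        assert d.filtered_values()[0, 2] == pytest.approx(0.2)

    def test_wrong_kind_rejected(self, study):
        a = _matrix(np.zeros((4, 4)), kind="mean_distance")
        b = _matrix(np.zeros((4, 4)), "B", kind="mean_distance")
        with pytest.raises(KindError):
            filter_significant(difference_map(a, b))


class TestGainLoss:
    def test_boundary_is_strict(self):
        a = _matrix(_sym(5, [(0, 2, 0.30), (1, 3, 0.31)]), "A")
        b = _matrix(np.zeros((5, 5)), "B")
        cat = gain_loss_map(difference_map(a, b))
        assert cat.categories[0, 2] == 0  # dP = +0.30 exactly: unchanged
        assert cat.categories[1, 3] == GAINED
        neg = gain_loss_map(difference_map(b, a))
        assert neg.categories[1, 3] == LOST  # swap flips gained <-> lost

    def test_invalid_thresholds(self):
        a = _matrix(np.zeros((3, 3)), "A")
        d = difference_map(a, _matrix(np.zeros((3, 3)), "B"))
        with pytest.raises(ParameterError):
            gain_loss_map(d, tau_gain=-0.1)
        with pytest.raises(ParameterError):
            gain_loss_map(d, tau_loss=0.1)

    def test_planted_gain_loss_perfect_recovery(self, study):
        """100% precision and recall for the planted +0.6 gain and -0.5
        loss among hundreds of null pairs."""
        d = difference_map(study["matrices"]["MUT"], study["matrices"]["WT"])
        cat = gain_loss_map(d)
        assert cat.gained_pairs == [(4, 19)]
        assert cat.lost_pairs == [(6, 21)]


class TestPersistence:
    def _cat(self, pairs_gained, pairs_lost, n):
        cats = np.zeros((n, n), dtype=np.int8)
        for i, j in pairs_gained:
            cats[i, j] = cats[j, i] = GAINED
        for i, j in pairs_lost:
            cats[i, j] = cats[j, i] = LOST
        return cats

    def _series(self, pair, frac, n_frames=10, n=8, condition="A"):
        from contactdiff.contact_core import ContactSeries

        ind = np.zeros((1, n_frames), dtype=bool)
        ind[0, : int(round(frac * n_frames))] = True
        return ContactSeries(
            pairs=(pair,),
            indicators=ind,
            distances=np.where(ind, 5.0, 20.0),
            params=ContactParams(mode="CA"),
            condition=condition,
            residues=tuple(("A", k + 1, "GLY") for k in range(n)),
        )

    def _make(self, occ_a, occ_b, category):
        from contactdiff.ensemble_compare import CategoricalContactMap

        pair = (1, 5)
        cat = CategoricalContactMap(
            categories=self._cat(
                [pair] if category == GAINED else [],
                [pair] if category == LOST else [], 8,
            ),
            tau_gain=0.3, tau_loss=-0.3,
            condition_a="A", condition_b="B",
            params=ContactParams(mode="CA"),
            residues=tuple(("A", k + 1, "GLY") for k in range(8)),
        )
        return persistence_filter(
            self._series(pair, occ_a), self._series(pair, occ_b, condition="B"), cat
        )

    def test_gained_pair_with_high_occupancy_passes(self):
        assert self._make(0.9, 0.1, GAINED).passed[(1, 5)]

    def test_gained_pair_below_half_fails(self):
        res = self._make(0.4, 0.0, GAINED)
        assert not res.passed[(1, 5)]
        assert res.occupancy_a[(1, 5)] == pytest.approx(0.4)

    def test_boundary_exactly_half_fails(self):
        assert not self._make(0.5, 0.0, GAINED).passed[(1, 5)]

    def test_lost_pair_judged_on_reference_condition(self):
        assert self._make(0.0, 0.8, LOST).passed[(1, 5)]
        assert not self._make(0.0, 0.5, LOST).passed[(1, 5)]

    def test_planted_calls_pass_persistence(self, study):
        d = difference_map(study["matrices"]["MUT"], study["matrices"]["WT"])
        cat = gain_loss_map(d)
        called = cat.gained_pairs + cat.lost_pairs
        sa = contact_series(study["trajectories"]["MUT"], study["params"], called)
        sb = contact_series(study["trajectories"]["WT"], study["params"], called)
        res = persistence_filter(sa, sb, cat)
        assert all(res.passed.values())


class TestKLD:
    def test_identical_matrices_give_zero(self, study):
        k = kld_profile(study["matrices"]["WT"], study["matrices"]["WT"])
        assert np.abs(k.values).max() <= 1e-12

    def test_toy_distributions_match_closed_form(self):
        got = kld_bits([0.5, 0.5], [0.9, 0.1])
        want = oracle_kld_bits([0.5, 0.5], [0.9, 0.1])
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.7370, abs=1e-4)

    def test_planted_residues_are_the_only_peaks(self, study):
        k = kld_profile(study["matrices"]["MUT"], study["matrices"]["WT"])
        assert set(k.peaks.tolist()) == {4, 19, 6, 21}
        others = np.delete(k.values, [4, 19, 6, 21])
        assert others.max() <= 1e-3

    def test_truth_consistency(self, study):
        """Measured per-residue KLD approaches the closed-form planted
        value at the divergent residues."""
        k = kld_profile(study["matrices"]["MUT"], study["matrices"]["WT"])
        truth = study["truth"].kld[("MUT", "WT")]
        assert k.values[4] == pytest.approx(truth[4], rel=0.15)
        assert k.values[21] == pytest.approx(truth[21], rel=0.15)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegativity_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pa = _sym(n, [(i, j, rng.random()) for i in range(n) for j in range(i + 1, n)])
        pb = _sym(n, [(i, j, rng.random()) for i in range(n) for j in range(i + 1, n)])
        k = kld_profile(_matrix(pa, "A"), _matrix(pb, "B"))
        assert np.all(k.values >= 0.0)

    def test_partners_method_ignores_uniform_scaling(self):
        """The row-normalized variant sees only redistribution: scaling a
        residue's whole partner vector changes bernoulli KLD but not the
        partners KLD (up to pseudocount effects)."""
        n = 6
        pa = _sym(n, [(0, 2, 0.8), (0, 4, 0.4)])
        pb = _sym(n, [(0, 2, 0.4), (0, 4, 0.2)])
        kp = kld_profile(_matrix(pa, "A"), _matrix(pb, "B"), method="partners")
        kb = kld_profile(_matrix(pa, "A"), _matrix(pb, "B"), method="bernoulli")
        assert kp.values[0] <= 0.01
        assert kb.values[0] > 0.1

    def test_mean_distance_input_rejected(self):
        a = _matrix(np.zeros((3, 3)), "A", kind="mean_distance")
        b = _matrix(np.zeros((3, 3)), "B", kind="mean_distance")
        with pytest.raises(KindError):
            kld_profile(a, b)


class TestResidueContactFrequency:
    def test_planted_certain_contact_gives_one(self, small_complex):
        params = ContactParams(mode="CA", cutoff=8.0)
        prof = residue_contact_frequency(
            small_complex["trajectories"]["MUT"], params
        )
        # pair (15, 40) is planted at p = 1.0 in MUT
        assert prof.values[14] == 1.0
        assert prof.values[39] == 1.0

    def test_matches_planted_sum(self, study):
        prof = residue_contact_frequency(study["matrices"]["WT"])
        truth = study["truth"].mean_contacts["WT"]
        F = study["spec"].n_frames
        for r in range(len(truth)):
            p = truth[r]
            assert abs(prof.values[r] - p) <= max(binomial_bound(p, F), 1e-12)

    def test_double_counting_identity(self, study):
        """Sum over residues equals exactly twice the mean number of
        contacts per frame."""
        mat = study["matrices"]["MUT"]
        prof = residue_contact_frequency(mat)
        total_pair_prob = np.nansum(np.triu(mat.values, k=1))
        assert prof.values.sum() == pytest.approx(2.0 * total_pair_prob, abs=1e-12)
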