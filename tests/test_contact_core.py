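"""Distance matrices and contact statistics against naive oracles."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from contactdiff import (
    ContactParams,
    Topology,
    Trajectory,
    contact_matrix,
    contact_series,
    mean_distance_matrix,
    residue_distance_matrix,
)
from contactdiff.errors import ParameterError, StructuralError
from conftest import oracle_contact_probability, oracle_residue_distances


def _system(atom_xyz, residue_of, names=None, elements=None):
    """Tiny hand-built system; residue_of is 1-based per atom."""
    atom_xyz = np.asarray(atom_xyz, dtype=float)
    n = atom_xyz.shape[0]
    names = names or ["CA"] * n
    elements = elements or ["C"] * n
    top = Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        masses=np.full(n, 12.011),
        residue_indices=np.asarray(residue_of, dtype=np.int64),
        residue_names=np.array(["GLY"] * n, dtype=object),
        chain_ids=np.array(["A"] * n, dtype=object),
    )
    return Trajectory(topology=top, coordinates=atom_xyz[None])


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        traj = _system([[0, 0, 0], [3, 4, 0]], [1, 2])
        d = residue_distance_matrix(
            traj.coordinates[0], traj.topology, ContactParams(mode="CA")
        )
        assert d[0, 1] == pytest.approx(5.0)

    def test_heavy_mode_takes_minimum_over_atom_pairs(self):
        traj = _system(
            [[0, 0, 0], [2, 0, 0], [6, 0, 0]],
            [1, 1, 2],
            names=["CA", "CB", "CA"],
        )
        d = residue_distance_matrix(
            traj.coordinates[0], traj.topology, ContactParams(mode="heavy")
        )
        assert d[0, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("mode", ["CA", "heavy"])
    def test_random_frame_equals_brute_force(self, small_complex, mode):
        traj = small_complex["trajectories"]["WT"]
        params = ContactParams(mode=mode)
        got = residue_distance_matrix(traj.coordinates[0], traj.topology, params)
        want = oracle_residue_distances(traj.coordinates[0], traj.topology, mode)
        np.fill_diagonal(got, 0.0)
        assert np.allclose(got, want, atol=1e-10, rtol=0)

    def test_missing_ca_names_residue(self):
        traj = _system([[0, 0, 0], [5, 0, 0]], [1, 2], names=["CA", "CB"])
        with pytest.raises(StructuralError, match="GLY2"):
            residue_distance_matrix(
                traj.coordinates[0], traj.topology, ContactParams(mode="CA")
            )


class TestContactMatrix:
    def test_probability_is_mean_of_indicator_series(self, study):
        traj = study["trajectories"]["WT"]
        mat = study["matrices"]["WT"]
        pairs = [(1, 9), (4, 19), (6, 21), (0, 1)]
        series = contact_series(traj, study["params"], pairs)
        for i, j in pairs:
            assert series.occupancy(i, j) == mat.values[i, j]

    def test_boundary_distance_counts_as_contact(self):
        traj = _system([[0, 0, 0], [8, 0, 0]], [1, 2])
        mat = contact_matrix(traj, ContactParams(mode="CA", cutoff=8.0))
        assert mat.values[0, 1] == 1.0

    def test_cutoff_monotonicity(self, small_complex):
        traj = small_complex["trajectories"]["MUT"]
        p_small = contact_matrix(traj, ContactParams(mode="CA", cutoff=6.0))
        p_large = contact_matrix(traj, ContactParams(mode="CA", cutoff=9.0))
        a = np.where(p_small.defined, p_small.values, 0.0)
        b = np.where(p_large.defined, p_large.values, 0.0)
        assert np.all(b >= a)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(20, 6, 3)) * 8.0
        base = _system(coords[0], list(range(1, 7)))
        traj = Trajectory(topology=base.topology, coordinates=coords)
        params = ContactParams(mode="CA", cutoff=8.0)
        p0 = contact_matrix(traj, params).values
        rots = Rotation.random(20, rng=rng)
        moved = np.stack(
            [rots[f].apply(coords[f]) + [50.0, -20.0, 5.0] for f in range(20)]
        )
        p1 = contact_matrix(
            Trajectory(topology=base.topology, coordinates=moved), params
        ).values
        assert np.array_equal(np.nan_to_num(p0), np.nan_to_num(p1))

    def test_min_seq_sep_masks_near_diagonal(self, small_complex):
        traj = small_complex["trajectories"]["WT"]
        mat = contact_matrix(traj, ContactParams(mode="CA", min_seq_sep=3))
        # |i-j| < 3 within a chain is undefined
        assert not mat.defined[0, 1] and not mat.defined[0, 2]
        assert mat.defined[0, 3]

    def test_chain_scope_inter_only(self, small_complex):
        traj = small_complex["trajectories"]["WT"]
        mat = contact_matrix(
            traj, ContactParams(mode="heavy", cutoff=4.5, chain_scope="inter")
        )
        n_prot = small_complex["spec"].n_residues
        assert not mat.defined[:n_prot, :n_prot].any()
        assert mat.defined[:n_prot, n_prot:].all()


class TestAgainstBruteForce:
    @pytest.mark.parametrize("mode,cutoff", [("CA", 8.0), ("heavy", 4.5)])
    def test_contact_probability_matches_oracle_exactly(
        self, small_complex, mode, cutoff
    ):
        traj = small_complex["trajectories"]["WT"]
        params = ContactParams(mode=mode, cutoff=cutoff)
        got = contact_matrix(traj, params).values
        want = oracle_contact_probability(traj, params)
        both = ~np.isnan(got) & ~np.isnan(want)
        assert np.array_equal(got[both], want[both])

    def test_series_matches_frame_by_frame_recomputation(self, small_complex):
        traj = small_complex["trajectories"]["WT"]
        params = ContactParams(mode="CA")
        pairs = [(4, 19), (9, 29), (14, 39), (0, 25)]
        series = contact_series(traj, params, pairs)
        for f in range(traj.n_frames):
            d = oracle_residue_distances(traj.coordinates[f], traj.topology, "CA")
            for i, j in pairs:
                assert series.indicator(i, j)[f] == (d[i, j] <= params.cutoff)


class TestMeanDistance:
    def test_static_trajectory(self):
        traj = _system([[0, 0, 0], [3, 4, 0]], [1, 2])
        static = Trajectory(
            topology=traj.topology,
            coordinates=np.repeat(traj.coordinates, 5, axis=0),
        )
        m = mean_distance_matrix(static, ContactParams(mode="CA"))
        assert m.values[0, 1] == pytest.approx(5.0)

    def test_two_point_average(self):
        top = _system([[0, 0, 0], [5, 0, 0]], [1, 2]).topology
        coords = np.array(
            [[[0, 0, 0], [5, 0, 0]], [[0, 0, 0], [20, 0, 0]]], dtype=float
        )
        m = mean_distance_matrix(
            Trajectory(topology=top, coordinates=coords), ContactParams(mode="CA")
        )
        assert m.values[0, 1] == pytest.approx(12.5)

    def test_contact_frames_only_variant(self):
        top = _system([[0, 0, 0], [5, 0, 0]], [1, 2]).topology
        coords = np.array(
            [[[0, 0, 0], [5, 0, 0]], [[0, 0, 0], [20, 0, 0]]], dtype=float
        )
        traj = Trajectory(topology=top, coordinates=coords)
        m = mean_distance_matrix(
            traj, ContactParams(mode="CA", cutoff=8.0), contact_frames_only=True
        )
        assert m.values[0, 1] == pytest.approx(5.0)

    def test_planted_expectation(self, study):
        """Planted pair mean distance = p*d_bound + (1-p)*d_far with
        d_far from the lattice geometry; jitter averages out."""
        spec = study["spec"]
        traj = study["trajectories"]["WT"]
        m = mean_distance_matrix(traj, study["params"])
        pair = spec.planted_pairs[4]  # (3, 18, p=0.9)
        p = pair.p["WT"]
        movers = [(q.i, q.j) for q in spec.planted_pairs]
        lane = movers.index((pair.i, pair.j))
        theta = 2 * np.pi * lane / len(movers)
        u = np.array([0.0, np.cos(theta), np.sin(theta)])
        base_i = np.array([(pair.i - 1) * spec.chain_spacing, 0, 0])
        base_j = np.array([(pair.j - 1) * spec.chain_spacing, 0, 0])
        d_far = np.linalg.norm(base_j + spec.d_unbound * u - base_i)
        expected = p * spec.d_bound + (1 - p) * d_far
        # 4-sigma binomial bound on the two-state mixture mean, plus a
        # small allowance for jitter-induced bias
        bound = (
            4 * np.sqrt(p * (1 - p) / spec.n_frames) * (d_far - spec.d_bound) + 0.05
        )
        assert m.values[pair.i - 1, pair.j - 1] == pytest.approx(expected, abs=bound)


def test_invalid_params():
    with pytest.raises(ParameterError):
        ContactParams(mode="CB")
    with pytest.raises(ParameterError):
        ContactParams(cutoff=-1.0)
    with pytest.raises(ParameterError):
        ContactParams(min_seq_sep=0)
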