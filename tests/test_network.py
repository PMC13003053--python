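"""nDCC estimation, pair classification, the thresholded residue graph,
and betweenness centrality with domain aggregation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from allodyn import (
    CorrelationMatrix,
    GraphError,
    SyntheticSpec,
    aggregate_centrality,
    average_matrices,
    betweenness,
    build_graph,
    classify_pairs,
    mean_distance_matrix,
    ndcc_matrix,
)
from allodyn.errors import SelectionError
from allodyn.io import DomainMap
from allodyn.network import CentralityProfile
from allodyn.synthetic import build_covariance, build_reference, sample_trajectory

from conftest import make_trajectory, random_trajectory


def corr_from(matrix):
    m = np.asarray(matrix, dtype=float)
    return CorrelationMatrix(m, [f"A:{i+1}" for i in range(len(m))], n_frames=100)


class TestNdcc:
    def test_identically_translated_residues_fully_correlated(self, rng):
        base = np.zeros((3, 3))
        base[:, 0] = [0.0, 0.38, 5.0]
        coords = np.repeat(base[None], 50, axis=0)
        shifts = 0.1 * rng.standard_normal((50, 3))
        coords[:, 0] += shifts
        coords[:, 1] += shifts  # same displacement every frame
        coords[:, 2] += 0.1 * rng.standard_normal((50, 3))
        c = ndcc_matrix(make_trajectory(coords), superpose=False)
        assert np.isclose(c.matrix[0, 1], 1.0)

    def test_mirror_image_displacements_anticorrelated(self, rng):
        base = np.zeros((3, 3))
        base[:, 0] = [0.0, 0.38, 5.0]
        coords = np.repeat(base[None], 50, axis=0)
        shifts = 0.1 * rng.standard_normal((50, 3))
        coords[:, 0] += shifts
        coords[:, 1] -= shifts
        coords[:, 2] += 0.1 * rng.standard_normal((50, 3))
        c = ndcc_matrix(make_trajectory(coords), superpose=False)
        assert np.isclose(c.matrix[0, 1], -1.0)

    def test_block_fixture_recovery(self):
        spec = SyntheticSpec(
            n_residues=20, n_frames=1000,
            domain_blocks=(("a", 0, 10), ("b", 10, 20)),
            intra_block_corr=0.8, inter_block_corr=0.0, seed=17,
        )
        ref = build_reference(spec)
        traj = sample_trajectory(spec, ref, build_covariance(spec))
        c = ndcc_matrix(traj, superpose=False).matrix
        iu = np.triu_indices(10, k=1)
        assert 0.75 <= c[:10, :10][iu].mean() <= 0.85
        assert 0.75 <= c[10:, 10:][iu].mean() <= 0.85
        assert -0.05 <= c[:10, 10:].mean() <= 0.05

    def test_zero_variance_residue_convention(self):
        coords = np.repeat(np.eye(3)[None], 40, axis=0).astype(float)
        coords[:, :2] += 0.1 * np.random.default_rng(0).standard_normal((40, 2, 3))
        # residue 2 never moves
        with pytest.warns(UserWarning, match="zero-variance"):
            c = ndcc_matrix(make_trajectory(coords), superpose=False)
        assert np.allclose(c.matrix[2, :2], 0.0)
        assert c.matrix[2, 2] == 1.0

    def test_translation_invariance_with_superposition(self, rng):
        traj = random_trajectory(rng, n_frames=40)
        shifted = traj.with_coords(traj.coords + rng.standard_normal((40, 1, 3)))
        a = ndcc_matrix(traj, superpose=True).matrix
        b = ndcc_matrix(shifted, superpose=True).matrix
        assert np.allclose(a, b, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrix_invariants_on_random_trajectories(self, seed):
        traj = random_trajectory(np.random.default_rng(seed), n_frames=25)
        c = ndcc_matrix(traj).matrix
        assert np.allclose(c, c.T, atol=1e-10)
        assert np.allclose(np.diag(c), 1.0, atol=1e-10)
        assert np.abs(c).max() <= 1.0 + 1e-12


class TestAverageMatrices:
    def test_average_of_identical_is_identity_operation(self, rng):
        traj = random_trajectory(rng)
        m = ndcc_matrix(traj)
        avg = average_matrices([m, m, m])
        assert np.allclose(avg.matrix, m.matrix)

    def test_opposite_off_diagonals_cancel(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.6
        neg = m.copy()
        neg[0, 1] = neg[1, 0] = -0.6
        avg = average_matrices([corr_from(m), corr_from(neg)])
        assert np.allclose(avg.matrix, np.eye(4))

    def test_elementwise_mean_matches_hand_arithmetic(self, rng):
        mats = []
        for _ in range(3):
            traj = random_trajectory(rng, n_frames=20)
            mats.append(ndcc_matrix(traj))
        avg = average_matrices(mats)
        assert np.allclose(avg.matrix, (mats[0].matrix + mats[1].matrix + mats[2].matrix) / 3)

    def test_dimension_mismatch(self, rng):
        a = ndcc_matrix(random_trajectory(rng, n_residues=5))
        b = ndcc_matrix(random_trajectory(rng, n_residues=6))
        with pytest.raises(ValueError):
            average_matrices([a, b])


class TestClassifyPairs:
    def test_identity_matrix_all_non_correlated(self):
        f = classify_pairs(corr_from(np.eye(5)))
        assert f.non_correlated == 1.0

    def test_uniform_strong_coupling(self):
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 1.0)
        assert classify_pairs(corr_from(m)).correlated == 1.0

    def test_enumerated_three_way_split(self):
        # six unordered pairs: {0.9, 0.9, 0.1, 0.1, -0.5, -0.5}
        m = np.eye(4)
        m[0, 1] = 0.9
        m[2, 3] = 0.9
        m[0, 2] = 0.1
        m[1, 3] = 0.1
        m[0, 3] = -0.5
        m[1, 2] = -0.5
        m = np.triu(m) + np.triu(m, 1).T
        f = classify_pairs(corr_from(m))
        assert f.correlated == pytest.approx(1 / 3)
        assert f.non_correlated == pytest.approx(1 / 3)
        assert f.anti_correlated == pytest.approx(1 / 3)

    def test_boundary_values_join_coupled_bins(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.25
        m[0, 2] = m[2, 0] = -0.25
        f = classify_pairs(corr_from(m))
        assert f.correlated == pytest.approx(1 / 3)
        assert f.anti_correlated == pytest.approx(1 / 3)

    def test_fractions_sum_to_one_and_permutation_invariant(self, rng):
        traj = random_trajectory(rng, n_frames=30, n_residues=10)
        c = ndcc_matrix(traj)
        f = classify_pairs(c)
        assert f.correlated + f.non_correlated + f.anti_correlated == pytest.approx(1.0)
        perm = rng.permutation(10)
        permuted = corr_from(c.matrix[np.ix_(perm, perm)])
        g = classify_pairs(permuted)
        assert (g.correlated, g.non_correlated, g.anti_correlated) == (
            f.correlated, f.non_correlated, f.anti_correlated)


class TestMeanDistance:
    def test_static_linear_chain_adjacent_spacing(self):
        coords = np.zeros((3, 5, 3))
        coords[:, :, 0] = 0.38 * np.arange(5)
        d = mean_distance_matrix(make_trajectory(coords))
        assert np.allclose(np.diag(d, 1), 3.8)  # Angstrom

    def test_single_frame_equals_frame_distances(self, rng):
        traj = random_trajectory(rng, n_frames=1, n_residues=6)
        d = mean_distance_matrix(traj)
        diff = traj.coords[0, :, None] - traj.coords[0, None]
        assert np.allclose(d, 10.0 * np.sqrt((diff**2).sum(-1)))

    def test_two_frame_mean(self, rng):
        traj = random_trajectory(rng, n_frames=2, n_residues=4)
        d = mean_distance_matrix(traj)
        per_frame = []
        for f in range(2):
            diff = traj.coords[f, :, None] - traj.coords[f, None]
            per_frame.append(np.sqrt((diff**2).sum(-1)))
        assert np.allclose(d, 10.0 * (per_frame[0] + per_frame[1]) / 2)


class TestBuildGraph:
    def test_unit_correlation_gives_zero_weight(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 1.0
        dist = np.full((3, 3), 5.0)
        g = build_graph(corr_from(m), dist)
        assert g[0][1]["weight"] == pytest.approx(0.0)

    def test_moderate_correlation_weight(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.5
        dist = np.full((3, 3), 5.0)
        g = build_graph(corr_from(m), dist)
        assert g[0][1]["weight"] == pytest.approx(-np.log(0.5))

    def test_distance_veto(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        dist = np.full((3, 3), 8.0)
        g = build_graph(corr_from(m), dist)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3  # isolates retained

    def test_nonpositive_cmin_rejected(self):
        with pytest.raises(GraphError):
            build_graph(corr_from(np.eye(3)), np.zeros((3, 3)), c_min=0.0)

    def test_monotone_thresholds_never_add_edges(self, rng):
        traj = random_trajectory(rng, n_frames=40, n_residues=12)
        c = ndcc_matrix(traj)
        dist = mean_distance_matrix(traj)
        base = set(build_graph(c, dist, c_min=0.2, d_max=10.0).edges)
        tighter_c = set(build_graph(c, dist, c_min=0.4, d_max=10.0).edges)
        tighter_d = set(build_graph(c, dist, c_min=0.2, d_max=5.0).edges)
        assert tighter_c <= base
        assert tighter_d <= base


def brute_force_betweenness(g):
    """Independent oracle: enumerate every simple path, keep minimal-weight
    ones (exact tie handling), accumulate pair-normalized credit."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    cb = dict.fromkeys(nodes, 0.0)

    def all_paths(s, t):
        paths = []

        def extend(path, weight):
            last = path[-1]
            if last == t:
                paths.append((weight, list(path)))
                return
            for nb in g[last]:
                if nb not in path:
                    path.append(nb)
                    extend(path, weight + g[last][nb]["weight"])
                    path.pop()

        extend([s], 0.0)
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        wmin = min(w for w, _ in paths)
        shortest = [p for w, p in paths if w <= wmin + 1e-12]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            cb[v] += through / sigma
    norm = 2.0 / ((n - 1) * (n - 2))
    return np.array([cb[v] * norm for v in nodes])


class TestBetweenness:
    def test_path_graph_middle_node(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0)])
        prof = betweenness(g)
        assert np.allclose(prof.values, [0.0, 1.0, 0.0])

    def test_four_cycle_equal_weights(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)])
        # each opposite pair has two tied shortest paths; credit is split
        assert np.allclose(betweenness(g).values, 1 / 6)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, 2.0)))
        assert np.allclose(betweenness(g).values, brute_force_betweenness(g), atol=1e-12)

    def test_tied_paths_match_brute_force(self):
        # diamond with equal weights: two exactly tied routes
        g = nx.Graph()
        g.add_weighted_edges_from(
            [(0, 1, 0.5), (0, 2, 0.5), (1, 3, 0.5), (2, 3, 0.5), (3, 4, 1.0)])
        assert np.allclose(betweenness(g).values, brute_force_betweenness(g), atol=1e-12)

    def test_too_few_nodes(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        with pytest.raises(GraphError):
            betweenness(g)


def profile_from(values, condition=None):
    return CentralityProfile(np.asarray(values, float),
                             [f"A:{i+1}" for i in range(len(values))], condition)


def two_domain_map():
    return DomainMap(
        domains={"head": np.array([0, 1, 2]), "leg": np.array([3, 4, 5])},
        pull_group=np.array([0]), ref_group=np.array([5]),
    )


class TestAggregateCentrality:
    def test_self_consistency_against_control(self):
        control = profile_from([0.1, 0.2, 0.3, 0.05, 0.15, 0.2], "control")
        table = aggregate_centrality(control, two_domain_map(), control)
        assert np.allclose(table["normalized_mean"], 1.0)
        assert np.allclose(table["pct_diff_vs_control"], 0.0)
        # hub count at control is itself: residues with CB >= 2x control mean
        thresh = 2 * np.mean([0.1, 0.2, 0.3, 0.05, 0.15, 0.2])
        expected = int((control.values >= thresh).sum())
        assert table["n_high_bc"].sum() == expected

    def test_doubled_profile_flags_everything(self):
        control = profile_from([0.1, 0.2, 0.3, 0.05, 0.15, 0.2], "control")
        doubled = profile_from(2 * control.values)
        table = aggregate_centrality(doubled, two_domain_map(), control,
                                     per_residue_control=True)
        assert np.allclose(table["normalized_mean"], 2.0)
        # against each residue's own control value, 2x control flags all
        assert table["n_high_bc"].sum() == 6
        assert table.attrs["overall_normalized"] == pytest.approx(2.0)
        # against the global control mean only residues at/above the control
        # mean clear twice that mean
        global_table = aggregate_centrality(doubled, two_domain_map(), control)
        assert global_table["n_high_bc"].sum() == int(
            (control.values >= control.values.mean()).sum())

    def test_hand_built_domain_means(self):
        control = profile_from([0.2, 0.2, 0.2, 0.2, 0.2, 0.2], "control")
        prof = profile_from([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        table = aggregate_centrality(prof, two_domain_map(), control).set_index("domain")
        assert table.loc["head", "mean_bc"] == pytest.approx(0.2)
        assert table.loc["leg", "mean_bc"] == pytest.approx(0.5)
        assert table.loc["leg", "pct_diff_vs_control"] == pytest.approx(150.0)
        # hub threshold 2*0.2 = 0.4: residues 3 (0.4), 4, 5 qualify
        assert table.loc["leg", "n_high_bc"] == 3

    def test_empty_domain_rejected(self):
        control = profile_from([0.1, 0.1, 0.1])
        dmap = DomainMap(domains={"x": np.array([0])},
                         pull_group=np.array([0]), ref_group=np.array([1]))
        dmap.domains["empty"] = np.array([], dtype=int)
        with pytest.raises(SelectionError):
            aggregate_centrality(control, dmap, control)


class TestConditionContrast:
    @pytest.mark.parametrize("seed", range(20))
    def test_force_like_exceeds_control_like_correlated_fraction(self, seed):
        """A globally coupled ('force-like', intra 0.6) ensemble must show a
        strictly larger correlated-pair fraction than a weakly coupled
        ('control-like', intra 0.1) one, at every seed."""
        fractions = {}
        for label, intra in (("force", 0.6), ("control", 0.1)):
            spec = SyntheticSpec(
                n_residues=30, n_frames=200,
                domain_blocks=(("all", 0, 30),),
                intra_block_corr=intra, seed=seed,
            )
            ref = build_reference(spec)
            traj = sample_trajectory(spec, ref, build_covariance(spec))
            c = ndcc_matrix(traj, superpose=False)
            fractions[label] = classify_pairs(c).correlated
        assert fractions["force"] > fractions["control"]
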