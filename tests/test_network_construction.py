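"""Cube nodes, rotation-maximized similarity and the permutation threshold."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gmnet.network_construction import (
    CubeNodeSet,
    build_network,
    build_similarity_matrix,
    extract_cubes,
    max_rotation_similarity,
    permutation_threshold,
    rotate_cube,
)
from gmnet.synthetic_data import (
    VolumeSimSpec,
    generate_structured_volume,
    planted_pairs,
)
from gmnet.volume_io import GMVolume


def make_vol(data, mm=2.0):
    return GMVolume(data=data, affine=np.diag([mm, mm, mm, 1.0]))


def brute_force_max_similarity(a, b):
    """Independent oracle: explicit loop over the 22 orientations built by
    composing single 45-degree steps, scored with np.corrcoef."""
    best = -np.inf
    orientations = [np.asarray(a, dtype=float)]
    for axis in "xyz":
        cur = np.asarray(a, dtype=float)
        for _ in range(7):
            cur = rotate_cube(cur, axis, 1)
            orientations.append(cur)
    for rotated in orientations:
        best = max(best, np.corrcoef(rotated, b)[0, 1])
    return best


class TestExtractCubes:
    def test_counts_on_exact_grids(self, rng):
        vol = make_vol(rng.random((6, 6, 6)) * 0.9 + 0.05)
        assert extract_cubes(vol).n_nodes == 8
        vol = make_vol(rng.random((30, 30, 30)) * 0.9 + 0.05)
        assert extract_cubes(vol).n_nodes == 1000

    def test_partial_blocks_dropped(self, rng):
        vol = make_vol(rng.random((7, 8, 6)) * 0.9 + 0.05)
        assert extract_cubes(vol).n_nodes == 2 * 2 * 2

    def test_zero_and_constant_cubes_excluded(self, rng):
        data = rng.random((6, 6, 6)) * 0.9 + 0.05
        data[:3, :3, :3] = 0.0  # all-zero corner cube
        nodes = extract_cubes(make_vol(data))
        assert nodes.n_nodes == 7
        data[:3, :3, :3] = 0.5  # constant (zero-variance) cube
        assert extract_cubes(make_vol(data)).n_nodes == 7

    def test_cubes_record_values_and_coords(self, rng):
        data = rng.random((6, 6, 6)) * 0.9 + 0.05
        nodes = extract_cubes(make_vol(data))
        k = [tuple(c) for c in nodes.grid_coords].index((1, 0, 1))
        assert np.array_equal(nodes.cubes[k], data[3:6, 0:3, 3:6].reshape(-1))
        assert nodes.cube_size_mm == pytest.approx(6.0)

    def test_too_small_volume_raises(self, rng):
        with pytest.raises(ValueError, match="small"):
            extract_cubes(make_vol(rng.random((2, 6, 6))))


class TestRotateCube:
    def test_identity_and_full_turn(self, rng):
        c = rng.normal(size=27)
        assert np.array_equal(rotate_cube(c, "x", 0), c)
        half = rotate_cube(c, "y", 4)
        assert np.array_equal(rotate_cube(half, "y", 4), c)

    @pytest.mark.parametrize("axis,np_axes", [("x", (1, 2)), ("y", (0, 2)), ("z", (0, 1))])
    def test_k2_equals_quarter_turn(self, rng, axis, np_axes):
        cube = rng.normal(size=27)
        rotated = rotate_cube(cube, axis, 2).reshape(3, 3, 3)
        expected = np.rot90(cube.reshape(3, 3, 3), k=-1, axes=np_axes)
        assert np.allclose(rotated, expected)

    @given(st.sampled_from("xyz"), st.integers(1, 7), st.integers(0, 2**32 - 1))
    def test_k_steps_compose_from_single_steps(self, axis, k, seed):
        cube = np.random.default_rng(seed).normal(size=27)
        stepped = cube
        for _ in range(k):
            stepped = rotate_cube(stepped, axis, 1)
        assert np.allclose(rotate_cube(cube, axis, k), stepped)

    def test_rotation_is_a_permutation(self, rng):
        cube = np.arange(27.0)
        for axis, k in itertools.product("xyz", range(8)):
            assert sorted(rotate_cube(cube, axis, k)) == list(cube)

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError, match="k"):
            rotate_cube(np.zeros(27), "x", 8)


class TestMaxRotationSimilarity:
    def test_self_similarity_is_one(self, rng):
        c = rng.normal(size=27)
        assert max_rotation_similarity(c, c) == pytest.approx(1.0)

    def test_recovers_own_rotation(self, rng):
        c = rng.normal(size=27)
        for axis, k in [("z", 3), ("x", 5), ("y", 1)]:
            assert max_rotation_similarity(c, rotate_cube(c, axis, k)) == pytest.approx(1.0)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=27), r.normal(size=27)
        assert max_rotation_similarity(a, b) == pytest.approx(
            brute_force_max_similarity(a, b), abs=1e-12
        )

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=27), r.normal(size=27)
        assert max_rotation_similarity(a, b) == pytest.approx(
            max_rotation_similarity(b, a), abs=1e-12
        )

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            max_rotation_similarity(np.ones(27), np.arange(27.0))


class TestSimilarityMatrix:
    def test_matches_pairwise_calls(self, rng):
        from gmnet.network_construction import CubeNodeSet

        cubes = rng.normal(size=(3, 27))
        nodes = CubeNodeSet(cubes=cubes, grid_coords=[[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        sim = build_similarity_matrix(nodes)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert sim.values[i, j] == pytest.approx(
                        max_rotation_similarity(cubes[i], cubes[j])
                    )
        assert np.allclose(sim.values, sim.values.T)

    def test_duplicated_nodes_score_one(self, rng):
        from gmnet.network_construction import CubeNodeSet

        c = rng.normal(size=(2, 27))
        nodes = CubeNodeSet(
            cubes=np.vstack([c, c]),
            grid_coords=[[0, 0, 0], [0, 0, 1], [1, 0, 0], [1, 0, 1]],
        )
        sim = build_similarity_matrix(nodes)
        assert sim.values[0, 2] == pytest.approx(1.0)
        assert sim.values[1, 3] == pytest.approx(1.0)

    def test_node_relabeling_permutes_matrix(self, rng):
        from gmnet.network_construction import CubeNodeSet

        cubes = rng.normal(size=(6, 27))
        coords = [[0, 0, i] for i in range(6)]
        sim = build_similarity_matrix(CubeNodeSet(cubes=cubes, grid_coords=coords))
        perm = rng.permutation(6)
        sim_p = build_similarity_matrix(
            CubeNodeSet(cubes=cubes[perm], grid_coords=[coords[i] for i in perm])
        )
        assert np.allclose(sim_p.values, sim.values[np.ix_(perm, perm)])

    def test_single_node_raises(self, rng):
        from gmnet.network_construction import CubeNodeSet

        nodes = CubeNodeSet(cubes=rng.normal(size=(1, 27)), grid_coords=[[0, 0, 0]])
        with pytest.raises(ValueError, match="2 nodes"):
            build_similarity_matrix(nodes)

    def test_noise_similarities_match_permutation_null(self, rng):
        """i.i.d. noise cubes: observed similarities are distributed like the
        within-cube permutation null (two-sample KS statistic small)."""
        from gmnet.network_construction import _ORIENTATIONS, _standardize
        from scipy.stats import ks_2samp

        cubes = rng.normal(size=(40, 27))
        nodes = CubeNodeSet(cubes=cubes, grid_coords=[[0, 0, i] for i in range(40)])
        obs = build_similarity_matrix(nodes).offdiag()
        u = _standardize(cubes)
        ii = rng.integers(0, 40, 2000)
        jj = rng.integers(0, 39, 2000)
        jj[jj >= ii] += 1
        perms = np.argsort(rng.random((2000, 27)), axis=1)
        a = np.take_along_axis(u[ii], perms, axis=1)
        null = np.einsum("dok,dk->do", a[:, _ORIENTATIONS], u[jj]).max(axis=1)
        stat = ks_2samp(obs, null).statistic
        assert stat < 0.08


class TestPermutationThreshold:
    def test_vacuous_level_retains_everything(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        thr = permutation_threshold(nodes, sim, spurious_level=1.0, n_null=1000, seed=0)
        assert thr == pytest.approx(sim.offdiag().min())

    def test_pure_noise_gives_near_empty_network(self, rng):
        vol = make_vol(rng.random((18, 18, 18)) * 0.9 + 0.05)
        nodes = extract_cubes(vol)
        sim = build_similarity_matrix(nodes)
        with pytest.warns(UserWarning, match="unsatisfiable"):
            thr = permutation_threshold(nodes, sim, 0.05, n_null=2000, seed=1)
        net = build_network(sim, thr)
        assert net.density < 0.001

    def test_planted_structure_fdp_controlled(self):
        """Across seeds, on average at most ~5% of retained edges join
        non-planted pairs (within Monte-Carlo tolerance)."""
        fdps = []
        for seed in range(8):
            spec = VolumeSimSpec(shape=(24, 24, 24), n_patterns=6,
                                 members_per_pattern=12, seed=seed)
            vol = generate_structured_volume(spec)
            nodes = extract_cubes(vol)
            sim = build_similarity_matrix(nodes)
            thr = permutation_threshold(nodes, sim, 0.05, n_null=10_000, seed=seed + 100)
            net = build_network(sim, thr)
            truth = planted_pairs(spec)
            coords = [tuple(c) for c in nodes.grid_coords]
            edges = np.argwhere(np.triu(net.adjacency, k=1))
            assert len(edges) > 0
            spurious = sum(
                1 for i, j in edges if frozenset((coords[i], coords[j])) not in truth
            )
            fdps.append(spurious / len(edges))
        mc_se = np.std(fdps, ddof=1) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= 0.05 + 2 * mc_se

    def test_determinism(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        t1 = permutation_threshold(nodes, sim, 0.05, n_null=1000, seed=42)
        t2 = permutation_threshold(nodes, sim, 0.05, n_null=1000, seed=42)
        assert t1 == t2

    def test_invalid_parameters(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        with pytest.raises(ValueError, match="spurious_level"):
            permutation_threshold(nodes, sim, 0.0, n_null=1000)
        with pytest.raises(ValueError, match="n_null"):
            permutation_threshold(nodes, sim, 0.05, n_null=10)


class TestBuildNetwork:
    def test_extreme_thresholds(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        assert build_network(sim, 1.1).density == 0.0
        assert build_network(sim, sim.offdiag().min()).density == 1.0

    def test_density_monotone_in_threshold(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        dens = [build_network(sim, t).density for t in np.linspace(-1, 1, 21)]
        assert all(a >= b for a, b in zip(dens, dens[1:]))

    def test_no_self_loops_and_symmetric(self, planted_volume_nodes):
        _, _, nodes = planted_volume_nodes
        sim = build_similarity_matrix(nodes)
        net = build_network(sim, 0.5)
        assert not net.adjacency.diagonal().any()
        assert np.array_equal(net.adjacency, net.adjacency.T)
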