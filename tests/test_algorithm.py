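"""MOSI stages: regional FC, split, absorb, profiles, similarity, unify,
and the full iteration with its convergence contract."""

import numpy as np
import pytest

from mosi import (
    BoldMatrix,
    FcProfiles,
    MosiConfig,
    Parcellation,
    PlantedSpec,
    VoxelLattice,
    absorb_small_modules,
    generate_planted_volume,
    global_fc_profiles,
    grow_regions,
    mosi_iterate,
    mosi_ladder,
    normalized_mutual_information,
    regional_fc_matrix,
    similarity_index,
    split_stage,
    unify_stage,
)
from mosi.lattice import connected_components
from oracles import pairwise_pearson, similarity_loop

T = 64
_t = np.arange(T)


def sinusoid(cycles: int, phase: float = 0.0) -> np.ndarray:
    """Unit sinusoid; distinct integer cycle counts are exactly orthogonal."""
    return np.sin(2 * np.pi * cycles * _t / T + phase)


def assert_contiguous(parc, lattice):
    adj = lattice.adjacency()
    for mid in parc.module_ids:
        assert len(connected_components(parc.voxels_of(mid), adj)) == 1


class TestRegionalFc:
    def test_identical_and_negated_series(self):
        lat = VoxelLattice.full((3, 1, 1))
        s = sinusoid(3)
        bold = BoldMatrix(np.column_stack([s, s, -s]), lat)
        R = regional_fc_matrix(bold, [0, 1, 2])
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert R[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diagonal(R), 1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        lat = VoxelLattice.full((4, 1, 1))
        X = rng.standard_normal((50, 4))
        bold = BoldMatrix(X, lat)
        R = regional_fc_matrix(bold, range(4))
        assert np.allclose(R, pairwise_pearson(X), atol=1e-12)

    def test_zero_variance_voxel_named(self):
        lat = VoxelLattice.full((2, 1, 1))
        data = np.column_stack([sinusoid(2), np.ones(T)])
        bold = BoldMatrix(data, lat, validate=False)
        with pytest.raises(ValueError, match="voxel 1"):
            regional_fc_matrix(bold, [0, 1])

    def test_needs_two_voxels(self):
        lat = VoxelLattice.full((2, 1, 1))
        bold = BoldMatrix(np.column_stack([sinusoid(1), sinusoid(2)]), lat)
        with pytest.raises(ValueError):
            regional_fc_matrix(bold, [0])


class TestGlobalProfiles:
    def _volume(self, signals, layout_dims=(6, 2, 2)):
        """One module per x-slab of width 2, module k driven by signals[k]."""
        lat = VoxelLattice.full(layout_dims)
        labels = lat.coords[:, 0] // 2 + 1
        data = np.column_stack([signals[l - 1] for l in labels])
        return lat, Parcellation(labels), BoldMatrix(data, lat)

    def test_identical_means_give_unit_profiles(self):
        s = sinusoid(3)
        lat, parc, bold = self._volume([s, s, s])
        prof = global_fc_profiles(parc, bold)
        assert np.allclose(prof.profile(1), 1.0, atol=1e-12)

    def test_orthogonal_sinusoids_give_zero_profiles(self):
        lat, parc, bold = self._volume([sinusoid(2), sinusoid(5), sinusoid(9)])
        prof = global_fc_profiles(parc, bold)
        for mid in (1, 2, 3):
            assert np.allclose(prof.profile(mid), 0.0, atol=1e-10)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(15)
        lat = VoxelLattice.full((6, 2, 2))
        labels = lat.coords[:, 0] // 2 + 1
        bold = BoldMatrix(rng.standard_normal((40, lat.n_voxels)), lat)
        parc = Parcellation(labels)
        prof = global_fc_profiles(parc, bold)
        means = np.column_stack(
            [bold.data[:, labels == m].mean(axis=1) for m in (1, 2, 3)]
        )
        assert np.allclose(prof.corr, pairwise_pearson(means), atol=1e-12)

    def test_too_few_modules_rejected(self):
        lat = VoxelLattice.full((4, 1, 1))
        bold = BoldMatrix(
            np.column_stack([sinusoid(k + 1) for k in range(4)]), lat
        )
        parc = Parcellation(np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError, match="too few modules"):
            global_fc_profiles(parc, bold)


class TestSimilarityIndex:
    def _profiles(self, corr, sizes):
        ids = np.arange(1, len(sizes) + 1)
        return FcProfiles(
            module_ids=ids, corr=np.asarray(corr, float), sizes=np.asarray(sizes)
        )

    def test_hand_evaluated_example(self):
        # profiles of modules 1 and 2 differ only at reference 3
        # (n=4, difference 0.2); reference weight total 16 -> d = 0.1
        corr = np.eye(4)
        corr[0, 2] = corr[2, 0] = 0.5
        corr[1, 2] = corr[2, 1] = 0.3
        corr[0, 3] = corr[3, 0] = 0.4
        corr[1, 3] = corr[3, 1] = 0.4
        prof = self._profiles(corr, [10, 10, 4, 12])
        assert similarity_index(1, 2, prof) == pytest.approx(0.1, abs=1e-14)

    def test_identical_profiles_and_symmetry(self):
        rng = np.random.default_rng(4)
        corr = rng.uniform(-1, 1, (5, 5))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        prof = self._profiles(corr, rng.integers(5, 40, 5))
        for u in range(1, 6):
            for v in range(u + 1, 6):
                d_uv = similarity_index(u, v, prof)
                assert d_uv == pytest.approx(similarity_index(v, u, prof), abs=1e-14)
                skip = {u - 1, v - 1}
                assert d_uv == pytest.approx(
                    similarity_loop(corr[u - 1], corr[v - 1], prof.sizes, skip),
                    abs=1e-12,
                )
        twin = corr.copy()
        twin[1] = twin[0]
        twin[:, 1] = twin[:, 0]
        np.fill_diagonal(twin, 1.0)
        assert similarity_index(1, 2, self._profiles(twin, prof.sizes)) == 0.0

    def test_degenerate_cases(self):
        prof = self._profiles(np.eye(2), [3, 3])
        with pytest.raises(ValueError, match="no shared reference"):
            similarity_index(1, 2, prof)
        with pytest.raises(ValueError):
            similarity_index(1, 1, prof)


class TestSplitStage:
    def test_mixed_module_split_along_planted_boundary(self):
        """A module holding two signal populations separates cleanly."""
        rng = np.random.default_rng(2)
        lat = VoxelLattice.full((6, 2, 2))
        a, b = sinusoid(3), sinusoid(7)
        side = lat.coords[:, 0] < 3
        data = np.where(side, a[:, None], b[:, None]) + 0.05 * rng.standard_normal(
            (T, lat.n_voxels)
        )
        bold = BoldMatrix(data, lat)
        parc = Parcellation(np.ones(lat.n_voxels, dtype=int))
        out = split_stage(parc, bold, MosiConfig(gamma=0.8, seed=1))
        assert out.n_modules >= 2
        assert_contiguous(out, lat)
        for mid in out.module_ids:  # planted boundary respected
            assert len(np.unique(side[out.voxels_of(mid)])) == 1

    def test_disconnected_submodule_separated(self):
        """Identical far-apart islands stay distinct modules: only
        neighboring voxels may share a module."""
        lat = VoxelLattice.full((5, 1, 1))
        s = sinusoid(2)
        # middle voxel anticorrelated: clamped to zero weight, so the four
        # s-driven voxels form one Louvain community split by the gap
        data = np.column_stack([s, s, -s, s, s])
        bold = BoldMatrix(data, lat)
        out = split_stage(
            Parcellation(np.ones(5, dtype=int)), bold, MosiConfig(gamma=0.8, seed=0)
        )
        assert_contiguous(out, lat)
        assert out.labels[0] != out.labels[3]  # islands split apart

    def test_homogeneous_module_unchanged(self):
        lat = VoxelLattice.full((4, 2, 2))
        rng = np.random.default_rng(5)
        data = sinusoid(3)[:, None] + 0.02 * rng.standard_normal((T, lat.n_voxels))
        bold = BoldMatrix(data, lat)
        out = split_stage(
            Parcellation(np.ones(lat.n_voxels, dtype=int)),
            bold,
            MosiConfig(gamma=0.8, seed=2),
        )
        assert out.n_modules == 1

    def test_single_voxel_module_passthrough(self):
        lat = VoxelLattice.full((3, 1, 1))
        bold = BoldMatrix(
            np.column_stack([sinusoid(1), sinusoid(2), sinusoid(3)]), lat
        )
        parc = Parcellation(np.array([1, 2, 3]))
        out = split_stage(parc, bold, MosiConfig(gamma=0.8, seed=0))
        assert out.n_modules == 3


class TestAbsorb:
    def _fragment_volume(self, rho: float):
        """12-voxel module A plus a 4-voxel fragment B with
        corr(mean_A, mean_B) == rho by construction."""
        lat = VoxelLattice.full((4, 2, 2))
        e1, e2 = sinusoid(3), sinusoid(8)
        a = e1
        b = rho * e1 + np.sqrt(1 - rho**2) * e2
        frag = lat.coords[:, 0] == 3
        data = np.where(frag, b[:, None], a[:, None])
        labels = np.where(frag, 2, 1)
        return Parcellation(labels), BoldMatrix(data, lat)

    @pytest.mark.parametrize(
        "rho,merged", [(0.9, True), (0.3, False), (0.5, True)]
    )
    def test_threshold_is_inclusive(self, rho, merged):
        parc, bold = self._fragment_volume(rho)
        out = absorb_small_modules(parc, bold, MosiConfig())
        assert (out.n_modules == 1) is merged

    def test_isolated_fragment_retained_with_warning(self):
        mask = np.zeros((7, 2, 2), dtype=bool)
        mask[:3] = True  # big island
        mask[5:] = True  # separate island, 8 voxels but labeled small
        lat = VoxelLattice(mask)
        rng = np.random.default_rng(1)
        data = rng.standard_normal((40, lat.n_voxels))
        labels = np.where(lat.coords[:, 0] < 3, 1, 2)  # island module 2: 8 voxels
        bold = BoldMatrix(data, lat)
        cfg = MosiConfig(min_module_size=10)
        with pytest.warns(UserWarning, match="isolated"):
            out = absorb_small_modules(Parcellation(labels), bold, cfg)
        # the small island cannot reach module 1 across the mask gap
        assert out.n_modules == 2

    def test_fragment_absorbed_into_best_neighbor_only(self):
        """With two neighbors, the fragment joins the better-correlated one."""
        lat = VoxelLattice.full((5, 2, 2))
        e1, e2 = sinusoid(3), sinusoid(8)
        x = lat.coords[:, 0]
        labels = np.select([x < 2, x == 2, x > 2], [1, 2, 3])
        good = 0.95 * e1 + np.sqrt(1 - 0.95**2) * e2
        data = np.empty((T, lat.n_voxels))
        data[:, labels == 1] = e1[:, None]
        data[:, labels == 2] = good[:, None]
        data[:, labels == 3] = e2[:, None]
        bold = BoldMatrix(data, lat)
        out = absorb_small_modules(Parcellation(labels), bold, MosiConfig())
        assert out.n_modules == 2
        merged_label = out.labels[lat.index_of[2, 0, 0]]
        assert merged_label == out.labels[lat.index_of[0, 0, 0]]


class TestUnify:
    def _slab_volume(self, signals, widths, dims):
        lat = VoxelLattice.full(dims)
        edges = np.cumsum([0] + widths)
        x = lat.coords[:, 0]
        labels = np.zeros(lat.n_voxels, dtype=int)
        data = np.empty((T, lat.n_voxels))
        for k, (lo, hi) in enumerate(zip(edges, edges[1:]), start=1):
            sel = (x >= lo) & (x < hi)
            labels[sel] = k
            data[:, sel] = signals[k - 1][:, None]
        return lat, Parcellation(labels), BoldMatrix(data, lat)

    def test_identical_latents_merge(self):
        # A and B share a latent; the references C, D, E have mutually
        # distinguishable FC profiles so only the A-B pair qualifies
        s, a, b = sinusoid(2), sinusoid(5), sinusoid(9)
        d_sig = 0.6 * a + 0.8 * b
        lat, parc, bold = self._slab_volume(
            [s, s, a, d_sig, b], [2, 2, 2, 2, 2], (10, 2, 2)
        )
        out = unify_stage(parc, bold, MosiConfig(), np.random.default_rng(0))
        assert out.n_modules == 4
        assert out.labels[lat.index_of[0, 0, 0]] == out.labels[lat.index_of[2, 0, 0]]

    def test_correlated_means_with_different_profiles_stay_separate(self):
        """High mean-signal correlation alone is not grounds to unify."""
        s, a, b = sinusoid(2), sinusoid(5), sinusoid(9)
        u = s + 0.4 * a
        v = s + 0.4 * b
        lat = VoxelLattice.full((4, 2, 4))
        z, x = lat.coords[:, 2], lat.coords[:, 0]
        labels = np.select(
            [(z < 2) & (x < 2), (z < 2) & (x >= 2), (z >= 2) & (x < 2)],
            [1, 2, 3],
            default=4,
        )
        data = np.empty((T, lat.n_voxels))
        for lab, sig in zip((1, 2, 3, 4), (u, v, a, b)):
            data[:, labels == lab] = sig[:, None]
        bold = BoldMatrix(data, lat)
        parc = Parcellation(labels)
        prof = global_fc_profiles(parc, bold)
        r_uv = np.corrcoef(u, v)[0, 1]
        assert r_uv > 0.8  # the means are highly correlated...
        assert similarity_index(1, 2, prof) > 0.05  # ...but the FC maps differ
        out = unify_stage(parc, bold, MosiConfig(), np.random.default_rng(0))
        assert out.n_modules == 4

    def test_chain_merges_one_pair_per_cycle(self):
        """A-B-C with tied distances: one merge only, since each module
        participates in at most one merge per cycle."""
        s, d0, e0 = sinusoid(2), sinusoid(5), sinusoid(9)
        d = d0
        e = 0.6 * s + 0.8 * e0  # refs correlate differently with the chain
        lat = VoxelLattice.full((6, 2, 4))
        z, x = lat.coords[:, 2], lat.coords[:, 0]
        labels = np.zeros(lat.n_voxels, dtype=int)
        labels[z < 2] = x[z < 2] // 2 + 1  # slabs A=1, B=2, C=3
        labels[(z >= 2) & (x < 3)] = 4
        labels[(z >= 2) & (x >= 3)] = 5
        data = np.empty((T, lat.n_voxels))
        for lab, sig in zip((1, 2, 3, 4, 5), (s, s, s, d, e)):
            data[:, labels == lab] = sig[:, None]
        bold = BoldMatrix(data, lat)
        out = unify_stage(
            Parcellation(labels), bold, MosiConfig(), np.random.default_rng(3)
        )
        assert out.n_modules == 4  # exactly one of A-B / B-C merged


class TestMosiIterate:
    def test_fixed_point_at_matched_resolution(self):
        vol = generate_planted_volume(
            PlantedSpec(dims=(8, 8, 4), n_regions=4, n_timepoints=100, snr=50, seed=9)
        )
        res = mosi_iterate(vol.parcellation, vol.bold, MosiConfig(gamma=0.8, seed=4))
        assert res.converged
        assert len(res.history) <= 2
        assert normalized_mutual_information(
            res.parcellation.labels, vol.parcellation.labels
        ) == pytest.approx(1.0)

    def test_recovers_planted_regions(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        res = mosi_iterate(init, small_volume.bold, MosiConfig(gamma=0.8, seed=3))
        nmi = normalized_mutual_information(
            res.parcellation.labels, small_volume.parcellation.labels
        )
        assert nmi >= 0.9
        assert_contiguous(res.parcellation, small_volume.lattice)

    def test_iteration_cap_flags_nonconvergence(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        res = mosi_iterate(
            init, small_volume.bold, MosiConfig(gamma=0.8, seed=3, max_iterations=1)
        )
        assert len(res.history) == 1
        assert not res.converged

    def test_history_records_every_iteration(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        res = mosi_iterate(init, small_volume.bold, MosiConfig(gamma=0.8, seed=3))
        frame = res.history_frame()
        assert list(frame["iteration"]) == list(range(1, len(res.history) + 1))
        assert (frame["module_count"] > 0).all()


class TestMosiLadder:
    def test_singleton_ladder_equals_single_run(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        cfg = MosiConfig(seed=3)
        solo = mosi_iterate(init, small_volume.bold, cfg)
        lad = mosi_ladder(init, small_volume.bold, [cfg.gamma], cfg)
        assert len(lad) == 1
        assert np.array_equal(lad[0].parcellation.labels, solo.parcellation.labels)
        assert lad[0].history == solo.history

    def test_rerun_is_bit_identical(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        cfg = MosiConfig(seed=11)
        runs = [
            mosi_ladder(init, small_volume.bold, [0.7, 0.8], cfg) for _ in range(2)
        ]
        for a, b in zip(*runs):
            assert np.array_equal(a.parcellation.labels, b.parcellation.labels)
            assert a.history == b.history

    def test_gammas_must_ascend(self, small_volume):
        init = grow_regions(small_volume.lattice, 2, seed=5)
        with pytest.raises(ValueError, match="ascending"):
            mosi_ladder(init, small_volume.bold, [0.9, 0.7], MosiConfig())
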