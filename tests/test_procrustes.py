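import numpy as np
import pytest

from mcnet.data import Dataset, LandmarkConfiguration
from mcnet.errors import (
    DegenerateConfigurationError,
    DesignError,
    MismatchError,
    StructureError,
)
from mcnet.procrustes import (
    AlignedDataset,
    centroid_size,
    gpa,
    procrustes_anova,
    transfer,
)
from mcnet.synthetic import SyntheticSpec, generate


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


def _make_dataset(ref_coords_list, mp_coords_list=None, specimens=None):
    """Build a dataset from per-specimen reference (and measurement) coords."""
    n = len(ref_coords_list)
    if mp_coords_list is None:
        mp_coords_list = [np.empty((0, 2))] * n
    kr = ref_coords_list[0].shape[0]
    km = mp_coords_list[0].shape[0]
    roles = ("reference",) * kr + ("measurement",) * km
    labels = tuple(f"R{i+1}" for i in range(kr)) + tuple(f"MP{i+1}" for i in range(km))
    if specimens is None:
        specimens = [(f"s{i+1}", 1) for i in range(n)]
    configs = tuple(
        LandmarkConfiguration(
            sid, rep, np.vstack([r, m]), roles, labels
        )
        for (sid, rep), r, m in zip(specimens, ref_coords_list, mp_coords_list)
    )
    return Dataset(configs)


SQUARE = np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]])


class TestCentroidSize:
    def test_square_of_side_two(self):
        assert centroid_size(SQUARE) == pytest.approx(np.sqrt(8.0))

    def test_two_points(self):
        assert centroid_size(np.array([[0.0, 0.0], [2.0, 0.0]])) == pytest.approx(
            np.sqrt(2.0)
        )

    @pytest.mark.parametrize("c", [0.5, 3.0, 17.2])
    def test_homogeneity(self, c, rng):
        x = rng.normal(size=(7, 2))
        assert centroid_size(c * x) == pytest.approx(c * centroid_size(x))

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((4, 2)))


class TestGpa:
    def test_exact_rigid_similarity_removal(self):
        base = SQUARE + np.array([0.3, -0.1]) * np.arange(4)[:, None]
        moved = 2.0 * base @ _rot(np.deg2rad(30)) + np.array([5.0, 7.0])
        ds = _make_dataset([base, moved])
        fit = gpa(ds)
        d = np.sum((fit.aligned_reference[0] - fit.aligned_reference[1]) ** 2)
        assert np.sqrt(d) <= 1e-9

    def test_fixed_point_of_aligned_input(self):
        # already centered, unit-size, mutually aligned data in the
        # canonical (principal-axes) pose passes through unchanged
        from mcnet.procrustes import _principal_axis_gauge

        shape = np.array([[1.5, 0.2], [-1.2, 0.4], [-0.2, -0.5], [-0.1, -0.1]])
        shape -= shape.mean(axis=0)
        shape /= centroid_size(shape)
        base = shape @ _principal_axis_gauge(shape)
        ds = _make_dataset([base, base, base])
        fit = gpa(ds)
        for aligned in fit.aligned_reference:
            np.testing.assert_allclose(aligned, base, atol=1e-9)

    def test_consensus_recovers_generating_mean(self, rng):
        # 50 specimens = mean shape + isotropic noise sigma=0.01
        mean = SQUARE / centroid_size(SQUARE)
        sigma = 0.01
        configs = [mean + rng.normal(0, sigma, mean.shape) for _ in range(50)]
        fit = gpa(_make_dataset(configs))
        # gauge-align the consensus back onto the generating mean
        u, _, vt = np.linalg.svd(fit.consensus.T @ mean)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        diff = fit.consensus @ r - mean
        assert np.max(np.abs(diff)) < 3 * sigma / np.sqrt(50)

    def test_invariances_and_unit_constraints(self, rng):
        configs = [SQUARE + rng.normal(0, 0.05, SQUARE.shape) for _ in range(6)]
        ds = _make_dataset(configs)
        fit = gpa(ds)
        # centroids at origin, consensus unit size, rotations proper
        for a in fit.aligned_reference:
            np.testing.assert_allclose(a.mean(axis=0), 0.0, atol=1e-9)
        assert np.sqrt(np.sum(fit.consensus**2)) == pytest.approx(1.0, abs=1e-9)
        for r in fit.rotations:
            np.testing.assert_allclose(r @ r.T, np.eye(2), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)
        # invariance to arbitrary per-configuration similarity pre-transforms
        moved = [
            c @ _rot(rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 2.0)
            + rng.normal(0, 5, 2)
            for c in configs
        ]
        fit2 = gpa(_make_dataset(moved))
        np.testing.assert_allclose(
            fit2.aligned_reference, fit.aligned_reference, atol=1e-9
        )

    def test_monotone_residual_history(self, rng):
        configs = [SQUARE + rng.normal(0, 0.2, SQUARE.shape) for _ in range(8)]
        fit = gpa(_make_dataset(configs))
        hist = np.array(fit.residual_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_single_configuration_rejected(self):
        with pytest.raises(StructureError):
            gpa(_make_dataset([SQUARE]))


class TestTransfer:
    def test_measurement_points_copying_references(self, rng):
        refs = [SQUARE + rng.normal(0, 0.1, SQUARE.shape) for _ in range(4)]
        ds = _make_dataset(refs, [r.copy() for r in refs])
        fit = gpa(ds)
        aligned = transfer(fit, ds)
        np.testing.assert_allclose(aligned.coords, fit.aligned_reference, atol=1e-9)

    def test_translation_only_configs_transfer_identically(self):
        mp = np.array([[0.2, 0.3], [0.4, -0.1]])
        ds = _make_dataset(
            [SQUARE, SQUARE + np.array([10.0, -3.0])],
            [mp, mp + np.array([10.0, -3.0])],
        )
        fit = gpa(ds)
        aligned = transfer(fit, ds)
        np.testing.assert_allclose(aligned.coords[0], aligned.coords[1], atol=1e-9)

    def test_nuisance_removal_matches_clean_generation(self):
        # zero noise: the recovered coordinates equal the clean (nuisance-free)
        # generation up to one global similarity (the consensus gauge)
        spec = SyntheticSpec(
            n_specimens=8,
            k_reference=7,
            modules=(("MP1", "MP2"), ("MP3", "MP4")),
            module_effect_sd=0.1,
            noise_sd=0.0,
            digitization_sd=0.0,
            replicates=1,
            seed=5,
        )
        syn = generate(spec)
        fit = gpa(syn.dataset)
        aligned = transfer(fit, syn.dataset)
        clean = syn.clean_measurement_coords
        # fit the global gauge on the pooled clouds
        a = clean.reshape(-1, 2)
        b = aligned.coords.reshape(-1, 2)
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        scale = np.sqrt(np.sum(bc**2) / np.sum(ac**2))
        u, _, vt = np.linalg.svd(ac.T @ bc)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        resid = ac @ r * scale - bc
        rms = np.sqrt(np.mean(resid**2))
        assert rms <= 1e-6

    def test_missing_specimen_is_mismatch(self):
        refs = [SQUARE, SQUARE * 1.1, SQUARE * 0.9]
        ds = _make_dataset(refs)
        fit = gpa(_make_dataset(refs[:2]))
        with pytest.raises(MismatchError):
            transfer(fit, ds)

    def test_commutes_with_specimen_relabeling(self, rng):
        refs = [SQUARE + rng.normal(0, 0.1, SQUARE.shape) for _ in range(3)]
        mps = [rng.normal(0, 0.5, (2, 2)) for _ in range(3)]
        ds = _make_dataset(refs, mps)
        perm = [2, 0, 1]
        ds_perm = _make_dataset(
            [refs[i] for i in perm],
            [mps[i] for i in perm],
            specimens=[(f"s{i+1}", 1) for i in perm],
        )
        a = transfer(gpa(ds), ds)
        b = transfer(gpa(ds_perm), ds_perm)
        lookup = {s: i for i, s in enumerate(b.specimen_ids)}
        for i, s in enumerate(a.specimen_ids):
            np.testing.assert_allclose(a.coords[i], b.coords[lookup[s]], atol=1e-9)


def _aligned(coords, specimens, replicates):
    k = coords.shape[1]
    return AlignedDataset(
        coords, tuple(f"MP{i+1}" for i in range(k)), specimens, replicates
    )


class TestProcrustesAnova:
    def test_identical_replicates_zero_error(self, rng):
        base = rng.normal(size=(3, 4, 2))
        coords = np.repeat(base, 2, axis=0)
        spec = ("a", "a", "b", "b", "c", "c")
        aligned = _aligned(coords, spec, (1, 2, 1, 2, 1, 2))
        tab = procrustes_anova(aligned)
        assert tab.ss_error == 0.0
        assert tab.zero_error
        assert np.isinf(tab.f_ratio)

    def test_additivity_and_signal_dominance(self, rng):
        # mirrors the replicated-digitization design: n=24 specimens, r=2
        n, r, k = 24, 2, 5
        ind = rng.normal(0, 0.05, size=(n, k, 2))
        coords = np.empty((n * r, k, 2))
        spec, reps = [], []
        for i in range(n):
            for j in range(r):
                coords[i * r + j] = ind[i] + rng.normal(0, 0.005, (k, 2))
                spec.append(f"s{i}")
                reps.append(j + 1)
        aligned = _aligned(coords, tuple(spec), tuple(reps))
        tab = procrustes_anova(aligned)
        grand = coords.mean(axis=0)
        ss_total = float(np.sum((coords - grand) ** 2))
        assert tab.ss_individual + tab.ss_error == pytest.approx(ss_total, rel=1e-9)
        assert tab.f_ratio > 10.0
        assert tab.p_value < 1e-6
        assert tab.df_individual == (n - 1) * (2 * k - 4)
        assert tab.df_error == n * (r - 1) * (2 * k - 4)

    def test_null_f_centered_near_one(self, rng):
        # no individual effect: F should scatter around 1
        n, r, k = 6, 2, 4
        fs = []
        for _ in range(200):
            coords = np.tile(rng.normal(size=(1, k, 2)), (n * r, 1, 1))
            coords = coords + rng.normal(0, 0.01, coords.shape)
            spec = tuple(f"s{i}" for i in range(n) for _ in range(r))
            reps = tuple(j + 1 for _ in range(n) for j in range(r))
            fs.append(procrustes_anova(_aligned(coords, spec, reps)).f_ratio)
        assert 0.85 < np.mean(fs) < 1.25

    def test_single_replicate_rejected(self, rng):
        aligned = _aligned(rng.normal(size=(3, 4, 2)), ("a", "b", "c"), (1, 1, 1))
        with pytest.raises(DesignError):
            procrustes_anova(aligned)

    def test_unbalanced_design_rejected(self, rng):
        aligned = _aligned(
            rng.normal(size=(5, 4, 2)), ("a", "a", "b", "b", "b"), (1, 2, 1, 2, 3)
        )
        with pytest.raises(DesignError):
            procrustes_anova(aligned)
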