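import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from groovekit import (
    GrooveSimSpec,
    pairwise_rmsd_matrix,
    representative_frame,
    rmsd_series,
    rmsf_profile,
    simulate_trajectory,
    superpose,
)
from groovekit.io import Trajectory, calpha_indices


def random_rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return R, t


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        P = rng.normal(size=(6, 3))
        fit = superpose(P, P)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rigid_motion(self, rng):
        P = rng.normal(size=(5, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ Rz.T + np.array([1.0, 2.0, 3.0])
        fit = superpose(P, Q)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.rotation, Rz, atol=1e-10)
        np.testing.assert_allclose(fit.apply(P), Q, atol=1e-10)

    def test_agrees_with_independent_least_squares_oracle(self, rng):
        # scipy's align_vectors solves the same Wahba problem independently
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        fit = superpose(P, Q)
        _, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert fit.rmsd == pytest.approx(rssd / np.sqrt(4), abs=1e-3)

    def test_no_rotation_beats_the_optimum(self, rng):
        # coarse rotation grid never finds a smaller RMSD
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        best = superpose(P, Q).rmsd
        P0, Q0 = P - P.mean(0), Q - Q.mean(0)
        angles = np.linspace(0, 330, 12)
        for a in angles:
            for b in angles:
                for c in angles:
                    R = Rotation.from_euler("zyx", [a, b, c], degrees=True).as_matrix()
                    rmsd = np.sqrt(((P0 @ R.T - Q0) ** 2).sum() / 4)
                    assert rmsd >= best - 1e-9

    def test_reflection_case_returns_proper_rotation(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P.copy()
        Q[:, 2] *= -1  # mirrored set
        fit = superpose(P, Q)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0)
        assert fit.rmsd > 0

    def test_rmsd_invariant_to_rigid_motion_of_either_input(self, rng):
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        base = superpose(P, Q).rmsd
        R, t = random_rigid(rng)
        assert superpose(P @ R.T + t, Q).rmsd == pytest.approx(base, abs=1e-9)
        assert superpose(P, Q @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize(
        "bad_mobile,bad_ref",
        [(np.zeros((2, 3)), np.zeros((2, 3))), (np.zeros((4, 3)), np.zeros((5, 3)))],
    )
    def test_input_validation(self, bad_mobile, bad_ref):
        with pytest.raises(ValueError):
            superpose(bad_mobile, bad_ref)


def jitter_trajectory(n_frames=50, sigma=0.5, seed=0, n_atoms=12):
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=4.0, size=(n_atoms, 3))
    coords = base + rng.normal(scale=sigma, size=(n_frames, n_atoms, 3))
    from groovekit.io import Atom, Structure

    atoms = [
        Atom("CA", "C", i + 1, "ALA", "A", tuple(base[i])) for i in range(n_atoms)
    ]
    return Trajectory(Structure(atoms), coords, dt=0.01)


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self):
        t = jitter_trajectory(sigma=0.0, n_frames=5)
        s = rmsd_series(t, np.arange(12))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-10)

    def test_pure_translation_is_removed(self, rng):
        t = jitter_trajectory(sigma=0.0, n_frames=4)
        coords = t.coords.copy()
        for k in range(1, 4):
            coords[k] += rng.normal(scale=3.0, size=3)
        t2 = Trajectory(t.topology, coords, dt=t.dt)
        s = rmsd_series(t2, np.arange(12))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_matches_independent_per_frame_recomputation(self, rng):
        t = jitter_trajectory(sigma=0.5, n_frames=20, seed=3)
        s = rmsd_series(t, np.arange(12), reference_frame=0)
        ref = t.coords[0] - t.coords[0].mean(0)
        for k in range(t.n_frames):
            mob = t.coords[k] - t.coords[k].mean(0)
            _, rssd = Rotation.align_vectors(ref, mob)
            assert s.values[k] == pytest.approx(rssd / np.sqrt(12), abs=1e-9)

    def test_reference_frame_out_of_range(self):
        t = jitter_trajectory(n_frames=5)
        with pytest.raises(IndexError):
            rmsd_series(t, np.arange(12), reference_frame=99)


class TestRmsfProfile:
    def test_static_trajectory_gives_zero_profile(self):
        t = jitter_trajectory(sigma=0.0, n_frames=4)
        prof = rmsf_profile(t, np.arange(12))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        # closed form for iid isotropic Gaussian displacements about a rigid
        # body: per-atom RMSF = sigma * sqrt(3); the 6 rigid-body degrees of
        # freedom absorbed by the fit shrink it by sqrt(1 - 6/(3N)).
        sigma, n_atoms = 0.5, 30
        t = jitter_trajectory(n_frames=2000, sigma=sigma, seed=11, n_atoms=n_atoms)
        prof = rmsf_profile(t, np.arange(n_atoms))
        expected = sigma * np.sqrt(3.0)
        assert prof.values.mean() == pytest.approx(expected, rel=0.05)

    def test_amplified_residue_is_argmax(self):
        spec = GrooveSimSpec(
            n_frames=300,
            residue_jitter=0.2,
            jitter_overrides=((("A", 7), 0.6),),
            ligand=False,
            seed=21,
        )
        t = simulate_trajectory(spec)
        sel = calpha_indices(t.topology, "A")
        prof = rmsf_profile(t, sel)
        assert prof.argmax_resid() == 7

    def test_invariant_to_global_rigid_motion(self, rng):
        t = jitter_trajectory(n_frames=40, sigma=0.3, seed=5)
        prof1 = rmsf_profile(t, np.arange(12))
        R, tr = random_rigid(rng)
        t2 = Trajectory(t.topology, t.coords @ R.T + tr, dt=t.dt)
        prof2 = rmsf_profile(t2, np.arange(12))
        np.testing.assert_allclose(prof1.values, prof2.values, atol=1e-8)

    def test_single_frame_is_an_error(self):
        t = jitter_trajectory(n_frames=1)
        with pytest.raises(ValueError):
            rmsf_profile(t, np.arange(12))


class TestRepresentativeFrame:
    def test_identical_frames_tie_break_to_first_of_window(self):
        t = jitter_trajectory(sigma=0.0, n_frames=6)
        assert representative_frame(t, np.arange(12), window=4) == 2

    def test_three_frame_toy_matches_hand_enumeration(self):
        # The y-pattern (+,-,-,+) on mirror-symmetric x positions is
        # orthogonal to every rigid-body mode, so the optimal fit is the
        # identity and pairwise RMSDs equal |Δd| exactly:
        # d01=1, d02=4, d12=3  ->  mean distances frame0: 2.5, frame1: 2.0,
        # frame2: 3.5  ->  the medoid is frame 1.
        base = np.array([[x, 0.0, 0.0] for x in (-15.0, -5.0, 5.0, 15.0)])
        pattern = np.array([1.0, -1.0, -1.0, 1.0])
        frames = []
        for d in (0.0, 1.0, 4.0):
            f = base.copy()
            f[:, 1] += d * pattern
            frames.append(f)
        from groovekit.io import Atom, Structure

        atoms = [Atom("CA", "C", i + 1, "ALA", "A", tuple(base[i])) for i in range(4)]
        t = Trajectory(Structure(atoms), np.array(frames), dt=0.1)
        M = pairwise_rmsd_matrix(t.coords)
        np.testing.assert_allclose(
            [M[0, 1], M[0, 2], M[1, 2]], [1.0, 4.0, 3.0], atol=1e-8
        )
        assert representative_frame(t, np.arange(4), window=3) == 1

    def test_equals_brute_force_medoid(self):
        t = jitter_trajectory(sigma=0.8, n_frames=50, seed=13)
        sel = np.arange(12)
        got = representative_frame(t, sel, window=50)
        # brute force with an independent RMSD implementation
        K = 50
        M = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                a = t.coords[i] - t.coords[i].mean(0)
                b = t.coords[j] - t.coords[j].mean(0)
                _, rssd = Rotation.align_vectors(b, a)
                M[i, j] = M[j, i] = rssd / np.sqrt(12)
        assert got == int(np.argmin(M.mean(axis=1)))

    def test_result_always_inside_window(self):
        t = jitter_trajectory(sigma=0.4, n_frames=30, seed=17)
        idx = representative_frame(t, np.arange(12), window=10)
        assert 20 <= idx < 30

    def test_window_validation(self):
        t = jitter_trajectory(n_frames=5)
        with pytest.raises(ValueError):
            representative_frame(t, np.arange(12), window=6)
        with pytest.raises(ValueError):
            representative_frame(t, np.arange(12), window=1)
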