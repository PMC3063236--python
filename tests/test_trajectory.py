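import warnings

import numpy as np
import pytest

from tcrstalk.synthetic_data import GaussianTrajSpec, make_gaussian_trajectory
from tcrstalk.trajectory_analysis import (
    Selection,
    TrajectoryEnsemble,
    TrajectoryError,
    analytic_entropy,
    entropy_difference,
    mode_entropies,
    quasiharmonic_entropy,
    read_trajectory,
    rmsd_series,
)


def entropy_se(variances, n_frames, temperature=300.0):
    """Delta-method standard error of the entropy estimate: per-mode sample
    eigenvalues of a Gaussian have variance ~ 2 lambda^2/(n-1)."""
    lam = np.asarray(variances, float)
    eps = 1e-7
    grad = (mode_entropies(lam + eps, temperature)
            - mode_entropies(lam - eps, temperature)) / (2 * eps)
    return float(np.sqrt(np.sum(grad**2 * 2 * lam**2 / (n_frames - 1))))


class TestReadTrajectory:
    def test_frame_and_atom_counts(self, tmp_path):
        path = tmp_path / "t.pdb"
        make_gaussian_trajectory(GaussianTrajSpec(n_atoms=9, n_frames=100, seed=3),
                                 out_path=path)
        traj = read_trajectory(path, "B:104-119@N,CA,C")
        assert traj.n_frames == 100
        assert traj.n_atoms == 9
        assert set(np.round(traj.atom_masses, 3)) == {12.011, 14.007}

    def test_selection_mismatch_names_offending_model(self, tmp_path):
        path = tmp_path / "t.pdb"
        make_gaussian_trajectory(GaussianTrajSpec(n_atoms=9, n_frames=10, seed=3),
                                 out_path=path)
        lines = path.read_text().splitlines()
        # drop one ATOM line inside MODEL 7
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("MODEL") and l.split() == ["MODEL", "7"])
        end = lines.index("ENDMDL", start)
        atom_idx = next(i for i in range(start, end) if lines[i].startswith("ATOM"))
        del lines[atom_idx]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryError, match="model 7"):
            read_trajectory(path, "B:104-119@N,CA,C")

    def test_single_model_file_rejected(self, g_hairpin, tmp_path):
        from tcrstalk.structure_model import write_pdb
        struct, _ = g_hairpin
        path = tmp_path / "single.pdb"
        write_pdb(struct, path)
        with pytest.raises(TrajectoryError):
            read_trajectory(path, "B:104-119@N,CA,C")

    def test_selection_string_round_trip(self):
        sel = Selection.from_string("B:104-119@N,CA,C")
        assert sel.chain_id == "B"
        assert sel.res_range == (104, 119)
        assert sel.atom_names == ("N", "CA", "C")


class TestRmsdSeries:
    def test_identical_frames_give_zero(self, gaussian_traj):
        _, ens, _ = gaussian_traj
        frames = np.repeat(ens.frames[:1], 5, axis=0)
        traj = TrajectoryEnsemble(frames=frames, atom_masses=ens.atom_masses)
        series = rmsd_series(traj, frames[0])
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_rigidly_rotated_frames_fit_to_zero(self, gaussian_traj):
        from scipy.spatial.transform import Rotation
        _, ens, _ = gaussian_traj
        rng = np.random.default_rng(6)
        ref = ens.frames[0]
        frames = np.stack([
            ref @ Rotation.random(rng=rng).as_matrix().T + rng.normal(size=3)
            for _ in range(6)
        ])
        traj = TrajectoryEnsemble(frames=frames, atom_masses=ens.atom_masses)
        assert np.allclose(rmsd_series(traj, ref).values, 0.0, atol=1e-9)

    def test_single_displaced_atom_closed_form(self, gaussian_traj):
        """One atom displaced by d among n atoms, fitting on the others,
        gives RMSD d/sqrt(n) exactly."""
        _, ens, _ = gaussian_traj
        ref = ens.frames[0].copy()
        d = 0.9
        frame = ref.copy()
        frame[2] += np.array([0, 0, d])
        traj = TrajectoryEnsemble(frames=frame[None], atom_masses=ens.atom_masses)
        fit = np.array([i for i in range(ens.n_atoms) if i != 2])
        series = rmsd_series(traj, ref, fit_indices=fit)
        assert series.values[0] == pytest.approx(d / np.sqrt(ens.n_atoms))


class TestEntropy:
    def test_frozen_trajectory_has_zero_entropy(self, gaussian_traj):
        _, ens, _ = gaussian_traj
        frames = np.repeat(ens.frames[:1], 8, axis=0)
        traj = TrajectoryEnsemble(frames=frames, atom_masses=ens.atom_masses)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = quasiharmonic_entropy(traj)
        assert result.entropy == 0.0
        assert result.n_modes_used == 0

    def test_recovers_analytic_entropy_within_three_se(self, gaussian_traj):
        spec, ens, analytic = gaussian_traj
        est = quasiharmonic_entropy(ens)
        se = entropy_se(spec.variance_vector(), spec.n_frames)
        assert abs(est.entropy - analytic) < 3 * se
        assert est.n_modes_used == 3 * spec.n_atoms - 6

    def test_entropy_monotone_in_fluctuation_scale(self):
        e1, _ = make_gaussian_trajectory(
            GaussianTrajSpec(n_atoms=6, n_frames=600, variances=0.03, seed=8))
        e4, _ = make_gaussian_trajectory(
            GaussianTrajSpec(n_atoms=6, n_frames=600, variances=0.12, seed=8))
        assert quasiharmonic_entropy(e4).entropy > quasiharmonic_entropy(e1).entropy

    def test_invariant_under_per_frame_rigid_motion(self):
        base = GaussianTrajSpec(n_atoms=9, n_frames=800,
                                variances=tuple(np.geomspace(0.02, 0.2, 21)),
                                seed=17)
        moved = GaussianTrajSpec(**{**base.__dict__, "rigid_motion": True})
        e0, _ = make_gaussian_trajectory(base)
        e1, _ = make_gaussian_trajectory(moved)
        s0 = quasiharmonic_entropy(e0).entropy
        s1 = quasiharmonic_entropy(e1).entropy
        assert abs(s0 - s1) < 1e-3

    def test_invariant_under_atom_permutation(self, gaussian_traj):
        _, ens, _ = gaussian_traj
        rng = np.random.default_rng(4)
        perm = rng.permutation(ens.n_atoms)
        permuted = TrajectoryEnsemble(frames=ens.frames[:, perm, :],
                                      atom_masses=ens.atom_masses[perm])
        s0 = quasiharmonic_entropy(ens).entropy
        s1 = quasiharmonic_entropy(permuted).entropy
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_convergence_toward_analytic_value(self):
        """Mean absolute error of the estimate shrinks with more frames."""
        variances = tuple(np.geomspace(0.03, 0.15, 12))
        errors = []
        for n_frames in (150, 600, 2400):
            errs = []
            for seed in (1, 2, 3):
                spec = GaussianTrajSpec(n_atoms=6, n_frames=n_frames,
                                        variances=variances, seed=seed)
                ens, analytic = make_gaussian_trajectory(spec)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    errs.append(abs(quasiharmonic_entropy(ens).entropy - analytic))
            errors.append(np.mean(errs))
        assert errors[2] < errors[0]

    def test_fewer_than_two_frames_rejected(self, gaussian_traj):
        _, ens, _ = gaussian_traj
        traj = TrajectoryEnsemble(frames=ens.frames[:1],
                                  atom_masses=ens.atom_masses)
        with pytest.raises(TrajectoryError):
            quasiharmonic_entropy(traj)


class TestEntropyDifference:
    def test_identical_trajectories_give_zero(self, gaussian_traj):
        _, ens, _ = gaussian_traj
        assert entropy_difference(ens, ens) == pytest.approx(0.0)

    def test_floppy_minus_stiff_is_positive(self):
        """Larger-amplitude (wild-type-like) ensemble minus stiffer
        (mutant-like) ensemble gives a positive entropy difference, and the
        estimate tracks the closed-form difference."""
        floppy_spec = GaussianTrajSpec(n_atoms=9, n_frames=1500, variances=0.12,
                                       seed=23)
        stiff_spec = GaussianTrajSpec(n_atoms=9, n_frames=1500, variances=0.03,
                                      seed=24)
        floppy, s_floppy = make_gaussian_trajectory(floppy_spec)
        stiff, s_stiff = make_gaussian_trajectory(stiff_spec)
        diff = entropy_difference(floppy, stiff)
        assert diff > 0
        expected = s_floppy - s_stiff
        tol = 3 * (entropy_se(floppy_spec.variance_vector(), 1500)
                   + entropy_se(stiff_spec.variance_vector(), 1500))
        assert abs(diff - expected) < tol

    def test_antisymmetry(self):
        a, _ = make_gaussian_trajectory(
            GaussianTrajSpec(n_atoms=6, n_frames=400, variances=0.10, seed=31))
        b, _ = make_gaussian_trajectory(
            GaussianTrajSpec(n_atoms=6, n_frames=400, variances=0.05, seed=32))
        assert entropy_difference(a, b) == pytest.approx(
            -entropy_difference(b, a))


class TestAnalyticOracle:
    def test_zero_below_floor(self):
        assert analytic_entropy([1e-12, 1e-10]) == 0.0

    def test_monotone_in_mode_variance(self):
        lams = np.geomspace(1e-3, 10, 40)
        s = mode_entropies(lams, 300.0)
        assert np.all(np.diff(s) > 0)
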