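import numpy as np
import pytest
import scipy.constants as const
from scipy.spatial.transform import Rotation

from alfgp.geometry import Geometry, compute_alf, featurize_set, periodic_mask
from alfgp.gpr import Hyperparameters, KernelSpec, fit_gpr, predict
from alfgp.molecule import (AtomicModelEnsemble, error_metrics, filter_dataset,
                            finite_diff_forces, kabsch_rmsd,
                            minimize_geometry, normal_modes,
                            perturb_along_mode, reconstruct_molecular)
from alfgp.synthetic import default_toy, equilibrium_geometry


def _freq_cm1(k_kjmol_a2, mu_amu):
    """Independent closed form: harmonic frequency in cm^-1 from scipy
    constants only."""
    k_si = k_kjmol_a2 * 1e3 / const.Avogadro / 1e-20  # J/m^2
    mu_si = mu_amu * const.atomic_mass
    return np.sqrt(k_si / mu_si) / (2 * np.pi * const.c * 100.0)


# ---------------------------------------------------------------------------
# Reconstruction and filtering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_ensemble(small_conformers):
    """Interpolating per-atom E_IQA models on 60 frames."""
    train = small_conformers.subset(np.arange(60))
    alf = compute_alf(train.geometry(0))
    spec = KernelSpec(periodic_mask(train.n_atoms))
    models = {}
    for a in range(train.n_atoms):
        X = featurize_set(train, alf, a)
        y = train.atomic_properties["E_IQA"][:, a]
        models[(a, "E_IQA")] = fit_gpr(
            X, y, Hyperparameters(np.full(spec.n_feats, 1.0), 1e-8), spec,
            target_name="E_IQA", center_atom=a)
    return AtomicModelEnsemble(models, alf, list(train.atom_symbols)), train


def test_reconstruct_is_sum_of_atomic_predictions(tiny_ensemble,
                                                  small_conformers):
    ensemble, _ = tiny_ensemble
    test = small_conformers.subset(np.arange(60, 80))
    total, per_atom = reconstruct_molecular(ensemble, test, "E_IQA")
    assert total.shape == (20,)
    assert per_atom.shape == (20, 4)
    assert np.allclose(total, per_atom.sum(axis=1), atol=1e-12)
    for a in range(4):
        X = featurize_set(test, ensemble.alf, a)
        direct = predict(ensemble.models[(a, "E_IQA")], X)
        assert np.allclose(per_atom[:, a], direct, atol=1e-12)


def test_reconstruct_molecular_mae_below_noise(tiny_ensemble):
    # interpolating models reproduce the noisy atomic observations, so the
    # molecular reconstruction error on the training frames stays at the
    # scale of the injected atomic noise (0.5 kJ/mol per atom, 4 atoms)
    ensemble, train = tiny_ensemble
    total, _ = reconstruct_molecular(ensemble, train, "E_IQA")
    met = error_metrics(total, train.molecular_properties["E_IQA"])
    assert met["MAE"] < 4 * 0.5


def test_reconstruct_missing_model_raises(tiny_ensemble, small_conformers):
    ensemble, _ = tiny_ensemble
    partial = AtomicModelEnsemble(
        {k: v for k, v in ensemble.models.items() if k[0] != 2},
        ensemble.alf, ensemble.atom_symbols)
    with pytest.raises(KeyError, match=r"atoms \[2\]"):
        reconstruct_molecular(partial, small_conformers, "E_IQA")


def test_filter_dataset_keeps_exact_and_is_idempotent(small_conformers):
    # remove the observation noise: copy exact molecular values into the
    # atomic channels so decomposition is exact
    cs = small_conformers.subset(np.arange(30))
    cs.atomic_properties["E_IQA"] = np.tile(
        cs.molecular_properties["E_IQA"][:, None] / 4, (1, 4))
    cs.atomic_properties["Q00"] = np.tile(
        cs.molecular_properties["Q00"][:, None] / 4, (1, 4))
    kept, rep = filter_dataset(cs)
    assert rep.n_kept == 30 and rep.n_removed_energy == 0
    kept2, rep2 = filter_dataset(kept)
    assert rep2.n_kept == kept.n_frames and rep2.n_removed_energy == 0 \
        and rep2.n_removed_charge == 0


def test_filter_dataset_margins(small_conformers):
    cs = small_conformers.subset(np.arange(10))
    cs.atomic_properties["E_IQA"] = np.tile(
        cs.molecular_properties["E_IQA"][:, None] / 4, (1, 4))
    cs.atomic_properties["Q00"] = np.tile(
        cs.molecular_properties["Q00"][:, None] / 4, (1, 4))
    cs.atomic_properties["E_IQA"][3, 0] += 2.0      # > 1 kJ/mol -> removed
    cs.atomic_properties["Q00"][7, 0] += 0.0005     # 0.5 me -> kept
    kept, rep = filter_dataset(cs)
    assert kept.n_frames == 9
    assert rep.n_removed_energy == 1 and rep.n_removed_charge == 0


def test_filter_dataset_missing_channel(small_conformers):
    cs = small_conformers.subset(np.arange(5))
    del cs.atomic_properties["Q00"]
    with pytest.raises(KeyError, match="Q00"):
        filter_dataset(cs)


def test_error_metrics_hand_cases():
    ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    m = error_metrics(ref, ref)
    assert m["MAE"] == 0.0 and m["RMSE"] == 0.0
    assert m["R2"] == pytest.approx(1.0, abs=1e-12)
    m = error_metrics(ref + 1.0, ref)
    assert m["MAE"] == pytest.approx(1.0) and m["RMSE"] == pytest.approx(1.0)
    assert m["R2"] == pytest.approx(1.0)
    pred = np.array([1.5, 1.5, 3.5, 3.5, 5.5])
    err = pred - ref
    m = error_metrics(pred, ref)
    assert m["MAE"] == pytest.approx(np.mean(np.abs(err)))
    assert m["RMSE"] == pytest.approx(np.sqrt(np.mean(err ** 2)))
    assert m["R2"] == pytest.approx(np.corrcoef(pred, ref)[0, 1] ** 2)
    with pytest.raises(ValueError):
        error_metrics(np.array([1.0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# Finite differences and normal modes
# ---------------------------------------------------------------------------

def _pair_spring(k, r0):
    def energy(g):
        r = np.linalg.norm(g.coordinates[1] - g.coordinates[0])
        return 0.5 * k * (r - r0) ** 2
    return energy


def test_finite_diff_forces_harmonic():
    k, r0 = 800.0, 1.2
    g = Geometry(["H", "Cl"], np.array([[0.0, 0, 0], [1.5, 0, 0]]))
    F = finite_diff_forces(_pair_spring(k, r0), g, h=0.01)
    # analytic force on atom 1 along -x: -k (r - r0)
    assert F[1, 0] == pytest.approx(-k * (1.5 - r0), rel=1e-4)
    assert F[0, 0] == pytest.approx(k * (1.5 - r0), rel=1e-4)
    assert np.allclose(F[:, 1:], 0.0, atol=1e-8)


def test_finite_diff_forces_convergence_order():
    # cubic-perturbed 1-D toy: FD error scales as h^2
    def energy(g):
        x = g.coordinates[1, 0]
        return 0.5 * 100.0 * (x - 1.0) ** 2 + 5.0 * (x - 1.0) ** 3

    g = Geometry(["H", "H"], np.array([[0.0, 5, 0], [1.3, 0, 0]]))
    exact = -(100.0 * 0.3 + 15.0 * 0.3 ** 2)  # F = -dE/dx at x = 1.3
    e1 = abs(finite_diff_forces(energy, g, h=0.02)[1, 0] - exact)
    e2 = abs(finite_diff_forces(energy, g, h=0.01)[1, 0] - exact)
    assert e1 / e2 == pytest.approx(4.0, rel=0.15)


def test_finite_diff_forces_validation():
    g = Geometry(["H", "H"], np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with pytest.raises(ValueError, match="positive"):
        finite_diff_forces(lambda g: 0.0, g, h=0.0)
    with pytest.raises(ValueError, match="non-finite"):
        finite_diff_forces(lambda g: float("nan"), g)


def test_normal_modes_diatomic_closed_form():
    k, r0 = 2000.0, 1.1
    g = Geometry(["H", "Cl"], np.array([[0.0, 0, 0], [r0, 0, 0]]))
    vib = normal_modes(_pair_spring(k, r0), g, h=0.01)
    masses = g.masses
    mu = masses[0] * masses[1] / masses.sum()
    expected = _freq_cm1(k, mu)
    assert vib.frequencies[-1] == pytest.approx(expected, rel=0.005)
    # translations are exactly zero; the two rotations carry the FD
    # truncation artifact O(sqrt(k/m) h), well below the true frequency
    assert np.all(np.abs(vib.frequencies[:-1]) < 0.02 * expected)
    assert np.all(np.diff(vib.frequencies) >= 0)


def test_normal_modes_uncoupled_oscillators():
    # three independent 1-D oscillators on separate atoms/axes
    ks = (150.0, 400.0, 900.0)

    def energy(g):
        c = g.coordinates
        return 0.5 * (ks[0] * c[0, 0] ** 2 + ks[1] * c[1, 1] ** 2
                      + ks[2] * c[2, 2] ** 2)

    g = Geometry(["O", "C", "H"],
                 np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2.0, 0]]))
    vib = normal_modes(energy, g, h=0.01)
    masses = g.masses
    expected = sorted(_freq_cm1(k, m) for k, m in zip(ks, masses))
    assert np.allclose(vib.frequencies[-3:], expected, rtol=1e-6)


def test_cartesian_mode_unit_norm():
    g = equilibrium_geometry(default_toy())
    toy = default_toy()
    from alfgp.synthetic import molecular_energy

    vib = normal_modes(lambda gg: molecular_energy(toy, gg), g)
    mode = vib.cartesian_mode(-1, g.masses)
    assert np.linalg.norm(mode) == pytest.approx(1.0)


def test_perturb_along_mode():
    g = equilibrium_geometry(default_toy())
    mode = np.zeros((4, 3))
    mode[0, 0] = 1.0
    same = perturb_along_mode(g, mode, 0.0)
    assert np.array_equal(same.coordinates, g.coordinates)
    moved = perturb_along_mode(g, mode, 0.3)
    assert np.linalg.norm(moved.coordinates - g.coordinates) == \
        pytest.approx(0.3)
    with pytest.raises(ValueError, match="zero mode"):
        perturb_along_mode(g, np.zeros((4, 3)), 0.1)


# ---------------------------------------------------------------------------
# Geometry optimization
# ---------------------------------------------------------------------------

def test_minimize_from_minimum_is_noop():
    k, r0 = 500.0, 1.0
    g = Geometry(["H", "H"], np.array([[0.0, 0, 0], [r0, 0, 0]]))
    res = minimize_geometry(_pair_spring(k, r0), g, force_tol=1.0)
    assert res.converged and res.n_steps == 0
    assert np.array_equal(res.geometry.coordinates, g.coordinates)


def test_minimize_energy_trace_non_increasing():
    k, r0 = 500.0, 1.0
    g = Geometry(["H", "H"], np.array([[0.0, 0, 0], [1.4, 0, 0]]))
    res = minimize_geometry(_pair_spring(k, r0), g, force_tol=0.5)
    assert res.converged
    assert np.all(np.diff(res.energies) <= 0)
    r_final = np.linalg.norm(res.geometry.coordinates[1]
                             - res.geometry.coordinates[0])
    assert r_final == pytest.approx(r0, abs=0.01)


def test_minimize_divergence_raises():
    # surface oscillating faster than the FD stencil: the FD "force" points
    # uphill, every trial is rejected, and the 50-shrinkage guard must fire
    w = 3 * np.pi / (2 * 0.01)

    def adversarial(g):
        return float(np.sin(w * g.coordinates).sum())

    g0 = Geometry(["H", "H"],
                  np.array([[0.013, 0.002, 0.007], [1.004, 0.003, 0.009]]))
    with pytest.raises(RuntimeError, match="50 shrinkages"):
        minimize_geometry(adversarial, g0, force_tol=-1.0, max_steps=200)


def test_minimize_rejects_non_finite_start():
    g = Geometry(["H", "H"], np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    with pytest.raises(ValueError, match="starting geometry"):
        minimize_geometry(lambda g: float("inf"), g)


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def test_kabsch_identity_and_rigid_invariance():
    g = equilibrium_geometry(default_toy())
    assert kabsch_rmsd(g, g) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(9)
    for _ in range(5):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3)
        moved = Geometry(g.atom_symbols, g.coordinates @ R.T + t)
        assert kabsch_rmsd(g, moved) < 1e-8


def test_kabsch_two_atom_hand_value():
    g1 = Geometry(["H", "H"], np.array([[0.0, 0, 0], [2.0, 0, 0]]))
    g2 = Geometry(["H", "H"], np.array([[0.0, 0, 0], [4.0, 0, 0]]))
    # centered: (+-1) vs (+-2) -> per-atom deviation 1 -> RMSD exactly 1
    assert kabsch_rmsd(g1, g2) == pytest.approx(1.0, abs=1e-10)
    assert kabsch_rmsd(g2, g1) == pytest.approx(kabsch_rmsd(g1, g2),
                                                abs=1e-12)


def test_kabsch_atom_mismatch():
    g1 = Geometry(["H", "H"], np.array([[0.0, 0, 0], [2.0, 0, 0]]))
    g2 = Geometry(["H", "O"], np.array([[0.0, 0, 0], [2.0, 0, 0]]))
    with pytest.raises(ValueError, match="share atom"):
        kabsch_rmsd(g1, g2)
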