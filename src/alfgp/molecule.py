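"""Deployment of trained atomic models at the molecular level.

Molecular properties are reconstructed as sums of atomic predictions (the
additivity the atomic partition guarantees); datasets are filtered on how
well the tabulated atomic properties reconstruct the molecular references;
harmonic vibrational analysis uses a mass-weighted Hessian assembled from
central finite differences of the forces; geometry optimization is a damped
steepest-descent force follower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (ALFDefinition, ConformerSet, Geometry, featurize,
                       featurize_set)
from .gpr import GPRModel, predict

__all__ = [
    "AtomicModelEnsemble",
    "VibrationResult",
    "FilterReport",
    "reconstruct_molecular",
    "filter_dataset",
    "error_metrics",
    "finite_diff_forces",
    "normal_modes",
    "perturb_along_mode",
    "minimize_geometry",
    "kabsch_rmsd",
]

# kJ/mol, amu, angstrom -> cm^-1 (CODATA): omega^2 [s^-2] = lambda * 1e26,
# since (1000 J / N_A) / (amu * A^2) = 1e26 s^-2 to 4e-10 relative error.
_KJMOL_AMU_A2_TO_S2 = 1.0e3 / (6.02214076e23 * 1.66053906660e-27 * 1e-20)
_C_CM_PER_S = 2.99792458e10


@dataclass
class AtomicModelEnsemble:
    """One GPR model per (atom, target property), sharing one ALF."""

    models: dict[tuple[int, str], GPRModel]
    alf: ALFDefinition
    atom_symbols: list[str]

    def atoms_for(self, target: str) -> list[int]:
        return sorted(a for (a, t) in self.models if t == target)


def reconstruct_molecular(ensemble: AtomicModelEnsemble,
                          conformers: ConformerSet, target: str
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame molecular value = sum over atoms of the predicted atomic
    value. Returns (molecular (F,), per_atom (F, N_atoms))."""
    n_atoms = conformers.n_atoms
    atoms = ensemble.atoms_for(target)
    if atoms != list(range(n_atoms)):
        missing = sorted(set(range(n_atoms)) - set(atoms))
        raise KeyError(f"missing atomic models for target {target!r}, "
                       f"atoms {missing}")
    per_atom = np.empty((conformers.n_frames, n_atoms))
    for a in atoms:
        X = featurize_set(conformers, ensemble.alf, a)
        per_atom[:, a] = predict(ensemble.models[(a, target)], X)
    return per_atom.sum(axis=1), per_atom


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed_energy: int
    n_removed_charge: int


def filter_dataset(conformers: ConformerSet, energy_margin: float = 1.0,
                   charge_margin: float = 0.001,
                   energy_key: str = "E_IQA", charge_key: str = "Q00"
                   ) -> tuple[ConformerSet, FilterReport]:
    """Keep frames whose atomic properties reconstruct the molecular
    references within the margins (defaults 1 kJ/mol and 1 me)."""
    for key in (energy_key, charge_key):
        if key not in conformers.atomic_properties:
            raise KeyError(f"missing atomic property channel {key!r}")
        if key not in conformers.molecular_properties:
            raise KeyError(f"missing molecular property channel {key!r}")
    de = np.abs(conformers.atomic_properties[energy_key].sum(axis=1)
                - conformers.molecular_properties[energy_key])
    dq = np.abs(conformers.atomic_properties[charge_key].sum(axis=1)
                - conformers.molecular_properties[charge_key])
    ok_e = de <= energy_margin
    ok_q = dq <= charge_margin
    keep = ok_e & ok_q
    report = FilterReport(conformers.n_frames, int(keep.sum()),
                          int((~ok_e).sum()), int((~ok_q).sum()))
    return conformers.subset(np.nonzero(keep)[0]), report


def error_metrics(predicted: np.ndarray, reference: np.ndarray) -> dict:
    """MAE, RMSE and squared Pearson correlation."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 points")
    err = predicted - reference
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.var(reference) == 0 or np.var(predicted) == 0:
        r2 = 1.0 if np.allclose(predicted, reference) else 0.0
    else:
        r2 = float(np.corrcoef(predicted, reference)[0, 1] ** 2)
    return {"MAE": mae, "RMSE": rmse, "R2": r2}


def finite_diff_forces(energy_fn, geometry: Geometry, h: float = 0.01
                       ) -> np.ndarray:
    """Central-difference forces F = -dE/dx (kJ/mol/A), shape (N, 3)."""
    if h <= 0:
        raise ValueError("displacement h must be positive")
    coords = geometry.coordinates
    forces = np.empty_like(coords)
    for i in range(geometry.n_atoms):
        for k in range(3):
            plus = coords.copy()
            plus[i, k] += h
            minus = coords.copy()
            minus[i, k] -= h
            ep = energy_fn(Geometry(geometry.atom_symbols, plus,
                                    geometry.frame_id))
            em = energy_fn(Geometry(geometry.atom_symbols, minus,
                                    geometry.frame_id))
            if not (np.isfinite(ep) and np.isfinite(em)):
                raise ValueError(
                    f"non-finite energy at displaced geometry (atom {i}, "
                    f"axis {k})")
            forces[i, k] = -(ep - em) / (2.0 * h)
    return forces


@dataclass
class VibrationResult:
    """Harmonic analysis: frequencies in cm^-1 (ascending; imaginary modes
    reported as negative) and mass-weighted eigenvectors as columns."""

    frequencies: np.ndarray  # (3N,)
    modes: np.ndarray        # (3N, 3N), column j <-> frequencies[j]
    displacement: float

    def cartesian_mode(self, j: int, masses: np.ndarray) -> np.ndarray:
        """Un-mass-weighted, unit-normalized Cartesian mode, shape (N, 3)."""
        v = self.modes[:, j].reshape(-1, 3) / np.sqrt(masses)[:, None]
        return v / np.linalg.norm(v)


def normal_modes(energy_fn, geometry: Geometry,
                 masses: np.ndarray | None = None,
                 h: float = 0.01) -> VibrationResult:
    """Mass-weighted Hessian by central differences of the forces.

    The Hessian is symmetrized by averaging; translational/rotational modes
    are not projected out and show up as near-zero frequencies.
    """
    n = geometry.n_atoms
    masses = geometry.masses if masses is None else np.asarray(masses, float)
    hess = np.empty((3 * n, 3 * n))
    coords = geometry.coordinates
    for i in range(n):
        for k in range(3):
            plus = coords.copy()
            plus[i, k] += h
            minus = coords.copy()
            minus[i, k] -= h
            fp = finite_diff_forces(
                energy_fn, Geometry(geometry.atom_symbols, plus), h)
            fm = finite_diff_forces(
                energy_fn, Geometry(geometry.atom_symbols, minus), h)
            # H[row, col] = d^2 E / dx_col dx_row = -dF_row/dx_col
            hess[:, 3 * i + k] = -(fp - fm).ravel() / (2.0 * h)
    hess = 0.5 * (hess + hess.T)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = hess * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals, evecs = np.linalg.eigh(mw)
    omega2 = evals * _KJMOL_AMU_A2_TO_S2
    freqs = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi *
                                                         _C_CM_PER_S)
    order = np.argsort(freqs)
    return VibrationResult(freqs[order], evecs[:, order], h)


def perturb_along_mode(q_min: Geometry, mode: np.ndarray, DF: float
                       ) -> Geometry:
    """Displace q_min by DF along a unit-normalized Cartesian mode vector."""
    mode = np.asarray(mode, dtype=float).reshape(q_min.n_atoms, 3)
    norm = np.linalg.norm(mode)
    if norm == 0:
        raise ValueError("zero mode vector")
    return Geometry(q_min.atom_symbols,
                    q_min.coordinates + DF * mode / norm,
                    q_min.frame_id)


@dataclass
class MinimizeResult:
    geometry: Geometry
    energies: np.ndarray
    n_steps: int
    converged: bool
    max_force: float


def minimize_geometry(energy_fn, q0: Geometry, max_steps: int = 2000,
                      force_tol: float = 1.0, h: float = 0.01,
                      step0: float = 1e-4) -> MinimizeResult:
    """Damped steepest descent on finite-difference forces.

    Steps along the force direction with an adaptive scalar step (grown on
    acceptance, halved on rejection); stops when max |F| < force_tol
    (kJ/mol/A) or after max_steps. The accepted-energy trace is
    non-increasing by construction; a step that cannot be made productive
    after 50 consecutive shrinkages raises with the trace attached.
    """
    coords = q0.coordinates.copy()
    e = energy_fn(q0)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at the starting geometry")
    energies = [e]
    alpha = step0
    for step in range(1, max_steps + 1):
        g = Geometry(q0.atom_symbols, coords)
        forces = finite_diff_forces(energy_fn, g, h)
        fmax = float(np.abs(forces).max())
        if fmax < force_tol:
            return MinimizeResult(g, np.array(energies), step - 1, True, fmax)
        rejected = 0
        while True:
            trial = coords + alpha * forces
            e_trial = energy_fn(Geometry(q0.atom_symbols, trial))
            if e_trial <= e:
                coords, e = trial, e_trial
                alpha *= 1.2
                break
            alpha *= 0.5
            rejected += 1
            if rejected >= 50:
                raise RuntimeError(
                    "geometry optimization diverged: no productive step "
                    f"after 50 shrinkages at step {step}; energy trace: "
                    f"{energies[-5:]}")
        energies.append(e)
    g = Geometry(q0.atom_symbols, coords)
    fmax = float(np.abs(finite_diff_forces(energy_fn, g, h)).max())
    return MinimizeResult(g, np.array(energies), max_steps, fmax < force_tol,
                          fmax)


def kabsch_rmsd(g1: Geometry, g2: Geometry) -> float:
    """Optimal-rotation, centroid-aligned RMSD (A) between two geometries."""
    if g1.atom_symbols != g2.atom_symbols:
        raise ValueError("geometries must share atom count and order")
    a = g1.coordinates - g1.coordinates.mean(axis=0)
    b = g2.coordinates - g2.coordinates.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    # residuals computed directly: the rssd returned by align_vectors loses
    # ~8 digits to cancellation when the two sets are near-identical
    resid = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
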