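"""Synthetic benchmark data with the statistical structure the method assumes.

Two generators are provided. The toy-molecule generator samples conformers of
a four-atom chain (an H-O-O-H, hydrogen-peroxide-like species) whose
molecular energy is an analytic function of its internal coordinates —
harmonic bonds and valence angles plus a cosine torsion — and whose atomic
energies and charges are exact partitions of the molecular values, so that
additive reconstruction holds to machine precision before observation noise
is added. The GP-draw generator samples targets from the composite kernel at
known hyperparameters, giving a parameter-recovery fixture with a known
answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConformerSet, Geometry
from .gpr import Hyperparameters, KernelSpec, covariance_matrix
from .molecule import filter_dataset

__all__ = [
    "ToyMoleculeSpec",
    "GPDrawSpec",
    "default_toy",
    "equilibrium_geometry",
    "geometry_from_internals",
    "internal_coordinates",
    "molecular_energy",
    "analytic_properties",
    "sample_conformers",
    "gp_draw",
    "make_benchmark",
]

_DEG = np.pi / 180.0


@dataclass
class ToyMoleculeSpec:
    """A 4-atom chain with one rotatable dihedral and an exact atomic
    partition of its energy and charge.

    Energies in kJ/mol, distances in angstrom, angles in radians, charges
    in e. The per-atom energy is e0_A + w_A * E_strain (sum of w = 1); the
    per-atom charge is q0_A + u_A * s(geometry) (sum of u = 0), with s a
    smooth function of the torsion and the central bond.
    """

    symbols: tuple[str, ...] = ("H", "O", "O", "H")
    r0: tuple[float, ...] = (0.96, 1.45, 0.96)
    k_bond: tuple[float, ...] = (3500.0, 2500.0, 3500.0)   # kJ/mol/A^2
    theta0: tuple[float, ...] = (100.0 * _DEG, 100.0 * _DEG)
    k_angle: tuple[float, ...] = (300.0, 300.0)            # kJ/mol/rad^2
    phi0: float = 112.0 * _DEG
    dihedral_amp: float = 12.0                             # kJ/mol
    e0: tuple[float, ...] = (-180.0, -1500.0, -1500.0, -180.0)
    partition_weights: tuple[float, ...] = (0.15, 0.35, 0.35, 0.15)
    q0: tuple[float, ...] = (0.42, -0.42, -0.42, 0.42)
    charge_response: tuple[float, ...] = (0.5, -0.5, -0.5, 0.5)
    c_phi: float = 0.02   # e per unit of cos(phi) deviation
    c_bond: float = 0.05  # e per angstrom of central-bond stretch
    noise_energy: float = 0.5      # kJ/mol per atom
    noise_charge: float = 0.0005   # e per atom

    def __post_init__(self) -> None:
        n = len(self.symbols)
        if n < 4:
            raise ValueError("the toy molecule needs at least 4 atoms")
        if not np.isclose(sum(self.partition_weights), 1.0):
            raise ValueError("partition weights must sum to 1")
        if not np.isclose(sum(self.charge_response), 0.0):
            raise ValueError("charge-response coefficients must sum to 0")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def total_charge(self) -> float:
        return float(sum(self.q0))


def default_toy() -> ToyMoleculeSpec:
    return ToyMoleculeSpec()


# ---------------------------------------------------------------------------
# Internal coordinates of the 4-atom chain 0-1-2-3
# ---------------------------------------------------------------------------

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                     -1.0, 1.0)
    return float(np.arccos(cosang))


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1h = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1h) * b1h
    w = b2 - (b2 @ b1h) * b1h
    return float(np.arctan2(np.cross(b1h, v) @ w, v @ w))


def internal_coordinates(geometry: Geometry
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Chain internals: bond lengths (3,), valence angles (2,), dihedral."""
    p = geometry.coordinates
    r = np.array([np.linalg.norm(p[1] - p[0]),
                  np.linalg.norm(p[2] - p[1]),
                  np.linalg.norm(p[3] - p[2])])
    theta = np.array([_angle(p[0], p[1], p[2]), _angle(p[1], p[2], p[3])])
    phi = _dihedral(p[0], p[1], p[2], p[3])
    return r, theta, phi


def geometry_from_internals(spec: ToyMoleculeSpec, r: np.ndarray,
                            theta: np.ndarray, phi: float,
                            frame_id: int = 0) -> Geometry:
    """Place the chain from its internals (standard Z-matrix construction)."""
    p0 = np.zeros(3)
    p1 = np.array([r[0], 0.0, 0.0])
    p2 = p1 + r[1] * np.array([-np.cos(theta[0]), np.sin(theta[0]), 0.0])
    b1 = p1 - p0
    b2 = p2 - p1
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nh = n / np.linalg.norm(n)
    m = np.cross(nh, b2h)
    p3 = p2 + r[2] * (-np.cos(theta[1]) * b2h
                      + np.sin(theta[1]) * (np.cos(phi) * m
                                            + np.sin(phi) * nh))
    return Geometry(list(spec.symbols), np.vstack([p0, p1, p2, p3]), frame_id)


def equilibrium_geometry(spec: ToyMoleculeSpec) -> Geometry:
    return geometry_from_internals(spec, np.array(spec.r0),
                                   np.array(spec.theta0), spec.phi0)


# ---------------------------------------------------------------------------
# Analytic energy/charge surface and its exact atomic partition
# ---------------------------------------------------------------------------

def _strain_energy(spec: ToyMoleculeSpec, r, theta, phi) -> float:
    e = 0.0
    for rb, rb0, kb in zip(r, spec.r0, spec.k_bond):
        e += 0.5 * kb * (rb - rb0) ** 2
    for th, th0, ka in zip(theta, spec.theta0, spec.k_angle):
        e += 0.5 * ka * (th - th0) ** 2
    e += 0.5 * spec.dihedral_amp * (1.0 - np.cos(phi - spec.phi0))
    return float(e)


def molecular_energy(spec: ToyMoleculeSpec, geometry: Geometry) -> float:
    """Total energy (kJ/mol): per-atom baselines plus the strain terms."""
    r, theta, phi = internal_coordinates(geometry)
    return float(sum(spec.e0) + _strain_energy(spec, r, theta, phi))


def analytic_properties(spec: ToyMoleculeSpec, geometry: Geometry
                        ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Exactly decomposable atomic energies/charges of one frame.

    Returns (E_atoms, Q_atoms, E_mol, Q_mol) with sum(E_atoms) = E_mol and
    sum(Q_atoms) = total charge to machine precision.
    """
    if geometry.n_atoms != spec.n_atoms or \
            geometry.atom_symbols != list(spec.symbols):
        raise ValueError("geometry does not match the toy-molecule topology")
    r, theta, phi = internal_coordinates(geometry)
    strain = _strain_energy(spec, r, theta, phi)
    e_atoms = np.array(spec.e0) + np.array(spec.partition_weights) * strain
    s = spec.c_phi * (np.cos(phi) - np.cos(spec.phi0)) \
        + spec.c_bond * (r[1] - spec.r0[1])
    q_atoms = np.array(spec.q0) + np.array(spec.charge_response) * s
    return e_atoms, q_atoms, float(e_atoms.sum()), float(q_atoms.sum())


# ---------------------------------------------------------------------------
# Conformer sampling
# ---------------------------------------------------------------------------

_MIN_CONTACT = 0.4  # angstrom; resample frames with closer non-bonded contacts


def sample_conformers(spec: ToyMoleculeSpec, n: int, spread: float = 0.05,
                      rng: np.random.Generator | None = None) -> ConformerSet:
    """Sample n frames: Gaussian internals about equilibrium (sd = spread, in
    A for bonds and rad for angles) and a uniform dihedral over (-pi, pi];
    atomic property channels carry independent Gaussian observation noise,
    molecular channels the exact analytic values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    coords = np.empty((n, spec.n_atoms, 3))
    e_at = np.empty((n, spec.n_atoms))
    q_at = np.empty((n, spec.n_atoms))
    e_mol = np.empty(n)
    q_mol = np.empty(n)
    for i in range(n):
        for _ in range(100):
            r = np.array(spec.r0) + spread * rng.standard_normal(3)
            theta = np.array(spec.theta0) + spread * rng.standard_normal(2)
            phi = rng.uniform(-np.pi, np.pi)
            if np.any(r <= 0.3) or np.any(theta <= 0.2) or \
                    np.any(theta >= np.pi - 0.2):
                continue
            g = geometry_from_internals(spec, r, theta, phi, frame_id=i)
            d = g.coordinates[:, None, :] - g.coordinates[None, :, :]
            dist = np.sqrt((d ** 2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            if dist.min() > _MIN_CONTACT:
                break
        else:
            raise RuntimeError(
                f"frame {i}: could not sample a clash-free conformer; "
                f"reduce spread")
        ea, qa, em, qm = analytic_properties(spec, g)
        coords[i] = g.coordinates
        e_at[i] = ea + spec.noise_energy * rng.standard_normal(spec.n_atoms)
        q_at[i] = qa + spec.noise_charge * rng.standard_normal(spec.n_atoms)
        e_mol[i], q_mol[i] = em, qm
    return ConformerSet(
        list(spec.symbols), coords,
        atomic_properties={"E_IQA": e_at, "Q00": q_at},
        molecular_properties={"E_IQA": e_mol, "Q00": q_mol},
    )


# ---------------------------------------------------------------------------
# GP prior draws with known hyperparameters
# ---------------------------------------------------------------------------

@dataclass
class GPDrawSpec:
    """Parameter-recovery fixture: targets drawn from the composite kernel at
    known (theta*, sigma_n*^2)."""

    n: int = 300
    dims: int = 4
    periodic_mask: np.ndarray = field(
        default_factory=lambda: np.array([False, False, False, True]))
    theta_star: np.ndarray = field(
        default_factory=lambda: np.array([2.5, 0.3, 1.8, 0.9]))
    noise_star: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        self.periodic_mask = np.asarray(self.periodic_mask, dtype=bool)
        self.theta_star = np.asarray(self.theta_star, dtype=float)
        if self.periodic_mask.size != self.dims or \
                self.theta_star.size != self.dims:
            raise ValueError("mask/theta_star must match dims")


def gp_draw(spec: GPDrawSpec, n: int | None = None,
            rng: np.random.Generator | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, y): X uniform on the box ([0, 2] per ordinary dimension,
    (-pi, pi] per periodic one), y from the zero-mean GP at theta* plus
    observation noise."""
    n = spec.n if n is None else n
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo = np.where(spec.periodic_mask, -np.pi, 0.0)
    hi = np.where(spec.periodic_mask, np.pi, 2.0)
    X = lo + rng.random((n, spec.dims)) * (hi - lo)
    hyper = Hyperparameters(spec.theta_star, spec.noise_star)
    K = covariance_matrix(X, hyper, KernelSpec(spec.periodic_mask))
    L = np.linalg.cholesky(K)
    y = L @ rng.standard_normal(n)
    return X, y


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------

def make_benchmark(spec: ToyMoleculeSpec, n_train: int, n_val: int,
                   n_test: int, seed: int = 0, spread: float = 0.05,
                   energy_margin: float = 1.0, charge_margin: float = 0.001
                   ) -> tuple[ConformerSet, ConformerSet, ConformerSet, dict]:
    """Disjoint train/validation/test conformer sets, reconstruction-filtered.

    Frames are sampled in batches until, after filtering on the default
    margins, the three requested split sizes are available. Returns the three
    sets plus a manifest (sizes, seed, removal counts).
    """
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split sizes must be positive")
    rng = np.random.default_rng(seed)
    needed = n_train + n_val + n_test
    kept: ConformerSet | None = None
    removed_e = removed_q = n_sampled = 0
    while kept is None or kept.n_frames < needed:
        batch = sample_conformers(spec, max(needed // 2, needed - (
            kept.n_frames if kept else 0)), spread=spread, rng=rng)
        n_sampled += batch.n_frames
        good, rep = filter_dataset(batch, energy_margin, charge_margin)
        removed_e += rep.n_removed_energy
        removed_q += rep.n_removed_charge
        if kept is None:
            kept = good
        else:
            kept = ConformerSet(
                kept.atom_symbols,
                np.concatenate([kept.coordinates, good.coordinates]),
                {k: np.concatenate([kept.atomic_properties[k],
                                    good.atomic_properties[k]])
                 for k in kept.atomic_properties},
                {k: np.concatenate([kept.molecular_properties[k],
                                    good.molecular_properties[k]])
                 for k in kept.molecular_properties},
            )
    train = kept.subset(np.arange(n_train))
    val = kept.subset(np.arange(n_train, n_train + n_val))
    test = kept.subset(np.arange(n_train + n_val, needed))
    manifest = {
        "seed": seed, "spread": spread,
        "n_train": n_train, "n_val": n_val, "n_test": n_test,
        "n_sampled": n_sampled, "n_kept": kept.n_frames,
        "n_removed_energy": removed_e, "n_removed_charge": removed_q,
        "energy_margin": energy_margin, "charge_margin": charge_margin,
    }
    return train, val, test, manifest
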