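"""Conformer I/O and atomic-local-frame (ALF) featurization.

A molecular geometry is encoded, per atom, as a fixed-length vector of
3*N_atoms - 6 internal coordinates built in that atom's local frame: the
distances to the two frame-defining neighbours, the valence angle between
them, and then an (r, theta, phi) spherical triple for every remaining atom.
The azimuthal phi dimensions are cyclic and are flagged by a periodic mask so
that the kernel can treat them with a periodic covariance.

Units are angstrom for distances and radians for angles throughout; features
are deliberately left unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "ConformerSet",
    "ALFDefinition",
    "FeatureVector",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "read_properties",
    "write_properties",
    "compute_alf",
    "featurize",
    "featurize_set",
    "periodic_mask",
    "n_features",
    "export_features",
    "ATOMIC_MASSES",
    "COVALENT_RADII",
]

# Atomic masses (amu) and Cordero covalent radii (angstrom) for the elements
# a desk-scale force-field toy is likely to contain.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.90,
}

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39,
}

_MIN_PAIR_DISTANCE = 1e-6  # angstrom; below this two atoms are "coincident"
_COLLINEAR_TOL = 1e-8  # radians; frame degeneracy threshold


class XYZParseError(ValueError):
    """Raised when a multi-frame XYZ file cannot be parsed."""


@dataclass
class Geometry:
    """One molecular frame: element symbols and Cartesian coordinates (A)."""

    atom_symbols: list[str]
    coordinates: np.ndarray  # (n_atoms, 3)
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atom_symbols)
        if n < 2:
            raise ValueError("a geometry needs at least 2 atoms")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{n} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() <= _MIN_PAIR_DISTANCE:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            raise ValueError(f"atoms {i} and {j} are coincident")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.atom_symbols])


@dataclass
class ConformerSet:
    """An ordered collection of frames sharing one topology.

    ``atomic_properties[name]`` is an (n_frames, n_atoms) array (e.g. E_IQA in
    kJ/mol, Q00 in e); ``molecular_properties[name]`` is an (n_frames,) array.
    """

    atom_symbols: list[str]
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    atomic_properties: dict[str, np.ndarray] = field(default_factory=dict)
    molecular_properties: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != len(self.atom_symbols):
            raise ValueError("atom count mismatch between symbols and coordinates")
        f, a = self.coordinates.shape[:2]
        for name, arr in self.atomic_properties.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (f, a):
                raise ValueError(f"atomic property {name!r} has shape {arr.shape},"
                                 f" expected {(f, a)}")
            self.atomic_properties[name] = arr
        for name, arr in self.molecular_properties.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (f,):
                raise ValueError(f"molecular property {name!r} has shape "
                                 f"{arr.shape}, expected {(f,)}")
            self.molecular_properties[name] = arr

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def geometry(self, i: int) -> Geometry:
        return Geometry(self.atom_symbols, self.coordinates[i], frame_id=i)

    def subset(self, indices) -> "ConformerSet":
        indices = np.asarray(indices)
        return ConformerSet(
            self.atom_symbols,
            self.coordinates[indices],
            {k: v[indices] for k, v in self.atomic_properties.items()},
            {k: v[indices] for k, v in self.molecular_properties.items()},
        )


@dataclass
class ALFDefinition:
    """Per-atom frame definition: (origin, x-axis atom, xy-plane atom)."""

    indices: np.ndarray  # (n_atoms, 3) int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("ALF indices must have shape (n_atoms, 3)")
        for row in self.indices:
            if len(set(row.tolist())) != 3:
                raise ValueError(f"ALF triple {row.tolist()} is not distinct")

    def __eq__(self, other) -> bool:
        return isinstance(other, ALFDefinition) and np.array_equal(
            self.indices, other.indices)


@dataclass
class FeatureVector:
    """ALF features of one atom in one frame, with the cyclic-dimension mask."""

    values: np.ndarray
    periodic_mask: np.ndarray
    center_atom: int


def n_features(n_atoms: int) -> int:
    if n_atoms < 3:
        raise ValueError("featurization requires at least 3 atoms")
    return 3 * n_atoms - 6


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> ConformerSet:
    """Read a multi-frame XYZ file (count line, comment, atom lines)."""
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    symbols: list[str] | None = None
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        frame += 1
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame}: malformed atom-count line {lines[pos]!r}"
            ) from exc
        if pos + 1 + n >= len(lines) + 1:
            raise XYZParseError(f"frame {frame}: truncated (expected {n} atoms)")
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise XYZParseError(f"frame {frame}: truncated (expected {n} atoms)")
        syms, coords = [], []
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise XYZParseError(f"frame {frame}: bad atom line {ln!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise XYZParseError(
                    f"frame {frame}: non-numeric coordinate in {ln!r}"
                ) from exc
            syms.append(parts[0])
            coords.append(xyz)
        if symbols is None:
            symbols = syms
        elif syms != symbols:
            raise XYZParseError(
                f"frame {frame}: atom count or symbol order differs from frame 1"
            )
        frames.append(np.array(coords))
        pos += 2 + n
    if symbols is None:
        return ConformerSet([], np.zeros((0, 0, 3)))
    return ConformerSet(symbols, np.stack(frames))


def write_xyz(conformers: ConformerSet, path) -> None:
    """Write a ConformerSet as multi-frame XYZ with 10-decimal coordinates."""
    with open(path, "w") as fh:
        for i in range(conformers.n_frames):
            fh.write(f"{conformers.n_atoms}\n")
            fh.write(f"frame {i}\n")
            for sym, (x, y, z) in zip(conformers.atom_symbols,
                                      conformers.coordinates[i]):
                fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def write_properties(conformers: ConformerSet, path) -> None:
    """Write property channels as tidy CSV (frame, atom, property, value).

    Molecular channels use atom = -1.
    """
    rows = []
    for name, arr in conformers.atomic_properties.items():
        for f in range(conformers.n_frames):
            for a in range(conformers.n_atoms):
                rows.append((f, a, name, arr[f, a]))
    for name, arr in conformers.molecular_properties.items():
        for f in range(conformers.n_frames):
            rows.append((f, -1, name, arr[f]))
    pd.DataFrame(rows, columns=["frame", "atom", "property", "value"]).to_csv(
        path, index=False)


def read_properties(conformers: ConformerSet, path) -> ConformerSet:
    """Attach property channels from a tidy CSV written by write_properties."""
    df = pd.read_csv(path)
    expected = {"frame", "atom", "property", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"property table must have columns {sorted(expected)}")
    f, a = conformers.n_frames, conformers.n_atoms
    for name, grp in df.groupby("property"):
        atomic = grp[grp["atom"] >= 0]
        if len(atomic):
            arr = np.full((f, a), np.nan)
            arr[atomic["frame"].to_numpy(), atomic["atom"].to_numpy()] = \
                atomic["value"].to_numpy()
            conformers.atomic_properties[str(name)] = arr
        mol = grp[grp["atom"] < 0]
        if len(mol):
            arr = np.full(f, np.nan)
            arr[mol["frame"].to_numpy()] = mol["value"].to_numpy()
            conformers.molecular_properties[str(name)] = arr
    return conformers


# ---------------------------------------------------------------------------
# ALF construction and featurization
# ---------------------------------------------------------------------------

def _connectivity(geometry: Geometry, bond_scale: float) -> list[list[int]]:
    coords = geometry.coordinates
    radii = np.array([COVALENT_RADII[s] for s in geometry.atom_symbols])
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cutoff = bond_scale * (radii[:, None] + radii[None, :])
    np.fill_diagonal(d, np.inf)
    bonded = d < cutoff
    return [list(np.nonzero(bonded[i])[0]) for i in range(geometry.n_atoms)]


def _priority_sorted(neighbours: list[int], masses: np.ndarray) -> list[int]:
    # highest atomic mass first, ties broken by lowest atom index
    return sorted(neighbours, key=lambda j: (-masses[j], j))


def compute_alf(geometry: Geometry, bond_scale: float = 1.2) -> ALFDefinition:
    """Build each atom's local frame from mass-priority bonded neighbours.

    The x-axis atom is the bonded neighbour of highest atomic mass (ties go to
    the lowest index); the xy-plane atom is the next neighbour in the same
    priority order, falling back to the x-axis atom's neighbours when the
    centre is terminal.
    """
    if geometry.n_atoms < 3:
        raise ValueError("ALF construction requires at least 3 atoms")
    neigh = _connectivity(geometry, bond_scale)
    masses = geometry.masses
    triples = np.empty((geometry.n_atoms, 3), dtype=int)
    for a in range(geometry.n_atoms):
        order = _priority_sorted(neigh[a], masses)
        if not order:
            raise ValueError(f"atom {a} ({geometry.atom_symbols[a]}) has no "
                             f"bonded neighbour within the cutoff")
        x_axis = order[0]
        if len(order) > 1:
            xy_plane = order[1]
        else:
            fallback = _priority_sorted(
                [j for j in neigh[x_axis] if j != a], masses)
            if not fallback:
                raise ValueError(
                    f"atom {a}: cannot define an xy-plane atom (x-axis atom "
                    f"{x_axis} has no other neighbour)")
            xy_plane = fallback[0]
        triples[a] = (a, x_axis, xy_plane)
    return ALFDefinition(triples)


def periodic_mask(n_atoms: int, strict_mod3: bool = False) -> np.ndarray:
    """Boolean mask flagging the azimuthal (cyclic) feature dimensions.

    With 1-based dimension index d, a dimension is periodic iff d % 3 == 0 and
    d >= 6. The valence angle at d = 3 is bounded in [0, pi] and is treated as
    non-periodic by default; ``strict_mod3`` restores the literal
    every-third-dimension rule.
    """
    if n_atoms < 3:
        raise ValueError("need at least 3 atoms")
    d = np.arange(1, n_features(n_atoms) + 1)
    mask = (d % 3 == 0)
    if not strict_mod3:
        mask &= d >= 6
    return mask


def _local_frame(coords: np.ndarray, center: int, x_atom: int, xy_atom: int):
    a = coords[center]
    u = coords[x_atom] - a
    v = coords[xy_atom] - a
    ru = np.linalg.norm(u)
    rv = np.linalg.norm(v)
    xhat = u / ru
    w = v - (v @ xhat) * xhat
    nw = np.linalg.norm(w)
    # collinearity check: angle between u and v within tolerance of 0 or pi
    if nw / rv < _COLLINEAR_TOL:
        raise ValueError(
            f"degenerate local frame for atom {center}: frame atoms are "
            f"collinear")
    yhat = w / nw
    zhat = np.cross(xhat, yhat)
    return a, xhat, yhat, zhat, ru, rv


def featurize(geometry: Geometry, alf: ALFDefinition,
              center_atom: int) -> FeatureVector:
    """ALF feature vector of one atom: two frame distances, the valence
    angle, then (r, theta, phi) for every remaining atom in index order."""
    coords = geometry.coordinates
    n = geometry.n_atoms
    center, x_atom, xy_atom = alf.indices[center_atom]
    if center != center_atom:
        raise ValueError("ALF row does not match the requested centre atom")
    a, xhat, yhat, zhat, ru, rv = _local_frame(coords, center, x_atom, xy_atom)
    cosang = np.clip((coords[x_atom] - a) @ (coords[xy_atom] - a) / (ru * rv),
                     -1.0, 1.0)
    feats = [ru, rv, float(np.arccos(cosang))]
    for i in range(n):
        if i in (center, x_atom, xy_atom):
            continue
        d = coords[i] - a
        r = np.linalg.norm(d)
        dx, dy, dz = d @ xhat, d @ yhat, d @ zhat
        theta = float(np.arccos(np.clip(dz / r, -1.0, 1.0)))
        phi = float(np.arctan2(dy, dx))
        if phi <= -np.pi:  # fold the closed end of atan2's range onto +pi
            phi = np.pi
        feats.extend([r, theta, phi])
    values = np.array(feats)
    return FeatureVector(values, periodic_mask(n), center_atom)


def featurize_set(conformers: ConformerSet, alf: ALFDefinition,
                  center_atom: int) -> np.ndarray:
    """Feature matrix (n_frames, 3*N-6) of one atom over a conformer set."""
    rows = [featurize(conformers.geometry(i), alf, center_atom).values
            for i in range(conformers.n_frames)]
    return np.vstack(rows)


def export_features(X: np.ndarray, mask: np.ndarray, path) -> None:
    """Write a feature matrix as CSV (or HDF5 when the suffix is .h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("features", data=X)
            fh.create_dataset("periodic_mask", data=mask)
    else:
        cols = [f"f{i + 1}{'p' if m else ''}" for i, m in enumerate(mask)]
        pd.DataFrame(X, columns=cols).to_csv(path, index=False)
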