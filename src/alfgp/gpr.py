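"""Anisotropic composite-kernel Gaussian-process regression.

The kernel is a product over feature dimensions of a squared-exponential
factor exp(-theta_d * delta_d^2) on ordinary dimensions and a periodic factor
exp(-theta_d * sin^2(delta_d / 2)) on cyclic (azimuthal-angle) dimensions,
optionally scaled by a signal variance sigma_f^2 (fixed to 1 by default).
Training solves K omega = y - m by Cholesky factorization, with the constant
prior mean m set to the arithmetic mean of the training targets so that
predictions fall back to a physically sensible value far from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "Hyperparameters",
    "KernelSpec",
    "GPRModel",
    "CholeskyError",
    "ModelFormatError",
    "kernel_value",
    "kernel_matrix",
    "covariance_matrix",
    "fit_weights",
    "fit_gpr",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_THETA_BOUNDS = (0.0, 3.0)
DEFAULT_NOISE_BOUNDS = (1e-14, 1e-4)

_MODEL_MAGIC = "alfgp-gpr-model"
_MODEL_VERSION = 1


class CholeskyError(RuntimeError):
    """Covariance factorization failed; raise sigma_n^2 rather than jittering."""


class ModelFormatError(ValueError):
    """Model file is corrupted or of an unsupported version."""


@dataclass
class Hyperparameters:
    """Per-dimension kernel parameters theta >= 0, regularisation noise
    sigma_n^2 > 0 and an optional signal variance prefactor (default 1)."""

    theta: np.ndarray
    noise: float
    prefactor: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise ValueError("theta must be a 1-D array")
        if np.any(self.theta < 0):
            raise ValueError("theta components must be non-negative")
        if not self.noise > 0:
            raise ValueError("noise sigma_n^2 must be positive")
        if not self.prefactor > 0:
            raise ValueError("prefactor sigma_f^2 must be positive")


@dataclass
class KernelSpec:
    """Which feature dimensions use the periodic covariance factor."""

    periodic_mask: np.ndarray

    def __post_init__(self) -> None:
        self.periodic_mask = np.asarray(self.periodic_mask, dtype=bool)

    @property
    def n_feats(self) -> int:
        return self.periodic_mask.size


def _dim_terms(delta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-dimension squared-distance terms g_d such that
    phi_d = exp(-theta_d * g_d)."""
    g = delta ** 2
    if mask.any():
        g[..., mask] = np.sin(delta[..., mask] / 2.0) ** 2
    return g


def kernel_value(x_i: np.ndarray, x_j: np.ndarray, hyper: Hyperparameters,
                 spec: KernelSpec) -> float:
    """Composite-kernel similarity of two feature vectors."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape or x_i.size != spec.n_feats:
        raise ValueError("feature length mismatch")
    g = _dim_terms(x_i - x_j, spec.periodic_mask)
    return float(hyper.prefactor * np.exp(-(g @ hyper.theta)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, hyper: Hyperparameters,
                  spec: KernelSpec) -> np.ndarray:
    """Cross-kernel matrix k(X_i, Y_j), without any noise term."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != spec.n_feats or Y.shape[1] != spec.n_feats:
        raise ValueError("feature width mismatch")
    g = _dim_terms(X[:, None, :] - Y[None, :, :], spec.periodic_mask)
    return hyper.prefactor * np.exp(-(g @ hyper.theta))


def covariance_matrix(X: np.ndarray, hyper: Hyperparameters,
                      spec: KernelSpec) -> np.ndarray:
    """Training covariance K_ij = k(x_i, x_j) + delta_ij sigma_n^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    K = kernel_matrix(X, X, hyper, spec)
    K[np.diag_indices_from(K)] += hyper.noise
    return K


def fit_weights(K: np.ndarray, y: np.ndarray, m: float) -> np.ndarray:
    """Solve K omega = y - m by Cholesky (direct solver, no silent jitter)."""
    y = np.asarray(y, dtype=float)
    if K.shape[0] != y.size:
        raise ValueError("K and y size mismatch")
    try:
        c = cho_factor(K, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise CholeskyError(
            "Cholesky factorization of the covariance failed; increase the "
            "regularisation noise sigma_n^2") from exc
    return cho_solve(c, y - m, check_finite=False)


@dataclass
class GPRModel:
    """A trained atomic GPR model: X, constant mean, weights, hyperparameters."""

    training_features: np.ndarray
    mean: float
    weights: np.ndarray
    hyperparameters: Hyperparameters
    kernel_spec: KernelSpec
    target_name: str = ""
    center_atom: int = -1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights.size != self.training_features.shape[0]:
            raise ValueError("one weight per training row is required")


def fit_gpr(X: np.ndarray, y: np.ndarray, hyper: Hyperparameters,
            spec: KernelSpec, target_name: str = "",
            center_atom: int = -1) -> GPRModel:
    """Fit a GPR model: m = mean(y), omega = K^-1 (y - m)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m = float(y.mean())
    K = covariance_matrix(X, hyper, spec)
    w = fit_weights(K, y, m)
    return GPRModel(X, m, w, hyper, spec, target_name, center_atom)


def predict(model: GPRModel, X_star: np.ndarray) -> np.ndarray:
    """Posterior-mean prediction m + sum_i omega_i k(x_i, x*)."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if X_star.shape[1] != model.training_features.shape[1]:
        raise ValueError("feature width mismatch with the training matrix")
    Ks = kernel_matrix(X_star, model.training_features,
                       model.hyperparameters, model.kernel_spec)
    return model.mean + Ks @ model.weights


# ---------------------------------------------------------------------------
# Serialization: versioned plain-text header + whitespace float payload
# ---------------------------------------------------------------------------

def save_model(model: GPRModel, path) -> None:
    header = {
        "version": _MODEL_VERSION,
        "target": model.target_name,
        "center_atom": model.center_atom,
        "n_train": int(model.training_features.shape[0]),
        "n_feats": int(model.training_features.shape[1]),
        "periodic_mask": model.kernel_spec.periodic_mask.astype(int).tolist(),
        "theta": model.hyperparameters.theta.tolist(),
        "noise": model.hyperparameters.noise,
        "prefactor": model.hyperparameters.prefactor,
        "mean": model.mean,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        fh.write(f"{_MODEL_MAGIC} {_MODEL_VERSION}\n")
        fh.write(json.dumps(header) + "\n")
        fh.write("[weights]\n")
        np.savetxt(fh, model.weights.reshape(1, -1), fmt="%.17e")
        fh.write("[features]\n")
        np.savetxt(fh, model.training_features, fmt="%.17e")


def load_model(path) -> GPRModel:
    path = Path(path)
    if str(path) == "":
        raise OSError("empty model path")
    text = path.read_text().splitlines()
    if not text or not text[0].startswith(_MODEL_MAGIC):
        raise ModelFormatError(f"{path}: not an alfgp model file")
    try:
        version = int(text[0].split()[1])
    except (IndexError, ValueError) as exc:
        raise ModelFormatError(f"{path}: corrupted header line") from exc
    if version != _MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model version {version}")
    try:
        header = json.loads(text[1])
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: corrupted JSON header") from exc
    try:
        iw = text.index("[weights]")
        ix = text.index("[features]")
        weights = np.fromstring(" ".join(text[iw + 1:ix]), sep=" ")
        X = np.loadtxt(text[ix + 1:], ndmin=2)
    except Exception as exc:
        raise ModelFormatError(f"{path}: corrupted payload") from exc
    if X.shape != (header["n_train"], header["n_feats"]) or \
            weights.size != header["n_train"]:
        raise ModelFormatError(f"{path}: truncated payload")
    hyper = Hyperparameters(np.array(header["theta"]), header["noise"],
                            header.get("prefactor", 1.0))
    spec = KernelSpec(np.array(header["periodic_mask"], dtype=bool))
    return GPRModel(X, header["mean"], weights, hyper, spec,
                    header.get("target", ""), header.get("center_atom", -1),
                    header.get("metadata", {}))


def export_theta_csv(model: GPRModel, path) -> None:
    """Write theta (and noise) as a small inspection CSV."""
    import pandas as pd

    rows = [("theta", d + 1, v) for d, v in
            enumerate(model.hyperparameters.theta)]
    rows.append(("noise", 0, model.hyperparameters.noise))
    pd.DataFrame(rows, columns=["parameter", "dimension", "value"]).to_csv(
        path, index=False)
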