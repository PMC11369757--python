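"""Hyperparameter search by a grey wolf optimizer with leadership promotions.

The optimizer (GWO-RUHL(n, p)) moves a pack of W candidate solutions through
the hyperparameter space. After ranking by loss, the three best candidates
(alpha, beta, delta — the leaders) stay put and every other (omega) wolf is
pulled toward a stochastic mean of the leader positions; every p iterations,
n randomly chosen omega wolves are additionally promoted into the vicinity of
the leader centroid. Components that leave the box bounds are redrawn
uniformly inside them.

The loss is the iterative hold-out cross-validation (IHOCV) objective: the
RMSE of an intermediate GPR model — fitted on the training set with the
candidate's hyperparameters — over a fixed internal validation set. The
kernel parameters theta are searched in linear space, the regularisation
noise in log10 space (its bounds span ten decades).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .gpr import (DEFAULT_NOISE_BOUNDS, DEFAULT_THETA_BOUNDS, CholeskyError,
                  GPRModel, Hyperparameters, KernelSpec, fit_gpr, predict)

__all__ = [
    "GWOConfig",
    "Population",
    "SearchTrace",
    "IhocvObjective",
    "ihocv_loss",
    "a_schedule",
    "init_population",
    "gwo_step",
    "ruhl_promotion",
    "minimize_objective",
    "optimize",
    "sample_uniform",
]


@dataclass
class GWOConfig:
    """Search settings (defaults follow the reference training engine)."""

    W: int = 50
    pool: int = 500
    tau: int = 200
    a_max: float = 2.0
    n_lucky: int = 5
    p_period: int = 5
    r_lucky: float = 0.20
    theta_bounds: tuple[float, float] = DEFAULT_THETA_BOUNDS
    noise_bounds: tuple[float, float] = DEFAULT_NOISE_BOUNDS
    seed: int = 0
    vanilla_C: bool = False          # classic C = 2 r2 instead of 2 a(t) r2
    promotion_additive: bool = False  # L + eps instead of L (1 + eps)
    search_prefactor: bool = False
    prefactor_bounds: tuple[float, float] = (1e-3, 1e3)

    def __post_init__(self) -> None:
        if self.W <= 3:
            raise ValueError("the pack needs more than 3 wolves")
        if self.pool < self.W:
            raise ValueError("initial pool must be at least W")
        if not 0 <= self.n_lucky < self.W - 3:
            raise ValueError("n_lucky must be smaller than the number of "
                             "omega wolves (W - 3)")


@dataclass
class Population:
    """Ranked pack: row 0..2 are the alpha/beta/delta leaders."""

    positions: np.ndarray  # (W, dim)
    losses: np.ndarray     # (W,)
    ids: np.ndarray        # (W,) stable tie-break
    iteration: int = 0

    def rank(self) -> None:
        order = np.lexsort((self.ids, self.losses))
        self.positions = self.positions[order]
        self.losses = self.losses[order]
        self.ids = self.ids[order]

    @property
    def best_loss(self) -> float:
        return float(self.losses[0])

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[0].copy()


@dataclass
class SearchTrace:
    """Optional instrumentation of a search run."""

    snapshots: list = field(default_factory=list)   # (t, positions copy)
    promotions: list = field(default_factory=list)  # (t, moved ids, positions)

    def snapshot(self, t: int, pop: Population) -> None:
        self.snapshots.append((t, pop.positions.copy()))

    def promotion(self, t: int, ids: np.ndarray, positions: np.ndarray) -> None:
        self.promotions.append((t, np.array(ids), positions.copy()))


# ---------------------------------------------------------------------------
# Search-space encoding: [theta (linear)..., log10 noise, (log10 prefactor)]
# ---------------------------------------------------------------------------

def search_bounds(n_feats: int, config: GWOConfig) -> np.ndarray:
    lo, hi = config.theta_bounds
    rows = [(lo, hi)] * n_feats
    rows.append((math.log10(config.noise_bounds[0]),
                 math.log10(config.noise_bounds[1])))
    if config.search_prefactor:
        rows.append((math.log10(config.prefactor_bounds[0]),
                     math.log10(config.prefactor_bounds[1])))
    return np.array(rows, dtype=float)


def decode_position(z: np.ndarray, n_feats: int,
                    search_prefactor: bool = False) -> Hyperparameters:
    theta = np.array(z[:n_feats], dtype=float)
    noise = float(10.0 ** z[n_feats])
    pref = float(10.0 ** z[n_feats + 1]) if search_prefactor else 1.0
    return Hyperparameters(theta, noise, pref)


def sample_uniform(n: int, bounds: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    return lo + rng.random((n, bounds.shape[0])) * (hi - lo)


# ---------------------------------------------------------------------------
# IHOCV objective
# ---------------------------------------------------------------------------

def ihocv_loss(hyper: Hyperparameters, spec: KernelSpec,
               X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray) -> float:
    """Validation RMSE of the intermediate GPR model (reference path).

    A failed Cholesky factorization returns +inf so that the candidate is
    simply outranked instead of aborting the search.
    """
    y_val = np.asarray(y_val, dtype=float)
    if y_val.size < 1 or np.asarray(y_train).size < 1:
        raise ValueError("train and validation sets must be non-empty")
    try:
        model = fit_gpr(X_train, y_train, hyper, spec)
    except CholeskyError:
        return float("inf")
    resid = predict(model, X_val) - y_val
    return float(np.sqrt(np.mean(resid ** 2)))


class IhocvObjective:
    """Cached IHOCV loss over search-space positions.

    The per-dimension squared differences of the training and cross
    (validation x training) feature pairs do not depend on the candidate, so
    they are precomputed once; each evaluation is then one matrix-vector
    product, an exponential, and a Cholesky solve. ``n_evals`` counts
    covariance factorizations (attempted ones included) of size ``n_train``.
    """

    def __init__(self, X_train: np.ndarray, y_train: np.ndarray,
                 X_val: np.ndarray, y_val: np.ndarray, spec: KernelSpec,
                 search_prefactor: bool = False) -> None:
        X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        self.n_train = X_train.shape[0]
        self.n_val = X_val.shape[0]
        self.n_feats = X_train.shape[1]
        self.spec = spec
        self.search_prefactor = search_prefactor
        self.y_train = np.asarray(y_train, dtype=float)
        self.y_val = np.asarray(y_val, dtype=float)
        self._m = float(self.y_train.mean())
        self._ym = self.y_train - self._m
        mask = spec.periodic_mask
        iu = np.triu_indices(self.n_train, k=1)
        dtr = X_train[iu[0]] - X_train[iu[1]]
        dcr = (X_val[:, None, :] - X_train[None, :, :]).reshape(-1, self.n_feats)
        for d in (dtr, dcr):
            d[:, ~mask] **= 2
            d[:, mask] = np.sin(d[:, mask] / 2.0) ** 2
        self._gtr = np.ascontiguousarray(dtr)
        self._gcr = np.ascontiguousarray(dcr)
        self._iu = iu
        self._K = np.empty((self.n_train, self.n_train))
        self.n_evals = 0
        self.n_failures = 0

    @property
    def dim(self) -> int:
        return self.n_feats + 1 + int(self.search_prefactor)

    def decode(self, z: np.ndarray) -> Hyperparameters:
        return decode_position(z, self.n_feats, self.search_prefactor)

    def __call__(self, z: np.ndarray) -> float:
        hyper = self.decode(z)
        self.n_evals += 1
        K = self._K
        off = hyper.prefactor * np.exp(-(self._gtr @ hyper.theta))
        K[self._iu] = off
        K.T[self._iu] = off
        np.fill_diagonal(K, hyper.prefactor + hyper.noise)
        try:
            c = cho_factor(K, lower=True, check_finite=False)
        except LinAlgError:
            self.n_failures += 1
            return float("inf")
        w = cho_solve(c, self._ym, check_finite=False)
        ks = hyper.prefactor * np.exp(-(self._gcr @ hyper.theta))
        pred = self._m + ks.reshape(self.n_val, self.n_train) @ w
        return float(np.sqrt(np.mean((pred - self.y_val) ** 2)))


# ---------------------------------------------------------------------------
# GWO-RUHL
# ---------------------------------------------------------------------------

def a_schedule(t: int, tau: int, a_max: float) -> float:
    """Linear decay of the exploration parameter from a_max (t=0) to 0 (t=tau)."""
    if not 0 <= t <= tau:
        raise ValueError("iteration outside [0, tau]")
    return a_max * (1.0 - t / tau)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    return np.array([objective(z) for z in positions])


def _reinit_oob(pos: np.ndarray, bounds: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Redraw out-of-bounds components uniformly inside the box."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    oob = (pos < lo) | (pos > hi)
    if oob.any():
        idx = np.nonzero(oob)[0]
        pos[idx] = lo[idx] + rng.random(idx.size) * (hi[idx] - lo[idx])
    return pos


def init_population(config: GWOConfig, objective, rng: np.random.Generator,
                    bounds: np.ndarray) -> Population:
    """Throw ``pool`` random candidates on the space and keep the W best."""
    positions = sample_uniform(config.pool, bounds, rng)
    losses = _evaluate(objective, positions)
    if not np.isfinite(losses).any():
        raise RuntimeError(
            "all initial candidates failed evaluation (infinite loss); check "
            "the data and the noise bounds")
    pop = Population(positions, losses, np.arange(config.pool))
    pop.rank()
    pop.positions = pop.positions[:config.W]
    pop.losses = pop.losses[:config.W]
    pop.ids = pop.ids[:config.W]
    return pop


def gwo_step(pop: Population, t: int, config: GWOConfig, objective,
             rng: np.random.Generator, bounds: np.ndarray,
             a: float) -> Population:
    """One pack update: every omega wolf moves, leaders stay, re-rank."""
    W, dim = pop.positions.shape
    leaders = pop.positions[:3].copy()
    for j in range(3, W):
        r1 = rng.random((3, dim))
        r2 = rng.random((3, dim))
        A = 2.0 * a * r1 - a
        C = 2.0 * r2 if config.vanilla_C else 2.0 * a * r2
        D = np.abs(C * leaders - pop.positions[j])
        proposal = np.mean(leaders - A * D, axis=0)
        pop.positions[j] = _reinit_oob(proposal, bounds, rng)
    pop.losses[3:] = _evaluate(objective, pop.positions[3:])
    pop.rank()
    pop.iteration = t
    return pop


def ruhl_promotion(pop: Population, config: GWOConfig, objective,
                   rng: np.random.Generator, bounds: np.ndarray,
                   trace: SearchTrace | None = None,
                   t: int = 0) -> Population:
    """Promote n random omega wolves near the leader centroid L."""
    W, dim = pop.positions.shape
    if config.n_lucky == 0:
        return pop
    lucky = rng.choice(np.arange(3, W), size=config.n_lucky, replace=False)
    L = pop.positions[:3].mean(axis=0)
    for j in lucky:
        eps = rng.uniform(-config.r_lucky, config.r_lucky, dim)
        new = L + eps if config.promotion_additive else L * (1.0 + eps)
        pop.positions[j] = _reinit_oob(new, bounds, rng)
        pop.losses[j] = objective(pop.positions[j])
    if trace is not None:
        trace.promotion(t, pop.ids[lucky], pop.positions[lucky])
    pop.rank()
    return pop


@dataclass
class SearchResult:
    best_position: np.ndarray
    best_loss: float
    history: np.ndarray  # best loss per iteration, length tau + 1
    population: Population
    trace: SearchTrace | None = None
    history_mean: np.ndarray | None = None  # pack-mean finite loss
    a_values: np.ndarray | None = None      # a(t) used per iteration


def minimize_objective(objective, bounds: np.ndarray, config: GWOConfig,
                       rng: np.random.Generator | None = None,
                       init_positions: np.ndarray | None = None,
                       tau: int | None = None,
                       a_max: float | None = None,
                       trace: SearchTrace | None = None) -> SearchResult:
    """Run the GWO-RUHL loop on an arbitrary objective over box bounds.

    ``init_positions`` (W x dim) bypasses the random pool — used by the
    transfer-learning relaxation phase, which starts from a perturbed guess.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tau = config.tau if tau is None else tau
    a_max = config.a_max if a_max is None else a_max
    if init_positions is None:
        pop = init_population(config, objective, rng, bounds)
    else:
        if init_positions.shape[0] != config.W:
            raise ValueError("init_positions must supply exactly W candidates")
        pop = Population(init_positions.copy(),
                         _evaluate(objective, init_positions),
                         np.arange(config.W))
        pop.rank()
    def _mean_loss() -> float:
        finite = pop.losses[np.isfinite(pop.losses)]
        return float(finite.mean()) if finite.size else float("inf")

    history = [pop.best_loss]
    history_mean = [_mean_loss()]
    a_values = [a_schedule(0, tau, a_max)] if tau > 0 else [0.0]
    if trace is not None:
        trace.snapshot(0, pop)
    for t in range(1, tau + 1):
        a = a_schedule(t, tau, a_max)
        gwo_step(pop, t, config, objective, rng, bounds, a)
        if config.p_period > 0 and t % config.p_period == 0:
            ruhl_promotion(pop, config, objective, rng, bounds, trace, t)
        history.append(pop.best_loss)
        history_mean.append(_mean_loss())
        a_values.append(a)
        if trace is not None:
            trace.snapshot(t, pop)
    return SearchResult(pop.best_position, pop.best_loss,
                        np.array(history), pop, trace,
                        history_mean=np.array(history_mean),
                        a_values=np.array(a_values))


@dataclass
class OptimizeResult:
    hyperparameters: Hyperparameters
    history: np.ndarray
    search: SearchResult
    objective: IhocvObjective


def optimize(train: tuple[np.ndarray, np.ndarray],
             val: tuple[np.ndarray, np.ndarray],
             kernel_spec: KernelSpec, config: GWOConfig,
             objective: IhocvObjective | None = None,
             rng: np.random.Generator | None = None,
             trace: SearchTrace | None = None) -> OptimizeResult:
    """Direct-learning hyperparameter optimization on (train, val) data."""
    if objective is None:
        objective = IhocvObjective(train[0], train[1], val[0], val[1],
                                   kernel_spec,
                                   search_prefactor=config.search_prefactor)
    bounds = search_bounds(objective.n_feats, config)
    result = minimize_objective(objective, bounds, config, rng=rng,
                                trace=trace)
    return OptimizeResult(objective.decode(result.best_position),
                          result.history, result, objective)


def fit_best(train: tuple[np.ndarray, np.ndarray], kernel_spec: KernelSpec,
             hyper: Hyperparameters, target_name: str = "",
             center_atom: int = -1) -> GPRModel:
    """Convenience: fit the final model at the optimized hyperparameters."""
    return fit_gpr(train[0], train[1], hyper, kernel_spec,
                   target_name=target_name, center_atom=center_atom)
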