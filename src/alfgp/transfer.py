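"""Two-phase (seeding-relaxation) transfer learning of GPR hyperparameters.

A source model is trained on a random subsample S of the target training set
T (|S| = eta |T|, with eta the knowledge compression coefficient). Its
optimized hyperparameters theta0 seed the target search: theta0 is copied
into the pack, the remaining W - 1 wolves are placed by small multiplicative
random walks around it (extent r_max), and the pack relaxes on the full
target set for zeta * tau iterations (zeta the relaxation weight). With
zeta = 0 the guess is used frozen (FS-TL); with eta = 1 and zeta = 0 the
protocol reduces exactly to direct learning.

The module also carries the analytic cost model: with per-iteration cost
dominated by the O(N^3) covariance factorization, the relative per-iteration
complexity is gamma = eta^3 and the relative total complexity is
Delta = (1 - zeta) N_s gamma + zeta (or N_s gamma + zeta under full seeding);
the expected speedup is 1 / Delta.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .gpr import GPRModel, Hyperparameters, KernelSpec, fit_gpr
from .hyperopt import (GWOConfig, IhocvObjective, SearchTrace,
                       minimize_objective, optimize, search_bounds)

__all__ = [
    "TLConfig",
    "TimingModel",
    "TLReport",
    "subsample_source",
    "perturb_guess",
    "transfer_learn",
    "relative_complexity",
    "speedup_condition",
]

MIN_SOURCE_SIZE = 10


@dataclass
class TLConfig:
    """Transfer-learning control parameters."""

    eta: float = 0.25
    zeta: float = 0.10
    r_max: float = 0.25
    full_seeding: bool = False
    n_sources: int = 1
    a_max_guess: float = 2.0
    a_max_relax: float = 1.0
    subsample_method: str = "random"

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if not 0 <= self.zeta <= 1:
            raise ValueError("zeta must be in [0, 1]")
        if self.r_max < 0:
            raise ValueError("r_max must be non-negative")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.subsample_method not in ("random", "stratified", "passive"):
            raise ValueError(f"unknown subsample method "
                             f"{self.subsample_method!r}")


@dataclass
class TimingModel:
    """Analytic relative training cost of a TL task versus direct learning."""

    gamma: float
    delta: float
    iterations_guess: int | None = None
    iterations_relax: int | None = None

    @property
    def speedup(self) -> float:
        return 1.0 / self.delta


def relative_complexity(eta: float, zeta: float, n_sources: int = 1,
                        full_seeding: bool = False) -> TimingModel:
    """gamma = eta^3 and Delta under the selected protocol variant."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1]")
    if not 0 <= zeta <= 1:
        raise ValueError("zeta must be in [0, 1]")
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    gamma = eta ** 3
    if full_seeding:
        delta = n_sources * gamma + zeta
    else:
        delta = (1.0 - zeta) * n_sources * gamma + zeta
    return TimingModel(gamma=gamma, delta=delta)


def speedup_condition(gamma: float, zeta: float, n_sources: int = 1,
                      full_seeding: bool = False) -> bool:
    """True iff the analytic model predicts acceleration (Delta < 1)."""
    if full_seeding:
        return gamma < (1.0 - zeta) / n_sources
    return (1.0 - zeta) * n_sources * gamma + zeta < 1.0


def split_iterations(tau: int, zeta: float, full_seeding: bool
                     ) -> tuple[int, int]:
    """(guess, relax) iteration counts; relax = round(zeta tau), min 1 when
    zeta > 0, and the guess phase receives the remainder (or the full tau
    under full seeding)."""
    n_relax = int(round(zeta * tau))
    if zeta > 0:
        n_relax = max(1, n_relax)
    n_guess = tau if full_seeding else tau - n_relax
    return n_guess, n_relax


def subsample_source(T, eta: float, method: str = "random",
                     rng: np.random.Generator | None = None):
    """Random subsample S of the target conformer set T, |S| = round(eta |T|).

    With eta = 1 the source IS the target (same frames, same order) and no
    randomness is consumed, so the protocol reduces bit-identically to direct
    learning. Stratified/passive sampling are recognised but not implemented.
    """
    if not 0 < eta <= 1:
        raise ValueError("eta must be in (0, 1]")
    if method != "random":
        raise NotImplementedError(
            f"{method} subsampling is a hook; only 'random' is implemented")
    n = T.n_frames if hasattr(T, "n_frames") else len(T)
    if eta == 1.0:
        return T
    size = int(round(eta * n))
    if size < MIN_SOURCE_SIZE:
        raise ValueError(
            f"source set of {size} frames is below the minimum trainable "
            f"size ({MIN_SOURCE_SIZE}); increase eta")
    rng = np.random.default_rng() if rng is None else rng
    idx = np.sort(rng.choice(n, size=size, replace=False))
    return T.subset(idx) if hasattr(T, "subset") else T[idx]


def perturb_guess(theta0: np.ndarray, W: int, r_max: float,
                  rng: np.random.Generator,
                  bounds: np.ndarray | None = None) -> np.ndarray:
    """Build the W-member relaxation pack around the guess solution.

    Row 0 is theta0 itself; rows 1..W-1 are component-wise
    theta0_d (1 + r_max eps), eps ~ U[-1, 1] fresh per component, clamped
    into bounds.
    """
    if W <= 3:
        raise ValueError("the pack needs more than 3 wolves")
    theta0 = np.asarray(theta0, dtype=float)
    eps = rng.uniform(-1.0, 1.0, size=(W - 1, theta0.size))
    pack = np.vstack([theta0, theta0 * (1.0 + r_max * eps)])
    if bounds is not None:
        pack = np.clip(pack, bounds[:, 0], bounds[:, 1])
    return pack


@dataclass
class PhaseReport:
    name: str
    train_size: int
    iterations: int
    factorizations: int
    best_loss: float
    cpu_time: float
    wall_time: float
    history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class TLReport:
    """Per-phase accounting of a transfer-learning run."""

    eta: float
    zeta: float
    full_seeding: bool
    source_size: int
    target_size: int
    phases: list[PhaseReport] = field(default_factory=list)
    guess_hyperparameters: Hyperparameters | None = None

    @property
    def full_size_factorizations(self) -> int:
        """Covariance factorizations at the full target size |T|."""
        return sum(p.factorizations for p in self.phases
                   if p.train_size == self.target_size)

    def to_dict(self) -> dict:
        return {
            "eta": self.eta, "zeta": self.zeta,
            "full_seeding": self.full_seeding,
            "source_size": self.source_size,
            "target_size": self.target_size,
            "full_size_factorizations": self.full_size_factorizations,
            "phases": [
                {"name": p.name, "train_size": p.train_size,
                 "iterations": p.iterations,
                 "factorizations": p.factorizations,
                 "best_loss": p.best_loss, "cpu_time": p.cpu_time,
                 "wall_time": p.wall_time}
                for p in self.phases],
        }


def transfer_learn(train, val, kernel_spec: KernelSpec, tl: TLConfig,
                   gwo: GWOConfig, featurizer=None,
                   trace: SearchTrace | None = None
                   ) -> tuple[Hyperparameters, TLReport]:
    """Run the seeding-relaxation protocol and return the final
    hyperparameters plus the per-phase report.

    ``train``/``val`` are (X, y) feature/target pairs of the *target* task;
    the source task reuses the target validation set. The final model fit is
    left to the caller (see ``fit_transfer_model``) so that the report's
    factorization counts isolate the search itself.
    """
    X_t, y_t = np.atleast_2d(np.asarray(train[0], float)), np.asarray(train[1], float)
    rng = np.random.default_rng(gwo.seed)
    n_target = X_t.shape[0]

    # Step 1: subsampling (eta = 1 consumes no randomness; S is T itself)
    if tl.eta == 1.0:
        idx = np.arange(n_target)
    else:
        size = int(round(tl.eta * n_target))
        if size < MIN_SOURCE_SIZE:
            raise ValueError(
                f"source set of {size} frames is below the minimum trainable "
                f"size ({MIN_SOURCE_SIZE}); increase eta")
        if tl.subsample_method != "random":
            raise NotImplementedError("only random subsampling is implemented")
        idx = np.sort(rng.choice(n_target, size=size, replace=False))
    X_s, y_s = X_t[idx], y_t[idx]

    n_guess, n_relax = split_iterations(gwo.tau, tl.zeta, tl.full_seeding)
    report = TLReport(tl.eta, tl.zeta, tl.full_seeding,
                      source_size=X_s.shape[0], target_size=n_target)

    # Step 2: guessing phase — GWO on the source set
    src_obj = IhocvObjective(X_s, y_s, val[0], val[1], kernel_spec,
                             search_prefactor=gwo.search_prefactor)
    bounds = search_bounds(src_obj.n_feats, gwo)
    t_cpu, t_wall = time.process_time(), time.perf_counter()
    guess = minimize_objective(src_obj, bounds, gwo, rng=rng, tau=n_guess,
                               a_max=tl.a_max_guess, trace=trace)
    report.phases.append(PhaseReport(
        "guess", X_s.shape[0], n_guess, src_obj.n_evals, guess.best_loss,
        time.process_time() - t_cpu, time.perf_counter() - t_wall,
        guess.history))
    theta0 = guess.best_position
    report.guess_hyperparameters = src_obj.decode(theta0)

    if n_relax == 0:
        # FS-TL: frozen seed, no relaxation and no full-size search
        return src_obj.decode(theta0), report

    # Steps 3-4: relaxation phase — perturb the guess, relax on the target
    tgt_obj = IhocvObjective(X_t, y_t, val[0], val[1], kernel_spec,
                             search_prefactor=gwo.search_prefactor)
    pack = perturb_guess(theta0, gwo.W, tl.r_max, rng, bounds)
    t_cpu, t_wall = time.process_time(), time.perf_counter()
    relax = minimize_objective(tgt_obj, bounds, gwo, rng=rng,
                               init_positions=pack, tau=n_relax,
                               a_max=tl.a_max_relax, trace=trace)
    report.phases.append(PhaseReport(
        "relax", n_target, n_relax, tgt_obj.n_evals, relax.best_loss,
        time.process_time() - t_cpu, time.perf_counter() - t_wall,
        relax.history))
    return tgt_obj.decode(relax.best_position), report


def fit_transfer_model(train, kernel_spec: KernelSpec,
                       hyper: Hyperparameters, target_name: str = "",
                       center_atom: int = -1) -> GPRModel:
    """Final fit on the full target set at the transferred hyperparameters
    (one additional full-size factorization)."""
    return fit_gpr(train[0], train[1], hyper, kernel_spec,
                   target_name=target_name, center_atom=center_atom)
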