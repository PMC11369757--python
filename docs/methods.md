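# Methods

This note records the model, the algorithms, the default parameters (with
units), and the numerical choices made in `alfgp`. It is the reference for
anyone auditing the test suite or reusing the package on real data.

## 1. Problem setting

`alfgp` trains one Gaussian-process regression (GPR) model per atom and per
target property (atomic energy `E_IQA` in kJ/mol, atomic charge `Q00` in e)
on conformers of a single molecule. Molecular predictions are reconstructed
as the sum of the atomic predictions, which is exact whenever the reference
atomic properties partition the molecular ones additively. The expensive part
of training is not the final fit but the hyperparameter search, which
factorizes an N x N covariance matrix at every candidate evaluation; the
transfer-learning protocol exists to cut the number of *full-size*
factorizations.

## 2. Featurization: atomic local frames (ALF)

Each atom A gets a right-handed local frame from its bonded neighbourhood
(bonds = interatomic distance below 1.2 x the sum of Cordero covalent radii):
the x-axis atom is the heaviest bonded neighbour (ties -> lowest index), the
xy-plane atom the next in the same priority order; a terminal atom borrows
the x-axis atom's neighbours for the plane. The feature vector of atom A has
3N - 6 entries: the two frame distances (angstrom), the valence angle between
them (rad), then an (r, theta, phi) spherical triple for every remaining atom
in index order. The azimuthal angles phi are cyclic; with 1-based feature
index d they sit at d % 3 == 0, d >= 6, and are flagged by a periodic mask
(the valence angle at d = 3 is bounded in [0, pi] and treated as
non-periodic; a `strict_mod3` switch restores the literal every-third rule).
Features are deliberately unscaled. Rigid rotations and translations of the
conformer leave the features unchanged (tested to 1e-9).

## 3. GPR model

Composite product kernel over feature dimensions:

- ordinary dimension: phi_d = exp(-theta_d * delta_d^2)
- cyclic dimension:   phi_d = exp(-theta_d * sin^2(delta_d / 2))

with an optional signal-variance prefactor sigma_f^2 (fixed to 1 by default)
and a diagonal regularisation noise sigma_n^2. The prior mean is the constant
mean of the training targets, so far-field predictions fall back to it.
Training solves K omega = y - m by Cholesky factorization; a failed
factorization raises (`CholeskyError`, advice: raise sigma_n^2) — there is no
silent jitter. Models serialize to a versioned plain-text format (JSON header
plus float payload).

Default search bounds: theta_d in [0, 3] (linear), sigma_n^2 in
[1e-14, 1e-4] (searched in log10 space, since the bounds span ten decades);
prefactor search off by default, bounds [1e-3, 1e3] (log10) when on.

## 4. Hyperparameter search: IHOCV + GWO-RUHL(n, p)

The loss of a candidate is the validation RMSE of the intermediate GPR model
fitted on the training set at the candidate's hyperparameters (iterative
hold-out cross-validation). Failed factorizations score +inf and are simply
outranked.

The grey wolf optimizer keeps W candidates (pack), initialized as the best W
of a uniform random pool. Per iteration t (of tau), with
a(t) = a_max (1 - t/tau): the three best wolves (alpha/beta/delta) stay put;
every other (omega) wolf j moves to the mean over the three leaders l of
l - A.(|C.l - j|), with A = 2 a r1 - a, C = 2 a r2 (switch `vanilla_C`
restores the classic C = 2 r2), r1, r2 fresh uniform draws per leader and
dimension. Components leaving the box are redrawn uniformly inside it. Every
p iterations, n randomly chosen omega wolves are promoted to
L (1 + eps), eps ~ U(-r, r) per component, where L is the leader centroid
(RUHL). Ranking is stable: ties in loss break by candidate id.

Defaults (full scale): W = 50, pool = 500, tau = 200, a_max = 2.0, n = 5,
p = 5, r = 0.20.

Performance: the per-dimension squared/sin^2 feature differences of the
training and validation pairs are precomputed once per dataset
(`IhocvObjective`), so one candidate evaluation is a matrix-vector product,
one `exp`, and one Cholesky solve. Measured on one CPU core: ~0.032 s per
evaluation at N = 1000 training points, ~5 ms at N = 300.

## 5. Transfer learning (seeding–relaxation)

1. Subsample the target training set T to a source S with |S| = eta |T|
   (eta = knowledge compression coefficient; eta = 1 means S is T itself and
   consumes no randomness, so the protocol reduces *bit-identically* to
   direct learning). Sources below 10 frames are rejected.
2. Guessing phase: run the GWO search on S for (1 - zeta) tau iterations
   (full tau under `full_seeding`) with a_max_guess = 2.0.
3. Perturb the guess theta0 into a W-member pack: row 0 is theta0, the rest
   theta0 (1 + r_max eps), eps ~ U(-1, 1) per component, r_max = 0.25,
   clamped to bounds. The perturbation acts in search coordinates (theta
   linear, noise log10).
4. Relaxation phase: run zeta tau iterations on T from that pack with
   a_max_relax = 1.0. zeta = 0 skips relaxation entirely (frozen-seed TL).

Analytic cost model (per-iteration cost dominated by the O(N^3)
factorization): gamma = eta^3, Delta = (1 - zeta) N_s gamma + zeta without
full seeding, N_s gamma + zeta with it; expected speedup = 1/Delta. These are
*model* quantities; the tests assert counted factorizations, never wall time.

Counted cost (instrumented, asserted exactly in the tests): a search phase
performs `init + n_iter (W - 3) + n (n_iter // p)` factorizations at its
training size, where init = pool for a fresh search and W for the relaxation
pack; the final model fit adds one more at |T|.

## 6. Molecular deployment

- Reconstruction: molecular value = sum of atomic predictions (exact
  linearity, tested to 1e-12).
- Dataset filtering: keep a frame iff the tabulated atomic properties
  reconstruct the molecular references within 1.0 kJ/mol (energy) and
  0.001 e (charge); idempotent.
- Forces: central finite differences of the energy, h = 0.01 angstrom,
  accuracy O(h^2).
- Normal modes: Hessian from central differences of those forces,
  symmetrized by averaging, mass-weighted, diagonalized; eigenvalues
  converted via (kJ/mol/angstrom^2/amu) -> s^-2 with the CODATA factor
  1.0e3 / (N_A m_u 1e-20) ~ 1.0000e26, then to cm^-1; negative eigenvalues
  are reported as negative frequencies. No translational/rotational
  projection is applied, so six (five for linear molecules) near-zero modes
  appear explicitly.
- Geometry optimization: damped steepest descent on the FD forces with an
  adaptive scalar step (x1.2 on acceptance, /2 on rejection; error after 50
  consecutive rejections), stopping at max |F| < force_tol (default
  1 kJ/mol/angstrom) or max_steps (default 2000). The accepted energy trace
  is non-increasing by construction.
- Kabsch RMSD via `scipy.spatial.transform.Rotation.align_vectors`, with the
  residual computed directly from the aligned coordinates (the rssd returned
  by scipy loses ~8 digits to cancellation for near-identical structures).

## 7. Synthetic data

- Toy molecule: an H-O-O-H chain with harmonic bonds (k = 3500/2500/3500
  kJ/mol/A^2 at 0.96/1.45/0.96 A), harmonic valence angles (300 kJ/mol/rad^2
  at 100 deg) and a cosine torsion (amplitude 12 kJ/mol at 112 deg). Atomic
  energies are e0_A + w_A x strain (weights sum to 1), atomic charges
  q0_A + u_A x s(geometry) (responses sum to 0), so atomic values sum to the
  molecular ones to machine precision before observation noise (0.5 kJ/mol
  and 0.5 me per atom — set so the reconstruction filter bites on a visible
  fraction of frames). Conformers: Gaussian internals about equilibrium
  (sd = `spread`: angstrom for bonds, rad for angles) and a *uniform*
  dihedral over (-pi, pi]; steric clashes below 0.4 A are resampled.
- GP draws: X uniform on [0, 2] per ordinary dimension and (-pi, pi] per
  cyclic one; y from the zero-mean GP at known theta* = [2.5, 0.3, 1.8, 0.9]
  (chosen with strong ARD contrast so theta* is identifiable from n = 300
  points) and noise* = 1e-6.

## 8. Desk-scale test sizes (package's own choices)

The acceptance-grade tests must finish on one CPU core inside a CI budget,
so the study sizes are scaled down from the full-scale defaults; tolerances
and assertions are NOT scaled:

- TL quality study: |T| = 1000 training frames (instead of 1500), 300
  validation, 500 test, tau = 60, W = 20, pool = 2W, three seeds,
  eta in {0.01, 0.10, 0.25}, zeta = 0.10. Measured: one loss evaluation at
  N = 1500 costs ~0.08 s, putting the full-size study at ~30 min for this
  suite alone; N = 1000 (~0.032 s/eval) fits the budget. |T| = 1000 is also
  the smallest target for which eta = 0.01 still yields a trainable
  (10-frame) source.
- Geometry-optimization contract runs with force_tol = 0.2 kJ/mol/A, chosen
  a priori from the toy's softest curvature (the ~6 kJ/mol/rad^2 torsion) so
  that the stationarity residual alone cannot consume the 0.1-A RMSD budget.
- The near-zero-mode check uses an all-oxygen trimer bound by pairwise
  harmonic springs (k = 100 kJ/mol/A^2). The FD Hessian contaminates the
  (exactly zero) rotational curvatures at O(k h^2 / r^2), i.e. a spurious
  frequency ~ sqrt(k/m) h; on the stiff, light default toy this reaches
  ~27 cm^-1 at h = 0.01, while the soft heavy trimer honestly shows all six
  invariance modes below 2 cm^-1.

## 9. Limitations

- Forces on GPR surfaces are finite-difference, not analytic; geometry
  optimization is a simple force follower, not MD or quasi-Newton.
- No uncertainty (posterior variance) is exposed; predictions are posterior
  means only.
- The feature set assumes a single bonded topology across all frames and at
  least 3 atoms; periodic systems and multipoles beyond Q00 are out of
  scope.
- Timing *speedups* are hardware statements and are reported in logs only;
  all assertions are on counted factorizations or the analytic Delta model.
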