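# alfgp

Anisotropic Gaussian-process regression for atomistic property surfaces,
with a grey-wolf hyperparameter search and a seeding–relaxation
transfer-learning protocol that cuts the number of full-size covariance
factorizations.

## What it does

Machine-learned force fields of the atomistic kind train one regression
model per atom: each atom's contribution to the molecular energy (kJ/mol)
and its partial charge (e) is predicted from a rotation- and
translation-invariant description of the atom's surroundings, and molecular
values are recovered as the sum of the atomic predictions. `alfgp`
implements the full pipeline for a single molecule:

- **ALF featurization** — each atom gets a local right-handed frame from its
  two highest-priority bonded neighbours; features are the two frame
  distances, the valence angle, and spherical (r, theta, phi) triples for
  all remaining atoms. Azimuthal angles are cyclic and tracked by a periodic
  mask.
- **Composite-kernel GPR** — a product kernel with one anisotropy theta_d
  per feature: a squared-exponential factor on ordinary dimensions and a
  periodic factor `exp(-theta_d sin^2(delta/2))` on cyclic ones, plus a
  diagonal noise term. Fitting is a single Cholesky solve; there is no
  silent jitter.
- **GWO-RUHL(n, p) hyperparameter search** — a grey wolf optimizer over
  theta (linear in [0, 3]) and the noise (log10 in [1e-14, 1e-4]),
  minimizing the validation RMSE of the intermediate model (IHOCV loss),
  with a "random upgrade of hierarchy of lucky wolves" move every p
  iterations.
- **Transfer learning** — search first on a small subsample (fraction eta of
  the training set), then perturb the found hyperparameters into a fresh
  pack and relax for the last zeta fraction of iterations at full size. An
  analytic cost model (gamma = eta^3, relative cost Delta) predicts when
  this is worthwhile; the implementation also counts actual factorizations
  per phase. At eta = 1, zeta = 0 the protocol is bit-identical to direct
  learning.
- **Deployment** — molecular reconstruction, dataset filtering against
  reconstruction margins, finite-difference forces and normal modes,
  damped steepest-descent geometry optimization, and Kabsch RMSD.
- **Synthetic data** — a four-atom H-O-O-H toy molecule with exactly
  decomposable atomic energies/charges, and GP prior draws at known
  hyperparameters, so every claim in the test suite is checked against
  ground truth.

See `docs/methods.md` for equations, defaults, units, and the numerical
choices (including the deliberately reduced problem sizes used in the test
suite).

## Worked example

Everything is driven by a TOML file; unset keys take documented defaults.

```toml
# run.toml
seed = 0

[data]
n_train = 200
n_val = 60
n_test = 60

[gwo]
W = 12      # pack size
pool = 24   # initial candidate pool
tau = 30    # iterations
n_lucky = 3

[train]
targets = ["E_IQA"]
```

Train one GPR model per atom on simulated toy data, then score the test
split (outputs below are the actual numbers these commands print at
seed 0):

```text
$ alfgp train --config run.toml --out run
trained 4 models into run/models

$ alfgp predict --config run.toml --out run
{
  "E_IQA": {
    "MAE": 1.3831901929199526,
    "RMSE": 1.9880057996853087,
    "R2": 0.9505357158193314
  }
}
```

`run/` now contains the serialized models, a per-iteration search trace
(`trace_E_IQA_atom0.csv`: best loss falls from 1.117 to 0.923 over the 30
iterations), and `timing.json` (313 counted covariance factorizations per
model: 24 pool + 30x9 omega moves + 3x6 lucky promotions + 1 final fit).

Normal modes and geometry optimization on the analytic toy surface:

```text
$ alfgp modes --config run.toml --out run2
analytic surface: 12 modes, max 3226.0 cm^-1

$ alfgp minimize --config run.toml --out run2 --df 0.3 --force-tol 0.5
{
  "surface": "analytic",
  "DF": 0.3,
  "converged": true,
  "steps": 27,
  "delta_E": 0.007609725653310306,
  "rmsd": 0.012051588421460186
}
```

The modes table shows the expected structure: six invariance modes near
zero (here within 27 cm^-1 — a finite-difference artifact quantified in
`docs/methods.md`), then real vibrations up to the two O-H stretches at
~3226 cm^-1. `minimize` perturbs the minimum along a mode, re-minimizes,
and reports the energy gap and Kabsch RMSD to the reference minimum.

Transfer learning and the DL-vs-TL comparison grid:

```sh
alfgp train --config run.toml --out run_tl   # with [transfer] transfer_learning = 1
alfgp experiment --config run.toml --out grid  # [experiment] etas/zetas sweep
```

Other commands: `alfgp simulate` (write the benchmark datasets to disk) and
`alfgp <cmd> --seed N` (override the config seed). All commands are
deterministic given the config and seed.

## Library use

```python
import numpy as np
from alfgp.geometry import compute_alf, featurize_set, periodic_mask
from alfgp.gpr import KernelSpec, fit_gpr, predict
from alfgp.hyperopt import GWOConfig, optimize
from alfgp.synthetic import default_toy, make_benchmark

toy = default_toy()
train, val, test, _ = make_benchmark(toy, 200, 60, 60, seed=0)
alf = compute_alf(train.geometry(0))
spec = KernelSpec(periodic_mask(4))

Xt = featurize_set(train, alf, 0)           # (200, 6) ALF features, atom 0
yt = train.atomic_properties["E_IQA"][:, 0]
Xv = featurize_set(val, alf, 0)
yv = val.atomic_properties["E_IQA"][:, 0]

result = optimize((Xt, yt), (Xv, yv), spec,
                  GWOConfig(W=12, pool=24, tau=30, n_lucky=3, seed=0))
model = fit_gpr(Xt, yt, result.hyperparameters, spec, target_name="E_IQA")
pred = predict(model, featurize_set(test, alf, 0))
# test MAE for this atom: 0.836 kJ/mol
```

## Layout

```
src/alfgp/geometry.py   XYZ/CSV I/O, ALF, featurization
src/alfgp/gpr.py        composite kernel, fit/predict, model (de)serialization
src/alfgp/hyperopt.py   IHOCV loss, GWO-RUHL optimizer, search traces
src/alfgp/transfer.py   TL protocol, analytic timing model, counted costs
src/alfgp/molecule.py   reconstruction, filtering, forces, modes, minimizer
src/alfgp/synthetic.py  toy molecule, GP prior draws, benchmark assembly
src/alfgp/config.py     TOML schema with strict validation
src/alfgp/cli.py        click CLI (simulate|train|predict|modes|minimize|experiment)
```
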