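# discmech

Multi-parametric quantitative MRI and biphasic mechanics of intervertebral
discs: simulation, parameter estimation, and cohort statistics.

## The problem

Planning treatment of spine pathologies needs the rigidity and
permeability of the intervertebral disc (IVD), but these can only be
measured destructively.  Quantitative MRI offers a non-invasive proxy:
the relaxation times T1 and T2, the magnetization transfer ratio MTR,
and the diffusion-tensor invariants ADC and FA all track the water,
proteoglycan and collagen content that also sets the disc's mechanical
behaviour.  The working hypothesis is a linear one — that a compressive
modulus or permeability MP of the nucleus pulposus (NP) or annulus
fibrosus (AF) can be predicted as

    MP = a0 + a1·T1 + a2·T2 + a3·MTR + a4·ADC + a5·FA

`discmech` implements the full analysis chain behind that hypothesis,
for anyone who wants to run it on their own disc (or cartilage) data or
to study its statistical behaviour in silico:

- **`discmech.synthetic`** — seeded generators for every input: MRI
  signal series and phantoms (Rician noise), unconfined/confined
  stress-relaxation curves, Darcy permeametry records, and four-group ×
  two-region cohort tables with a configurable linear MRI→mechanics
  linkage patterned on the published group means and SDs.
- **`discmech.qmri`** — estimators for T1 (inversion-recovery TSE model,
  grid-initialized nonlinear least squares), T2 (log-linear), MTR,
  and the diffusion tensor (log-linear least squares; ADC/FA from the
  eigenvalues), voxelwise or per ROI.
- **`discmech.biomech`** — biphasic forward models and fitters:
  E, μ, k_r, ν, c from unconfined compression (Bessel-mode series
  solution of radial consolidation + quasi-linear viscoelastic overlay);
  H_A0, k_0, β, M from confined compression (nonlinear consolidation PDE
  with H_A0·e^{βε}, k_0·e^{Mε} laws, mass-conserving finite-volume
  solver); k_a from Darcy's law k = Q·l·μ/(ΔP·S); plus the 0.1 g/min
  equilibrium stop criterion.
- **`discmech.stats`** — one-way ANOVA with Dunn–Šidák post-hoc,
  the multilinear regressions with R², standard error of estimate,
  noncentral-F power and VIF-based predictor elimination, correlation
  PCA with correlation circles, and Ward clustering (heights = exact
  within-cluster sum-of-squares increments) with a reproducible
  "natural division" rule for the cluster count.
- **`discmech.pipeline`** — `run_study` chains
  simulate → fit-mri → fit-mech → analyze into a hash-stamped,
  byte-reproducible run directory; `discmech` is also a CLI with
  `simulate`, `fit-mri`, `fit-mech`, `analyze`, `run` and `report`
  subcommands.

See `docs/methods.md` for the models, their assumptions, and the
numerical choices.

## Worked example

Simulate a nucleus-pulposus acquisition at the healthy group means
(T1 1140 ms, ADC 15.04×10⁻⁴ mm²/s, FA 8.03×10⁻²), add Rician noise,
and refit:

```python
from discmech import qmri
from discmech.acquisition import default_protocol
from discmech.synthetic import (TissueGroundTruth, tensor_from_md_fa,
                                simulate_ir_series, simulate_dwi_series,
                                add_rician_noise, simulate_darcy_test)
from discmech.biomech import darcy_permeability

proto = default_protocol()
truth = TissueGroundTruth(t1=1140, t2=124, mtr=0.34,
                          tensor=tensor_from_md_fa(15.04e-4, 0.0803), s0=1000)

ir = add_rician_noise(simulate_ir_series(truth, proto, magnitude=True), 5.0, seed=1)
t1, s0, diag = qmri.fit_t1(ir, proto, magnitude=True)

dwi = add_rician_noise(simulate_dwi_series(truth, proto), 5.0, seed=2)
adc, fa = qmri.tensor_metrics(qmri.fit_diffusion_tensor(dwi, proto))

k_a = darcy_permeability(simulate_darcy_test(10.0))
```

This prints (seeds as above):

```
T1 = 1140.8 ms (truth 1140), S0 = 1001.2, converged=True
ADC = 15.06 x1e-4 mm^2/s (truth 15.04), FA = 8.17 x1e-2 (truth 8.03)
k_a = 10.00 x1e-15 m^4/(N s) (truth 10)
```

i.e. with ~0.5% noise the estimators sit within a fraction of a percent
of the ground truth for T1 and ADC; FA, a noise-amplifying dispersion
measure, moves ~2% — exactly the behaviour that matters when comparing
disc groups whose FA differs by a factor of two.

A full study (cohort simulation, phantom fitting, mechanical fits, and
the whole statistics layer) is one call:

```sh
discmech run --seed 1 --out runs/demo
```

which writes `simulate/cohort.csv`, `analyze/regressions.csv`,
dendrograms in Newick form, and a human-readable `report.md`, all
stamped with the config hash; rerunning reproduces identical bytes.

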