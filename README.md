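# labelkin

Kinetic analysis for self-labeling protein tags (SNAP-tag, HaloTag,
CLIP-tag and relatives). Given fluorescence-polarization or anisotropy
time traces recorded across a protein-concentration series, `labelkin`
fits mass-action kinetic schemes globally and reports apparent
second-order labeling rate constants with Monte Carlo confidence
intervals. It is aimed at chemical biologists characterizing tag or
substrate variants, and at method developers who need a tested,
scriptable replacement for spreadsheet + DynaFit workflows.

## What it computes

The labeling reaction between tag protein P and substrate S is modeled
by one of three schemes:

* **direct**: P + S → PS, rate constant k_app (M⁻¹ s⁻¹); the
  irreversible second-order system has a closed-form solution used
  directly in fitting;
* **two-step**: P + S ⇌ PS\* (k₁, k₋₁), PS\* → PS (k₂), for
  stopped-flow data that resolve the encounter complex. Derived:
  K_d = k₋₁/k₁ and the composite k_app = k₁k₂/(k₂+k₋₁);
* **competition**: P + S → PS (kS_app) and P + I → PI (kI_app), for
  ranking nonfluorescent substrates against a fluorescent reporter.

The measured signal is affine in the bound fraction,
signal = r_free + (r_bound − r_free)·bound/total. Baseline r_free and
protein concentrations are fixed; rate constants, r_bound and a shared
substrate-concentration correction are fitted to all traces at once
(limiting-protein wells make the substrate concentration identifiable
through their lowered plateau). Uncertainty comes from a parametric
bootstrap: simulate from the fit at the residual noise level, refit,
exclude the worst 5%, report percentile intervals.

Also included: one-phase association screening fits, sigmoidal in-cell
labeling curves (t½ with CI propagation across biological duplicates),
Gaussian filament-profile FWHM fits, extinction-coefficient fits, and a
synthetic-data generator reproducing the standard microplate,
stopped-flow, competition and in-cell designs.

## Worked example

Simulate the standard microplate design (substrate 20 nM, protein 0 and
a 2-fold ladder from 900 nM down) from a known rate constant, then run
the full inference chain:

```python
import numpy as np
from labelkin import (
    FitSpec, Model1Params, global_fit, monte_carlo_ci,
    average_all_replicates, extract_baseline,
)
from labelkin import synthetic as syn
from labelkin.observables import ObservableMap

truth = Model1Params(1.51e5)                      # M^-1 s^-1, ground truth
obs = ObservableMap(r_free=60.0, r_bound=300.0)   # mP
template = syn.platereader_std(seed=1, grid=np.arange(0.0, 7201.0, 60.0))
traces = syn.generate(template, truth, obs)

averaged = average_all_replicates(traces)
r_free = extract_baseline(averaged)
spec = FitSpec(scheme="model1", r_free=r_free)
fit = global_fit(averaged, spec, obs)
mc = monte_carlo_ci(averaged, spec, obs, fit, n=1000, drop_frac=0.05, seed=1)

print(f"k_app     = {fit.estimates['k_app']:.4g} M^-1 s^-1")
print(f"95% CI    = ({mc.ci['k_app'][0]:.4g}, {mc.ci['k_app'][1]:.4g})")
print(f"S0 (adj.) = {fit.adjusted_S0:.4g} M  (nominal 2e-08)")
print(f"r_bound   = {fit.estimates['r_bound']:.1f} mP")
print(f"residual sd = {fit.residual_sd:.2f} mP over {fit.n_points} points")
print(f"MC kept   = {mc.n_kept}/{mc.n_requested}")
```

Output:

```
k_app     = 1.523e+05 M^-1 s^-1
95% CI    = (1.485e+05, 1.56e+05)
S0 (adj.) = 2.001e-08 M  (nominal 2e-08)
r_bound   = 300.2 mP
residual sd = 4.79 mP over 968 points
MC kept   = 950/1000
```

The fitted k_app (1.523×10⁵) recovers the generating value 1.51×10⁵
within 1%, and the true value lies inside the bootstrap CI. The
adjusted substrate concentration lands on the nominal 20 nM, and the
residual sd matches the generator's noise (2% of the 240 mP dynamic
range ≈ 4.8 mP). Exactly 950 of 1000 bootstrap refits are kept after
the 5% worst-fit exclusion.

The same pipeline is available from the shell — `labelkin simulate`,
`labelkin fit`, `labelkin montecarlo`, `labelkin report` — driven by a
YAML config; every run writes a fit report, residual CSV and a manifest
recording the command line, config, seed and input checksums. Traces
are exchanged as plain CSV with molar concentrations (see
`labelkin.io.TRACE_COLUMNS`).

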