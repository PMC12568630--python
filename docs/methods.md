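# Methods

## The measurement problem

Self-labeling protein tags (SNAP-tag and its descendants, HaloTag,
CLIP-tag) react covalently and irreversibly with a small synthetic
substrate that carries a payload, usually a fluorophore. The figure of
merit of a tag–substrate pair is the apparent second-order rate constant
k_app (M⁻¹ s⁻¹) of the labeling reaction. In vitro it is measured by
following a polarization or anisotropy signal over time: the small free
fluorophore tumbles fast (low signal, `r_free`); once bound to the
~20–35 kDa tag it tumbles slowly (high signal, `r_bound`). This package
implements the full inference chain from such traces to rate constants
with uncertainty.

## Kinetic schemes

Three mass-action schemes cover the experimental regimes
(`labelkin.models`):

1. **Direct scheme** — `P + S → PS` with one constant k_app. The ODEs
   are d[P]/dt = d[S]/dt = −k_app[P][S], d[PS]/dt = +k_app[P][S].
   Appropriate for microplate kinetics, where the sub-second binding
   step is not resolved. The irreversible second-order reaction has an
   exact solution,

       PS(t) = P0·S0·(1 − e^(−k(P0−S0)t)) / (P0 − S0·e^(−k(P0−S0)t)),

   with the equal-concentration limit PS(t) = C²kt/(1 + Ckt). The
   closed form is what fitting evaluates (fast and exact); the generic
   ODE route is retained as an independent cross-check, and the test
   suite requires ≤1e−8 relative agreement between the two. For
   P0 < S0 the expression is evaluated in a rearranged form that avoids
   overflow of the growing exponential; within 1e−9 relative of
   P0 = S0 the equal-concentration branch is used (its error there is
   far below integrator tolerance).

2. **Two-step scheme** — `P + S ⇌ PS* ; PS* → PS` with association k1
   (M⁻¹ s⁻¹), dissociation k_−1 (s⁻¹) and covalent chemistry k2 (s⁻¹).
   Needed for stopped-flow data at micromolar concentrations, where the
   non-covalent encounter complex PS* is populated. Two derived
   quantities summarize it: the affinity K_d = k_−1/k1 and the
   composite constant

       k_app = k1·k2 / (k2 + k_−1),

   the labeling speed in the sub-saturating (second-order) regime. A
   regime-limit test verifies that at concentrations ≪ K_d the two-step
   scheme reproduces the direct scheme run at this composite constant
   to within 2%.

3. **Competition scheme** — a nonfluorescent substrate S and a
   fluorescent reporter I race for the same protein:
   `P + S → PS` (kS_app) and `P + I → PI` (kI_app), both irreversible
   mass action. Only PI is observed; increasing competitor suppresses
   reporter labeling, which encodes kS_app. All five rate equations are
   plain mass action (d[PS]/dt = kS_app[P][S] etc.), the only form that
   is dimensionally consistent with the scheme and conserves mass.

Integration uses LSODA (switching to BDF when stiff — the two-step
scheme at stopped-flow concentrations mixes ~10⁷ M⁻¹ s⁻¹ association
with ≥10² s⁻¹ unimolecular steps) with rtol 1e−10. Species are
nondimensionalized by the total concentration before integration so
that the absolute tolerance (1e−12 on the scaled system) is meaningful
at any concentration scale from nM to µM; without the scaling, the
≤1e−8 oracle agreement is not reachable at nanomolar inputs. Tiny
negative excursions below the tolerance scale are clipped to zero;
anything larger would surface as a test failure.

## Observables

FP (mP) and anisotropy are both modeled as affine in the bound mole
fraction (`labelkin.observables`):

    signal(t) = r_free + (r_bound − r_free) · Σ bound(t) / fluor_total.

For the two-step scheme both PS* and PS count as bound by default — a
non-covalently bound fluorophore already tumbles with the protein — and
this is configurable to {PS} only. Strictly, anisotropy mixing is
intensity-weighted; the affine form is exact only at matched quantum
yields, which is the standard working assumption for non-fluorogenic
substrates and the one adopted here. Fluorogenic quantum-yield changes
on binding would break the affine form and are out of scope.

The key identifiability feature is the *decreasing plateau*: when
protein is limiting (P0 < S0), only a fraction P0/S0 of the substrate
is ever labeled, so the final signal falls below r_bound. Because the
designs deliberately include limiting-protein wells, the substrate
concentration itself becomes fittable (see below).

## Preprocessing

`labelkin.preprocess` mirrors what instrument software leaves undone:
technical replicates sharing a hardware time grid are averaged
pointwise (grids disagreeing by >1 ns are an error — no silent
resampling); stopped-flow pretrigger samples are removed and times
shifted to start at zero; the baseline r_free is the time-mean of the
zero-protein (free substrate) traces, under a flat-trace model, and is
fixed in all downstream fits. Fit entry points refuse unaveraged
replicate stacks rather than preprocessing silently.

## Global fitting

`labelkin.estimation.global_fit` fits one shared parameter vector to
every trace of a concentration series simultaneously:

* fixed: r_free (from the baseline), each trace's nominal protein
  concentration, and the instrument dead time (delay, default 0 s);
* free: the scheme's rate constants, the bound-state signal r_bound,
  and a shared substrate-concentration factor, bounded to ±50% of
  nominal, absorbing quantification error (identifiable through the
  decreasing plateau).

Rate constants are optimized as log10 values inside bounds of
[1e0, 1e10] M⁻¹ s⁻¹ for second-order and [1e−6, 1e6] s⁻¹ for
first-order constants, with bounded trust-region least squares
underneath and uniform residual weighting. Five log-spaced multi-starts
(three for reduced test scales) guard against local minima; for the
two-step scheme the start ladder sweeps the association constant over
decades with the unimolecular steps tracking it, covering both the
rapid-equilibrium and the chemistry-limited corner. The best start's
solution is reported, with the objective (SSR), the residual sd
normalized by the residual degrees of freedom, and the adjusted
substrate concentration.

For the two-step scheme, k1, k_−1 and k2 are individually weakly
determined when the design barely reaches saturation, but the composite
k_app is well determined — the Monte Carlo samples show a markedly
smaller relative spread for the composite than for k1 or k_−1. Reported
headline values are therefore composites.

Secondary fits (all via `lmfit`): one-phase association
Y = Y0 + (Ymax−Y0)(1−e^(−kt)) with k_app = k/[P] in the pseudo-first-
order regime; the sigmoidal in-cell curve
Y = Y0 + (Ymax−Y0)/(1+(t_half/x)^H) in minutes, with an asymptotic 95%
CI on t_half from the covariance at the optimum; the Gaussian line
profile y = y0 + A/(ω√(π/2))·e^(−2(x−x_c)²/ω²) with FWHM = ω√(2 ln 2);
and the Beer–Lambert line whose slope over the cuvette path length
(default 0.3 cm) gives the extinction coefficient. Degenerate inputs
(flat traces, peakless profiles, zero-variance concentrations) raise
typed errors rather than returning noise-fitted parameters.

## Monte Carlo uncertainty

`monte_carlo_ci` implements the Monte Carlo CI convention used with
kinetic global fits as a parametric bootstrap: n synthetic datasets are
simulated from the fitted model with i.i.d. Gaussian noise at the fit's
residual sd (residual resampling is available as a flavor), each is
refitted starting from the best-fit point, the worst `drop_frac` of
refits by final objective is excluded (default n = 1000 with 5%
excluded, keeping exactly 950; non-convergent refits count toward the
excluded fraction), and per-parameter sds and 2.5/97.5 percentile
intervals are reported. With a fixed seed the result is bit-identical.
A coverage test at reduced scale (200 independent datasets, n = 100
bootstrap refits each) checks that the 95% interval covers the true
rate constant at the nominal rate within ±5 points.

For biological duplicates of the in-cell t_half, `propagate_duplicate_ci`
computes mean = (t1+t2)/2, per-replicate SE_i = (CI_hi−CI_lo)/(2·1.96),
pooled SE = √((SE1²+SE2²)/2), and CI = mean ± 1.96·pooled SE. The
pooled form divides the summed squares by 2, not by 4 as the textbook
standard error of a two-replicate mean would; this convention is
implemented verbatim as the default because it is the one used with
such duplicate summaries in practice, with the textbook variant behind
`textbook=True`.

## Synthetic data

`labelkin.synthetic` generates instrument-faithful datasets for the
standard designs, with defaults:

| template | fluorophore | protein ladder | grid | replicates |
|---|---|---|---|---|
| platereader_std | 20 nM | 0 + 2-fold ladder 900→7 nM (8 steps) | 30 s × 2 h | 1 |
| platereader_fast | 2 nM | 0 + 2-fold ladder 50→0.78 nM | 30 s × 2 h | 1 |
| stoppedflow | 0.5 µM | 0 + geometric 0.25–3.13 µM (5 steps) | 1 ms × 2 s (dual-rate 200 µs/2 ms optional) | 15 |
| competition | reporter 100 nM | 0 and 200 nM; competitor 0 + 0.1–1 µM | 10 s × 1 h | 1 |
| incell | — | — | 30 s × 90 min | 1 |

The published microplate design states only the ladder's range
(4.60–900 nM), not its dilution factor; a 2-fold ladder is the default
and configurable. Noise is additive i.i.d. Gaussian on the signal with
default sd 2% of the free-to-bound dynamic range — instrument noise
magnitudes are not published, so this default is declared, not
inferred. One master seed governs a dataset; per-trace substreams are
derived from (seed, trace index), so extending a design never
reshuffles the noise of existing traces.

What the generator does *not* emulate: photobleaching and drift,
injector/mixing artifacts, detector saturation, heteroscedastic noise,
cell-to-cell expression variability. Passing recovery tests therefore
demonstrate the correctness of the inference chain under the stated
noise model, not robustness to every instrument pathology.

## Problem sizes in the shipped tests and acceptance run

Recovery tests and the acceptance script run the stopped-flow design at
4 ms sampling over 2 s (501 points/trace, 5 protein concentrations,
15 replicates averaged) and the microplate design at 30–300 s sampling;
the Monte Carlo coverage check uses 200 datasets × 100 bootstrap refits
on a 4-concentration microplate set. These sizes were chosen so the
whole chain — generation, preprocessing, multi-start ODE fitting,
bootstrap — runs on a laptop-class single core in minutes while leaving
the estimators' behavior unchanged; the recovered composite constants
sit well inside the acceptance tolerances at these scales.

## Known limitations

* CIs for the sigmoidal t_half are asymptotic (normal-theory), not
  profile-likelihood; for strongly asymmetric likelihoods they will be
  optimistic.
* The competition fit assumes both arms irreversible; a reversible
  reporter would bias kS_app.
* No model selection is performed between schemes; objectives are
  reported and the choice is the analyst's.
* The mixing dead time is supported as a fixed offset but defaults to
  0 s; stopped-flow users should supply their instrument's value.
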