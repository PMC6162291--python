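# Methods

## Model

The package calibrates a two-field phase-field description of an avascular
tumor monolayer. Volume fractions are bookkept as φ_T = φ_V + φ_N (total =
viable + necrotic); hypoxic and proliferative subpopulations are not
resolved separately because the assays only observe viable cells. Mass flux
follows the Cahn–Hilliard structure J = −M̄_T(φ)∇μ with chemical potential
μ = Ψ′(φ_T) − ε_T²Δφ_T, where Ψ(φ) = Ē_T φ²(1−φ)² is a quartic double well
with minima at the pure phases: cells adhere to each other, so the mixture
segregates into tumor/no-tumor regions separated by an interface of
thickness ~ε_T. Necrotic cells are dead and immotile, so the mobility is
degraded to M̄_T = M_T(1 − φ_N/φ_T) (taken as M_T where φ_T = 0, where the
ratio is undefined but no transport occurs anyway). Sources encode logistic
proliferation modulated linearly by nutrient (φ_σ), first-order apoptosis,
and first-order viable→necrotic transfer gated by a Heaviside function on
the nutrient deficit σ_VN − φ_σ. All boundaries are zero-flux.

Spatially homogeneous states make the transport term vanish, so each
calibration stage can use an exact ODE reduction (exponential death,
logistic-with-death, two-compartment necrosis). Each reduction's closed
form is implemented alongside the RK4 integrator and used as its test
oracle; the φ_σ = 0 necrosis case has the closed form
φ_V(t) = φ_V0 e^{−(λ_apop+λ_VN)t}.

## Parameters

| parameter | units | role | default / prior |
|---|---|---|---|
| λ_prol | day⁻¹ | mitosis rate at full nutrient | truth 0.5; prior U(0, 10) |
| λ_apop | day⁻¹ | programmed-death rate | truth 0.09; prior U(0, 10) |
| λ_VN | day⁻¹ | starvation transfer rate | truth e^−2.2…e^−5.5 by serum; prior U(0, 10) |
| K | – | carrying capacity (max viable fraction) | truth 0.14; prior U(0, 1) |
| φ_V0 | – | initial viable fraction | from seeding density; prior U(10⁻⁵, 1) |
| φ_σ | – | nutrient fraction, FBS%/10 | prescribed per scenario |
| σ_VN | – | necrosis nutrient threshold | fixed at 1.0 (10% FBS is optimal, so any deficit gates necrosis on) |
| M_T | μm/day | tumor mobility | truth 200; prior U(0, 1000) |
| Ē_T | – | double-well energy scale | truth 0.65; prior U(0.15, 1.15) |
| ε_T | μm | interface interaction length | truth 30; prior U(1, 1000) |
| σ | data units | noise/inadequacy sd | prior U(10⁻⁵, 20) time courses, U(10⁻⁵, 0.2) mobility |

M_T's μm/day label is carried nominally: inside the fourth-order CH
operator its strict dimension would differ, but the calibration treats it
as a scalar and no dimensional reinterpretation is attempted. Time is in
days, lengths in μm, throughout.

## Statistical model

Measurement noise and model inadequacy are collapsed into a single
zero-mean Gaussian with calibrated sd σ (nothing identifies the two
separately here, and no mean offset is identifiable either). The
time-course likelihood is the product over N_t days × N_r replicates of
Gaussian residual densities between each replicate measurement and the
model's day value. The spatial likelihood replaces the residual with
1 − PCC(data frame, model frame): it is maximized when the model field is
perfectly linearly correlated with the measured field, and treats 1 − PCC
as a Gaussian deviate with calibrated σ. Frame 0 is the model's initial
condition (taken from the data) and is excluded from the spatial product.

Priors are uniform where nothing is known (bounds above). Stage chaining
fits each posterior marginal with a Normal (moment-matched) and, for
positive samples, a LogNormal (moments of the log), keeps whichever is
closer to the empirical CDF in L1, truncates it to the original support,
and uses it as the downstream prior. A KDE-based empirical prior is
available as an option; the parametric fit is the default because its
density is cheap to evaluate inside the next stage's MCMC. Model evidence
is not computed (no model comparison is performed).

### Sampler

Adaptive random-walk Metropolis, one chain. The start point is chosen by
scanning a batch of prior draws (default 256) and running a deterministic
Nelder–Mead descent from the top few (default 3), keeping the best end
point: with hyperpriors as wide as U(10⁻⁵, 20) on a noise sd whose
posterior concentrates near 10⁻³, a chain started at a random prior draw
spends its whole budget locating the mode — and the time-course
posteriors have diffuse pseudo-modes ("everything dies immediately" or
"the signal is flat and the noise is large") that can trap both a
random-walk chain and a single local search, which is why the descent is
multi-start. Burn-in then adapts in two phases: diagonal proposal
widths from cumulative chain variance for the first half, then full
covariance adaptation (Cholesky of the running covariance, scaled by
2.38/√d) with statistics restarted at the phase switch so the covariance
reflects the equilibrated chain rather than the transient. Cumulative
(Welford) statistics are used rather than a sliding window, which we found
can collapse the proposal onto a temporarily stuck chain. The global scale
follows a Robbins–Monro update toward 30% acceptance. All adaptation
freezes at the end of burn-in, so the retained chain is Markovian.
Diagnostics: acceptance rate and a crude autocorrelation-sum ESS per
parameter. Fixed seeds give bit-identical chains.

Posterior-predictive bands resample parameter draws with replacement, push
them through the forward model (vectorized closed forms for the reduced
models), and report the pointwise mean and 2.5/97.5 percentiles. The
production default is 200,000 draws; stages use 2,000 for metric
evaluation, which already puts the Monte Carlo error of the band well
below the calibration errors being reported.

### Error metric

d_t(F, S) = ∫|F_t − S_t| dφ_V / ȳ_t, with F_t the model CDF at day t (from
predictive draws by default; a deterministic-mean variant is a config
switch), S_t the replicate CDF and ȳ_t the day's mean measurement. The
integral is evaluated exactly over the merged sample breakpoints (both
CDFs are step functions and agree beyond the largest sample, so no
quadrature or truncation is involved); up to the normalizer it is the
1-Wasserstein distance. The same integral between prior and posterior
samples of a parameter, normalized by the prior mean, quantifies how much
a stage moved the parameter ("distribution shift"). Both are reported in
percent.

## Numerics

* ODEs: classical RK4, fixed step, default 0.01 day. Inside the necrosis
  likelihood the stage default is 0.05 day — the error ~(rate·Δt)⁴ is
  ~10⁻⁸ relative for the rates involved, orders of magnitude below the
  noise — with a plain-float inner loop, since it runs tens of thousands
  of times per calibration.
* PDE: 2nd-order central finite differences on a uniform grid, zero-flux
  boundaries by mirrored ghosts (periodic available for test harnesses).
  Time stepping is semi-implicit convex splitting of Ψ = Ψ_c − Ψ_e with
  Ψ_c = (3/2)Ē_T φ² (so the implicit part is linear) and the expansive part
  explicit; the mobility is lagged one step. Each step is one sparse
  direct solve (SuperLU), with the factorization cached while the mobility
  field is unchanged — in particular for the whole mobility stage, where
  φ_N ≡ 0 makes the operator constant per parameter proposal. Residuals
  are checked against a 10⁻⁸ relative tolerance and a failed solve raises
  with step and residual. The face-assembled divergence operator has
  exactly zero row and column sums, so mass is conserved to solver
  precision (measured drift ~10⁻¹⁵ relative), and the splitting makes the
  discrete free energy non-increasing step over step.
* The scheme has no discrete maximum principle: sharp interfaces over- and
  undershoot [0, 1] by up to a few percent, as usual for CH
  discretizations. States are therefore validated against [−δ, 1+δ] with a
  configurable diagnostic tolerance (default 10⁻², 5×10⁻² for the
  clipped-cluster synthetic fields) rather than silently clamped;
  excursions beyond it abort the run.
* Full model: Lie splitting per step — CH transport substep, then a
  pointwise RK4 reaction substep. A spatially uniform state reproduces the
  reduced two-compartment ODE trajectory to the splitting error; with
  sources off the full solver reduces exactly to the mobility-only path.
* The Heaviside necrosis gate is exact, not smoothed: φ_σ is constant per
  scenario, so the gate never switches mid-run.

## Synthetic data generator

The generator emulates the study design: 5 seeding densities (5×10³–10⁵
cells/ml, mapped to φ_V0 = 4.22×10⁻³…8.44×10⁻² by the anchored linear
conversion), Mitomycin-C-treated (proliferation off) vs untreated arms,
serum levels {0, 2.5, 5, 7.5, 10}% mapped to φ_σ ∈ {0, 0.25, 0.5, 0.75, 1},
4 replicates, daily sampling for 7 days (apoptosis, necrosis) or 21 days
(proliferation), and 25-frame/12-hour field series for mobility. Viability
noise is additive Gaussian on the volume-fraction scale with scenario sd =
5% of the day-0 signal; negative draws are floored at zero and flagged per
observation so likelihood-misspecification effects remain traceable.
(A multiplicative-noise option exists but is off by default.) Field series
evolve clustered initial conditions — tanh-profile discs, mirroring the
already-segregated colonies the mobility experiments start from — under
the same CH solver, plus pixelwise Gaussian noise (sd 0.01) and clamping
to [0, 1].

Default truths (λ_apop = 0.09/day, λ_prol = 0.5/day, K = 0.14, λ_VN from
e^−5.5 to e^−2.2 per day across serum levels, M_T = 200 μm/day, Ē_T = 0.65,
ε_T = 30 μm) sit centrally in the parameter ranges typical of liver
carcinoma monolayers; they are fixture choices, not measurements. What the
generator does *not* emulate: fluorescence-to-count conversion error
structure, spatial segmentation artifacts, replicate-level systematic
offsets, photobleaching, or any 3D/matrix effects. Passing recovery tests
therefore demonstrates the inferential machinery is correct and
well-calibrated under the stated noise model, not that the model is
adequate for any particular real dataset.

One deliberate asymmetry avoids a pure inverse crime in the mobility
stage: the generator integrates at Δt = 0.005 day while the calibration
likelihood steps frame-to-frame (Δt = 1/48 day), and the likelihood's
initial condition is the *noisy* observed first frame. Both choices leave
a realistic residual model error; its visible effect is that the
interface-length posterior shifts away from the generating ε_T while M_T
remains covered, echoing the weak identifiability of the energy parameters
over a 12-hour window (the Ē_T posterior is essentially its prior).

## Problem sizes and design choices

Calibration chains default to 4,000–8,000 kept draws after 2,000–5,000
burn-in — with covariance adaptation these give ESS in the hundreds for
the time-course stages, and repeated-study coverage of the 95% intervals
matches the nominal rate in the recovery checks. The Cahn–Hilliard
recovery runs on a 32×32 grid over the 1.16 mm field of view (36 μm
pixels), which resolves the ~100 μm clusters while keeping a four-parameter
MCMC with a PDE solve per likelihood evaluation to about a minute; the
invariants (mass, energy) are checked on 64×64. Finite differences replace
finite elements deliberately: on a uniform rectangular pixel grid they are
equivalent at this accuracy and far easier to verify against closed forms.
Cross-validation holds out one replicate at a time, re-initializes the
predictive ensemble at the held-out replicate's day-0 reading, and scores
with the same L1-CDF metric.

## Known limitations

* The sequential design transfers any bias in an upstream stage into the
  downstream priors; the necrosis rate in particular absorbs error in the
  apoptosis rate through the observed combined decay (their posteriors are
  strongly correlated, which is why the sampler adapts a full covariance).
* The PCC likelihood is invariant to affine rescaling of the model field,
  so the mobility stage cannot constrain parameters that only rescale
  field amplitude.
* One chain per stage: multimodality is handled by the mode-seeking start,
  not by tempering; pathological multimodal posteriors would need multiple
  study repetitions to diagnose (the recovery checks run 10–20).
* No adaptive time stepping, 2D domains only, no nutrient-diffusion
  coupling; the φ_σ field is a prescribed constant per scenario.
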