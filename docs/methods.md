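# Methods

## The model

`lbcreg` trains regression emulators by *interval calibration* instead
of a symmetric discrepancy loss. Two fully connected ReLU networks are
fitted jointly on observations {(x_i, y_i)}:

* a **predictor** f(x; θ) producing point estimates ŷ, and
* an **interval estimator** g(x; φ) producing nonnegative widths
  (δˡ, δᵘ) per response dimension at each confidence level α in a fixed
  grid 𝒜 = [0.1, 0.3, 0.5, 0.7, 0.9, 0.99].

The interval at level α is [ŷ − δˡ, ŷ + δᵘ]. It is *calibrated* when
the fraction of held-out responses it contains equals α. The interval
estimator minimises, at a single randomly drawn α per iteration,

    L_g = |α − coverage| + λ₁·mean|y − (ŷ − δˡ)| + λ₂·mean|(ŷ + δᵘ) − y|,

where coverage is the mean indicator that y lies in the interval and
the λ-terms penalise interval size so the coverage term cannot be
satisfied by arbitrarily wide intervals. The predictor minimises a
weighted two-sided hinge,

    L_f = Σᵢ wᵢ [max(0, (ŷᵢ − δˡᵢ) − yᵢ + γ) + max(0, yᵢ − (ŷᵢ + δᵘᵢ) + γ)],
    wᵢ = (δˡᵢ + δᵘᵢ) / Σⱼ (δˡⱼ + δᵘⱼ),

which pushes every response inside its current interval with margin γ,
spending effort preferentially on samples with wide (uncertain)
intervals. Alternating the two updates solves the bilevel problem: the
predictor improves the point estimates against the current intervals,
the intervals re-calibrate against the current predictor. Because no
residual prior enters anywhere, the fitted pair adapts to skewed,
heteroscedastic, or outlier-contaminated noise; with sign-skewed noise
the calibrated widths become asymmetric (δᵘ ≫ δˡ for right-skewed
noise), which re-centres the predictor's equilibrium near the noise-free
function rather than the noisy conditional mean — the mechanism behind
the R² advantage over ℓ₂ training on asymmetric data. At inference only
f is evaluated, so the deployed model has exactly the parameter count of
the equivalent plain network.

### Why the averaging convention matters

In `calibration_loss` the coverage and both λ-penalties are means over
all samples *and* response dimensions. This makes the loss invariant to
batch size and response dimensionality, so λ₁ = λ₂ = 0.05 means the
same thing for every dataset. Coverage for multivariate responses is
likewise accounted per dimension (the joint box is not required to
contain the whole vector), matching the per-dimension interval heads.

### The smooth indicator

The coverage indicator 1[·] has zero gradient almost everywhere, so
gradient steps for g use the surrogate
σ(t·(y − lower)) · σ(t·(upper − y)) with temperature t (default 50 on
the [0,1] response scale). It converges pointwise to the hard indicator
away from the endpoints; every *reported* coverage uses the hard
indicator. The size penalties are exact subgradients.

## Defaults and their provenance

| parameter | default | meaning |
|---|---|---|
| 𝒜 | 0.1, 0.3, 0.5, 0.7, 0.9, 0.99 | confidence grid; one α drawn per iteration |
| λ₁, λ₂ | 0.05 | interval-size penalties (normalised response scale) |
| γ | 0.05 | hinge margin (normalised response scale) |
| lr predictor / interval | 1e−5 / 1e−4 | Adam learning rates |
| batch size | 8 | mini-batch for both networks |
| schedule | (2, 1) | predictor epochs : interval epochs per outer iteration |
| outer iterations | 1000 | alternation rounds |
| split | disjoint_halves | each network trains on its own 50% of the rows |
| temperature | 50 | smooth-indicator sharpness |

Responses (and features) are min-max scaled to [0, 1] per dimension
before training, because γ and λ are absolute thresholds and are only
meaningful on a fixed scale; the normalisation state is stored in the
trained emulator and all predictions are returned in original units.
One integer seed drives initialisation, splitting, batching, α draws
and dropout.

Architecture follows the sample-size rule: hidden layers
[64, 128, 512, 256, 32] for n ≥ 5000, [64, 256, 32] otherwise, ReLU
throughout; the interval network ends in a softplus so widths are
nonnegative by construction. `hidden_widths` overrides the rule — the
1D illustration experiments use a single hidden layer of 100 units (see
below).

### Convergence controls (package additions)

Three optional controls stabilise desk-scale runs; none alters the
objective:

* **Validation monitoring** (`monitor_validation` /
  `early_stopping_patience`): a 10% carve-out of the training rows is
  scored every `eval_every` iterations and the best iterate (both
  networks jointly) is restored at the end; with a patience the run
  also stops early. Selection uses the validation *MAE*, not RMSE:
  under the skewed noise this method targets, RMSE selection favours
  mean-biased iterates and would erase exactly the robustness the
  hinge objective buys.
* **Final interval refinement** (`final_interval_iterations`): after
  the alternation, the predictor is frozen and the interval network
  runs extra epochs cycling deterministically through every α, so all
  heads settle against the final predictor. The alternation leaves the
  heads adapted to whichever α was drawn last; this phase removes that
  artefact.
* **`lr_schedule="cosine"`** anneals the predictor learning rate to 10%
  across the run. Hinge gradients do not shrink near an optimum the way
  squared-error gradients do, so without annealing the predictor
  orbits its optimum at a radius set by the learning rate. Off by
  default; the interval network always keeps its full rate so it can
  track the predictor.

## Synthetic benchmarks

The generator draws x ~ U[0, 1] and observes the fixed function
f(x) = x + 0.3·sin(2πx) + 0.2·sin(7πx) (f(0)=0, f(1)=1, smooth with a
low- and a high-frequency component) under noise
n = sign · magnitude:

* **magnitude** ~ Exponential(base_scale), default base_scale 0.1, or
  half-normal. The exponential default is deliberate: for a signed
  mixture the skewness sign must track the majority sign, and the
  exponential family (the boundary case μ₃ = 3μ₁μ₂) is the lightest
  simple family for which it does at every fraction. A signed
  half-normal mixture has its third moment *flipped* by the mean shift
  (skew −0.25 at positive fraction 0.9), which would invert every
  skew-direction experiment.
* **sign** is +1 with probability `positive_fraction` (0.5 = symmetric,
  matching the "percentage of positive noise components"
  parameterisation of the asymmetry experiments).
* **heteroscedasticity**: scale(x) = base_scale · (1 + hetero_slope·x),
  default slope 0 (homoscedastic).
* **outliers**: a `round(outlier_fraction·n)` subset (default 0; 0.05
  when enabled) has magnitudes inflated by `outlier_scale` (default 5).

Noise-free values are stored alongside, so benchmarks can score recovery
of the true function; responses − clean_responses reproduces the
injected noise bit-for-bit.

What this generator does *not* emulate: covariate-dependent skewness,
multivariate responses, input noise, and distribution shift between
train and test. Passing benchmarks here demonstrates the loss-function
mechanism, not performance on any particular real dataset.

### The 1D experiment operating point

The 1D experiments use a single hidden layer of 100 ReLU units for every
network — small 1D problems neither need nor stably train the deep
stacks of the tabular regime. Learning rates for this regime were chosen
on the *symmetric*-noise case for each method independently (the point
where neither method has a structural advantage): 1e−3 for the
predictor and the ℓ₂ baseline, 1e−4 for the interval estimator, with
shared-data mode, 800 outer iterations, validation monitoring, and 60
final interval-refinement epochs (`lbcreg.evaluation.SYNTH_1D_LBC /
SYNTH_1D_DNN`). The asymmetry benchmark averages three seeded
replicates per noise fraction with a 50% held-out split: a single
training run of either method carries sampling noise of the same order
as the effects being measured (the skewness estimator of a two-sided
exponential sample of 1000 points has a standard error near 0.2).

## Baselines

Identical-architecture networks trained with ℓ₂ or Huber loss
(transition threshold 1.0 on the normalised scale), Adam at 1e−4 with
batch 8 and early stopping by default; an MC-dropout variant (dropout
after every hidden layer, rate τ = 0.3 at inference, predictions
averaged over T = 20 seeded stochastic passes); random forests and
gradient-boosted trees with 100 trees under squared error via
scikit-learn, fitted on raw (unscaled) data since trees are
scale-invariant. All baselines expose the same `predict` surface and
are addressable by name (`lbc`, `dnn_l2`, `dnn_huber`, `dnn_dropout`,
`rf`, `gbt`) in the cross-validation harness.

## Evaluation

RMSE is computed over all entries; R² per response dimension
(1 − SS_res/SS_tot) then averaged; residual skewness is the biased
Fisher–Pearson moment coefficient m₃/m₂^{3/2} (no small-sample
correction, so tests are exact); empirical coverage uses the hard
indicator with boundaries counting as inside. The cross-validation
harness runs k folds (default 5) under several shuffling seeds (default
3, 15 runs total) and reports means ± standard deviations across all
runs; min-max statistics are always computed on the training folds only
and applied to the held-out fold. Fold assignment depends only on
(n, k, seed), so methods evaluated with the same seeds see identical
splits and are compared paired. Synthetic benchmarks score R² against
the noise-free targets, since the question there is recovery of the
true function, while residual skewness is computed against the noisy
observations.

## Numerical choices and degenerate inputs

* Interval widths are kept nonnegative by a softplus output layer, not
  by clipping, so gradients exist everywhere.
* All-zero interval widths make the hinge weights undefined; uniform
  weights are substituted with a warning.
* Constant feature columns are dropped with a warning before
  normalisation; a constant response dimension is an error for
  networks (the inverse map is undefined) while tree ensembles, fitted
  on raw data, handle it naturally.
* Leave-one-out folds have undefined R²; such folds record NaN and the
  aggregation skips them.
* Non-finite losses abort training with a diagnostic rather than
  continuing silently.
* Hinge subgradients use the strict-inequality convention (gradient 0
  exactly at the kink); the |α − coverage| term uses sign(coverage − α)
  with sign(0) = 0.

## Known limitations

* The batch-size-8 coverage term quantises: within a mini-batch the
  empirical coverage moves in steps of 1/(8·m), which biases the
  extreme heads (α = 0.1 and 0.99) toward under-coverage; the low head
  often sits near zero width. The mean absolute calibration error
  stays well inside 0.10 in the shipped configurations, but per-level
  tails are the weak point.
* Intervals at different confidence levels are independent heads with
  no nesting constraint; crossing between adjacent levels can occur.
* The predictor's accuracy floor is set by the hinge dead zone (±γ
  after interval shrinkage) and the terminal learning rate; on
  noise-free data R² > 0.99 needs a reduced γ or the cosine schedule.
* Training is plain-numpy on CPU and is sized for thousands of samples,
  not the 10⁵⁺ regime.
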