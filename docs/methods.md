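# Methods

## Reaction-time model

Correct-commission RTs are modelled as ex-Gaussian: RT = G + E with
G ~ Normal(μ, σ²) and E ~ Exp(τ) independent, giving mean μ + τ and variance
σ² + τ². The density is evaluated in the log domain through the scaled
complementary error function,

    log f(x) = −log τ − z²/2 + log(½ erfcx(u)),   z = (x−μ)/σ,  u = (σ/τ − z)/√2,

switching for u < 0 (deep right tail, where erfcx overflows) to the
equivalent form u² + log Φ(−u√2). The naive closed form
exp(σ²/2τ² − (x−μ)/τ)Φ(·) overflows for small τ; this formulation does not.

**Fitting.** Maximum likelihood over (μ, log σ, log τ) with L-BFGS-B and the
analytic score (the Mills-ratio term φ(w)/Φ(w) is computed via `log_ndtr`
so it stays finite at w ≪ 0). Start values come from moment matching
(τ₀ = (skew/2)^{1/3}·sd, σ₀² = max(var − τ₀², (0.1 sd)²), μ₀ = mean − τ₀);
box bounds keep the optimizer inside a numerically sane region (μ within
the data range ± 2 spans; σ, τ within [10⁻⁴, 10] × span). A fitting unit
needs at least `min_trials = 10` RTs with nonzero spread; anything less
raises `InsufficientDataError` rather than returning a silently meaningless
triple — three parameters from a handful of trials is noise.

**Negative skew.** The ex-Gaussian assumes a right tail. In the cross-fading
task a very slow response to trial n is recorded as a very fast response to
trial n+1, so some units' RT distributions skew left. Two policies:
`flip` fits −RT and reports (−μ_fit, σ, τ) with `flipped=True`; `exclude`
flags the unit. The skewness estimator is the bias-corrected (adjusted
Fisher-Pearson) sample skewness with the flip/exclude decision at exactly 0.
For the state comparison the exclusion decision is made **per participant**
on the combined across-state pool, not per state pool: excluding whole
participants is what keeps the paired design interpretable, and a
participant's skew is a property of their response mechanics, not of one
brain state. (Per-pool exclusion was tried and discards 2–3× more
participants for no gain in null calibration.)

**Goodness of fit.** R² compares the empirical histogram against a histogram
of `sim_n = max(10 n, 10⁴)` draws from the fitted distribution on shared
Freedman–Diaconis bins (computed from the data), as densities;
R² = 1 − SS_res/SS_tot. The comparison direction (ex-Gaussian vs a
plain-Gaussian fit of the same data) is reliable from τ/σ ≈ 1 upward at
n = 500; near τ/σ ≈ 0.5 the third parameter's estimation noise roughly
offsets the small Gaussian misfit and the direction approaches chance —
a statistical fact about the estimator, not a defect of either fit.

**Reliability.** Split-half reliability of a parameter across participants
is the Spearman–Brown corrected correlation 2r/(1+r) between per-half
estimates; each half is fitted (and flip-handled) independently.

## Press assignment

RT is measured from the onset of the transition to the current image; at
RT = isi the image is 100% coherent; the coherence split is linear in RT.
A press is adjacent to the two trials whose full-coherence moments bracket
it. It is *unambiguous* for a trial when its RT there lies in
[0.7·isi, 1.4·isi] — between 70% coherence of that scene and 40% coherence
of the next — with closed endpoints, which makes the canonical 720 ms
example at isi = 0.8 unambiguous. Assignment runs in three passes:
unambiguous presses lock to their trial (fastest per trial wins; surplus
presses rejoin the pool, which is how multiple-press trials are resolved);
remaining presses go to the adjacent trial without a response, or, when
both are free, to the closest full-coherence moment (ties to the earlier
trial), except that a free no-go neighbour keeps the benefit of the doubt;
the pass iterates to a fixed point (capped at the press count) because an
assignment can resolve a neighbour's ambiguity. At a run boundary, an
ambiguous press whose only existing neighbour is a free no-go is likewise
left unassigned.

These rules are greedy. A brute-force oracle (same validity rules,
exhaustive search, used in the tests) finds instances — roughly 15% of
adversarial random toy streams, far denser in ambiguity than real data —
where pressing a lone free no-go is forced by the "exactly one neighbour
free" rule while the global maximum would spare it. The implementation
follows the stated rules and logs every such shortfall through the module
logger instead of silently deviating.

A run is flagged for "tune-out" exclusion when any gap between consecutive
assigned presses (or against the run boundaries) reaches 30 s (closed
bound).

## Maximum-entropy model and energy landscape

Per-network activity is cleaned (OLS residualization against a
caller-supplied confound matrix plus intercept; rank-deficient confounds
fall back to the pseudo-inverse with a warning), standardized to zero mean
and unit variance per run, averaged within networks, and binarized at the
time-mean of the concatenated series (strictly-above → 1, ties → 0).

With ⟨σᵢ⟩ and ⟨σᵢσⱼ⟩ the empirical first and second moments, the model
P(V) ∝ exp(−E(V)) is fitted by gradient ascent on the exponential-family
log-likelihood: h ← h + η(⟨σ⟩_emp − ⟨σ⟩_model), likewise for J, with model
moments from exhaustive enumeration of the 2^N patterns (N ≤ 16; O(N²·2^N)
per step, trivial at N = 8). Defaults: η = 0.2, tolerance 10⁻⁵ on the
largest absolute moment mismatch, h = J = 0 start, 10⁵ iteration cap.
The log-likelihood trace is optionally recorded and is non-decreasing at
this step size. Empirical moments at the 0/1 boundary (a network always
on/off) are clamped to [ε, 1−ε], ε = 1/(2T), with a warning. The sign
convention is the physical one — lower energy, higher probability — so the
landscape's minima are the dominant patterns. Fit quality is the Pearson
correlation between model pattern probabilities and empirical appearance
frequencies (1-of-K counts); it is NaN-with-a-warning when either side has
zero variance.

Pattern index k encodes network i's activity in bit i. A pattern is a local
minimum iff its energy is strictly below all N Hamming-1 neighbours (ties
break *against* minimality); basins are steepest descent, moving to the
lowest-energy strictly-lower neighbour, ties to the lowest pattern index.
Both are checked against literal-definition brute force in the tests.

State labels are shifted backwards by round(lag/tr) volumes (exact halves
round down: 5 s at TR = 2 s → 2 volumes; at TR = 1.08 s → 5 volumes); the
shift is applied within each run. Trials map to the volume whose [v·tr,
(v+1)·tr) interval contains their onset; trials past the labelled span are
dropped and counted, never imputed. Minima are named by their active set:
a strict majority of {FPN_A, DMN, Limbic} active with a strict majority of
{FPN_B, DAN, SN, SMN, Visual} inactive is State1; the mirror condition is
State2; everything else "other".

## State comparison

Per participant and state, ex-Gaussians are fitted to the
correct-commission pools (≥ 10 trials each); participants failing either
pool, or negatively skewed overall (under the `exclude` policy), are
excluded from all three parameter comparisons jointly, keeping the design
balanced. Each parameter gets a two-tailed paired t-test (df = n − 1;
identical vectors yield t = 0, p = 1 rather than 0/0) and Hedges'
g = J(df)·(m₁ − m₂)/s_pooled with the small-sample correction
J(df) = 1 − 3/(4df − 1), df = n₁ + n₂ − 2 — the pooled-SD standardizer, not
the paired d_z, so effect sizes are comparable across designs regardless of
the within-pair correlation. No multiple-comparison correction is applied
across the three parameters; replication across independent synthetic
datasets is the intended check. Spearman correlations use average ranks;
the multiple regression of error counts on (μ, σ, τ) reports raw and
standardized coefficients, per-coefficient t/p, R² and F. Mind-wandering
probe means must lie in [0, 100].

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth recorded at every stage:

* **Trial streams** — 90/10 city/mountain, scene identities uniform over
  10 ids per category with immediate repeats rejected, onsets at k·isi.
* **Network activity** — a lazy single-flip Metropolis chain over pattern
  space with stationary law P ∝ exp(−E), recording every `dwell_control`-th
  state (default 8: states persist a few volumes, as real state sequences
  do; large values approach independent draws). The laziness (stay
  probability 1/(N+1)) removes the bit-flip parity periodicity that would
  otherwise make the zero-energy chain non-ergodic on the recorded
  subsequence. A continuous BOLD-like observation adds ±1 offsets with
  N(0,1) noise, chosen so time-mean binarization recovers the binary truth
  with high probability. Exact independent sampling (enumeration +
  categorical draw) is also provided and is what the recovery tests use.
* **Planted two-state world** — a Hopfield-style spin model storing the
  State1 pattern (coupling depth 0.55, converted to the 0/1 convention)
  whose only two minima are State1 and its complement, symmetric in energy;
  basin occupancies are ≈ 0.59/0.41 because the 3-active and 5-active
  minima have differently sized basins.
* **Behaviour** — each trial's generating state is the label of volume
  floor(onset/tr) + round(lag/tr), i.e. the exact volume the pipeline will
  consult after its backward hemodynamic shift, so generator → pipeline
  round trips are exact in a clean world. City trials press with
  probability 1 − omission_rate(state) at onset + RT (state's ex-Gaussian,
  untruncated: draws beyond 1.4·isi naturally become next-trial fast
  presses, reproducing the task's slow-to-fast leakage); mountains press
  with probability commission_rate(state). Optional dials displace presses
  into the ambiguous window or duplicate them (multiple-press trials).
* **Populations** — μ truncated-normal, σ and τ lognormal with matched
  mean/SD; error rates are logistic functions of σ's Gaussian latent with
  `error_link` interpreted as the planted *Spearman* correlation
  (converted via ρ = 2 sin(π ρ_s/6)).

What the generator does **not** emulate: voxel-level imaging, head motion,
physiological noise structure, serial RT dependence beyond the state
process, learning/fatigue trends, or anticipatory presses as a separate
class. A green end-to-end test therefore establishes that the chain
recovers what it assumes — planted states, planted parameter differences,
planted correlations — not that real fMRI meets those assumptions.

## Pipeline defaults

25 participants × 1 run × 300 trials, isi 0.8 s, TR 2 s, lag 5 s,
dwell 8, planted depth 0.55, State1 (μ, σ, τ) = (0.80, 0.08, 0.05) s
(typical positive-skew gradCPT values), State2 σ = 0.12 (the 1.5× variance
factor), equal μ and τ, omission/commission rates 0.05/0.30, press
displacement dials at 0.01. One config seed is split hierarchically
(SeedSequence spawns per participant and run), so reruns are byte-identical
and any participant can be regenerated in isolation.

## Known limitations

* The greedy press assignment can fall short of the global
  correct-response maximum on dense ambiguity (logged, see above).
* The σ/τ decomposition degrades near τ → 0; fit-comparison direction is
  near chance at τ/σ ≈ 0.5 with n = 500 trials.
* Displaced-press contamination biases μ slightly downward in the
  higher-σ state's pool (the slow-tail leakage is state-asymmetric); at
  the default dial settings the μ false-rejection rate in a null world is
  ~5–8% rather than exactly 5%.
* The maximum-entropy machinery enumerates 2^N patterns and is intended
  for N ≤ 16.
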