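# Methods

`spikelapse` reimplements, end to end, an analysis of interictal spikes
(IS) recorded from hippocampus while mice perform a delayed spatial
alternation task, together with the spiking-network model used to
interpret how the spatial pattern of IS affects offline replay.  Every
stage can be exercised on synthetic data produced by the package itself;
this note describes the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## IS detection and taxonomy (`is_detection`)

A single LFP channel is polarity-oriented by the sign of its sample
skewness (IS are large one-sided deflections, so the heavy tail marks
their direction), down-sampled to 1 kHz by polyphase resampling,
band-pass filtered with a zero-phase order-3 Butterworth (applied
forward-backward so peak times are unbiased), and local maxima with
topographic prominence above a threshold are taken as IS times.

The detector is scored against hand-label-style windows: a window with at
least one detection counts one true positive; each additional detection
inside a window, and every detection outside all windows, is a false
positive; an empty window is a false negative.  The tuning objective is

    F_beta = (1 + beta^2) P R / (beta^2 P + R),  beta = 1/2,

which weights precision roughly twice as much as recall — appropriate
when false events contaminate downstream waveform and rate analyses more
than missed events do.  Tuning is an exhaustive grid search (thresholds
500–2500 uV step 100; low edge {1, 2, 4, 8, 16} Hz; high edge {200, 400}
Hz, spanning the per-animal settings that detector tuning typically
lands on); ties break toward the higher threshold, then the narrower
band.  The band-pass and peak-prominence computation is shared across
thresholds within a band, so the search is linear in the number of bands.

Taxonomy: maximal runs of inter-spike intervals under 2 s with at least
two spikes are BIRDs (brief rhythmic interictal discharges) with
first/within/last labels; everything else is solitary; a sub-2 s-ISI
train lasting 10 s or more is a seizure.  Per-event rms amplitude is
computed over ±100 ms of the raw oriented trace — the same window the
decoding stage extracts — so amplitude and waveform statistics describe
the same snippet.

## Maze zones and trials (`maze_zones`)

The figure-8 maze (default 80 × 90 cm) is represented by axis-aligned
zone rectangles: delay (40 cm of the central arm), a 15 × 15 cm
stem/choice box, 15 × 25 cm reward boxes, and outer arms (top corridor
plus descending side corridors).  Points outside every rectangle are
"none" (return corridors and the mid-stem gap are deliberately
unassigned, as the zone statistics use only the four named classes).
Trials are parsed from the sequence of zone entries (delay → … →
reward); correctness follows the alternation rule, with the first trial
of a session counted correct because alternation is undefined without a
prior choice.  Delay exit latency is the time from the end of the
imposed 30 s delay interval to the delay-zone exit.

## Spatial statistics (`spatial_stats`)

The pooled IS train is treated as if emitted by a single place cell: the
maze is binned 15 × 15, per-bin rates are raw counts over occupancy
seconds (no smoothing), and the Skaggs information rate

    I = sum_i lambda_i P(x_i) log2(lambda_i / r),   r = sum_i lambda_i P(x_i)

is summed over occupied bins with 0·log 0 := 0; I_spike = I / r is in
bits per spike.  BIRD path length is the summed Euclidean distance along
successive spike positions (spikes take the nearest tracked sample).

Two session-level regressions follow.  I_spike against mean BIRD path
length is a Gamma GLMM with reciprocal link and a random intercept per
animal, fit by maximum likelihood with the random effect integrated out
by 25-node Gauss–Hermite quadrature (Nelder–Mead then BFGS polish,
1e-8 objective tolerance; standard errors from the numerical Hessian).
With only a handful of animals the ML variance component can collapse to
zero — that is a property of ML at small group counts, not a defect.
Performance against I_spike is an ordinary fixed-effects Gaussian
regression with dispersion estimated from the data (statsmodels OLS).

## Hierarchical Bayesian rate models (`bayes_models`)

Both rate models are Poisson with a multiplicative gain structure:

* zone model: S[a,z] ~ Poisson(T[a,z] · rho_a · eta_z), with priors
  rho_a ~ LogNormal(−1, 0.3) and eta_z ~ LogNormal(0, 1);
* state model: S_i ~ Poisson(T_i · rho_a(i) · Σ_s eta_s p(s_i = s)),
  with the per-trial state marginals p(s_i) fixed inputs, a
  zero-truncated Normal(0.5, 0.5) prior on rho (the printed
  max(Normal, 0) form has an atom at zero; truncation keeps the density
  proper), and LogNormal(0, 1) gains.

A gain of 1 is the neutral value.  The likelihood is exactly invariant
under rho → c·rho, eta → eta/c, so the scale along that ridge is
identified only by the priors; inferences about gain *ratios* and about
whether a gain differs from its peers are data driven, but the absolute
split between baseline and gain inherits the prior's preference.  The
package's calibration test draws truth from the priors and confirms
~95% HPD coverage; planting a fixed truth whose baseline sits away from
the prior median shifts the whole ridge and the marginal intervals with
it, which is expected Bayesian behavior rather than a sampler defect.

Sampling is Hamiltonian Monte Carlo in unconstrained log space (the
log-normal priors become Gaussian there, and both models have
closed-form gradients, verified against finite differences): 20-step
leapfrog trajectories with ±20% step jitter, dual-averaged step size
toward a 65% acceptance target, and a dense metric estimated from the
warmup draws at mid-warmup.  Defaults follow the 4 chains × 1,000
iterations (500 warmup) schedule; split R-hat and bulk ESS are computed
with ArviZ and attached to every fit (R-hat < 1.01 and ESS > 400 on all
well-specified fits in the suite).  HPD intervals use the shortest
sorted-sample window; when an interval excludes the null, the tail mass
at which a widened interval first reaches the null is found by bisection
to 1e-3.  Posterior predictive checks replicate counts from posterior
draws; model comparison uses AIC with the plug-in log-likelihood at the
posterior mean and k = number of free parameters, against a "clamped"
variant with all gains fixed at 1.

## Behavioral-state HMM (`behavior_hmm`)

Per-trial correctness is a Bernoulli emission of a latent engagement
state evolving as a Markov chain; sessions restart from the initial
distribution.  Initialization: transition matrix (I + εJ)/(1 + Nε) with
ε = 0.5 (the sticky row-stochastic form; diag 0.6 / off-diag 0.2 at
N = 3), uniform initial distribution, emissions at N uniformly spaced
values in [0.1, 0.9].  Fitting is Baum–Welch over the concatenated
multi-session data with scaled forward–backward recursions, stopping at
1e-6 relative log-likelihood change (monotonicity asserted every
iteration).  That stopping rule is part of the procedure's behavior: at
a few thousand trials the exact ML optimum lies on a near-flat ridge
where the middle and top states partially merge (the top emission can
drift several points upward for a ~4-nat likelihood gain), while the
prescribed tolerance stops in the basin that matches the generating
states.  Viterbi decoding breaks ties toward the lower state index;
forward–backward marginals feed the state-rate model above.  The
hierarchical bootstrap stratifies trials by state, repeatedly samples an
animal with probability proportional to its trial count in that state
and then one of its trials uniformly, and reports the mean and 95%
percentile interval over 1,000 replicate means.  N = 2 is available as a
config option; N = 3 is the default.

## Waveform decoding (`lfp_decoding`)

Each IS contributes the ±100 ms of LFP around its detection time,
down-sampled to 2 kHz (401 samples, inclusive endpoints) and z-scored
per waveform.  Waveforms are embedded into 2-D with t-SNE at default
parameters (fixed, recorded seed; coordinates are not asserted across
library versions — only the separability property is).  A bagging
ensemble of 100 unpruned decision trees with stratified five-fold
cross-validation classifies reward-zone membership; out-of-fold scores
are pooled into a single ROC (pooling is more stable than averaging
per-fold AUCs at these event counts).  Decodability (AUC) is regressed
against mean task performance by OLS, reporting the F statistic against
the constant model.  Amplitude comparisons divide each animal's
per-event rms by that animal's rms standard deviation before unpaired
t-tests (reward vs non-reward; correct vs incorrect within reward).

## Replay simulator (`replay_sim`)

**Exploration.** A virtual mouse runs at 35 cm/s along two 150 cm arms
from the midpoint, teleporting back and alternating arms with 90%
probability.  In CA3 and CA1, 30% of pyramidal cells are place cells
(centers uniform over the track, sigma = 7 cm, lambda_max = 20 Hz,
theta = 7 Hz with phase precession via the (pi/sigma)·sign(x_i)(x − x_i)
phase term); the rest fire at 0.1 Hz.  Pyramidal spiking is clamped to
these inhomogeneous Poisson rates during training.

**IS input.** A single train is drawn from a location-locked rate
profile (2,000 Hz peak, sigma 4 cm) and each eligible CA3 cell receives
each spike with probability 0.01.  Three regimes: `epileptic` broadcasts
to all CA3 pyramidal cells (the pathological case used for spontaneous-
dynamics comparisons); `clustered` (high spatial information) and
`dispersed` (low spatial information) restrict delivery to place cells
currently at ≥10% of their peak spatial envelope, with the IS location
fixed at ±100 cm or drawn uniformly along the traversed arm per trial —
the pair used for the cue comparisons.

**Plasticity.** Trace-based all-pairs STDP on normalized weights
clipped to [0,1] after every update: CA3→CA3 symmetric (step 0.08,
tau 62.5 ms both lags), CA3→CA1 asymmetric (step 0.8, tau+ 20 ms,
tau− 40 ms, depression factor 0.4), w_max = 40 nS.  Initial weights are
log-normal at the nS scale (0.3 nS CA3, 0.7 nS CA1 medians), i.e. a few
per mil of w_max: after training, a weak random background plus strong
potentiated synapses between cells with overlapping fields.  The strong
chains are what replay propagates along.

**Offline network.** AELIF neurons (separate pyramidal/interneuron
parameter sets, including the near-threshold pyramidal reset that makes
population events burst-like), bi-exponential conductance synapses
normalized to unit peak per event, 1 ms delays, forward Euler at 0.1 ms
with refractory clamping (spike counts change <5% at dt 0.01 ms on the
step-size benchmark).  Dentate background drives CA3 with an
independent 12 Hz Poisson realization per connected cell at 15 nS
(10 nS during cueing); independent realizations matter because burst
ignition requires chance EPSP summation within single cells.  Feedback
inhibition (interneuron→pyramidal) carries the strong 5 nS GABA weight
and interneuron→interneuron the weak 0.65 nS one; with the weights the
other way around the network is bistable between silence and permanent
runaway and never produces the discrete self-terminating bursts the
model exists to study.  Cues deliver independent 30 Hz/20 ms Poisson
bursts at 80 nS to place cells within a 20 cm window of the cue center
(independent per target; a single shared 30 Hz train would be empty 55%
of the time).  The LFP proxy is the summed synaptic current onto 200
random CA1 pyramidal cells scaled by 1/(4·pi·sigma_ext·r)
(sigma_ext = 0.3 S/m, r = 5 um), sampled at 1 kHz.

**Analysis.** Replays are prominences ≥1 mV at ≥200-sample separation on
the 200 Hz low-passed (7th-order zero-phase Butterworth) proxy, with
±150 ms windows.  Position is decoded per 25 ms bin by the population
vector (the field center with the most spikes; ties toward smaller
|x|).  Contamination counts place-cell spikes whose centers lie on the
un-cued arm within the replay window.  Spectra: Welch PSD (256-sample
segments, 32 overlap, 1,024 FFT points) and a complex Morlet wavelet
map (bandwidth 1.5, center frequency 1.0) at 200 log-spaced bands in
[10^1.2, 10^2.5] Hz on the mean replay waveform; the reported spectral
peak is the frequency of maximum mean wavelet power in that band.

**Desk scaling.** Tests and comparisons run at 25% population size (312
pyramidal + 25 interneurons per region) with connection probabilities
divided by the scale factor (capped at 1) so each neuron keeps its
full-size in-degree at the printed per-synapse conductances.  This
preserves both the mean synaptic input and — critically — the
connectivity of the learned place-field chains, which stop percolating
if probabilities are held fixed and weights compensated instead (that
variant remains available as `scale_mode="weight"`).  Training runs are
120 s with 5 s spontaneous probes and 1 s cued probes; comparisons pool
10 seeds per condition (2 trained networks × 5 offline seeds for the cue
sweep).

## The synthetic-data generator (`synthetic_data`)

LFP = 1/f^1 spectrally shaped noise (150 uV rms default) + theta
sinusoid (7 Hz, 100 uV) + one biexponential transient per event (2 ms
rise, 15 ms decay, 1,500 uV peak; the IS-to-noise ratio is a free
setting because the source analyses never report an amplitude
distribution against the noise floor).  Trajectories are generated
directly on the zone skeleton at 30 Hz and 20 cm/s with optional
Gaussian jitter — the analyses consume zones, not pixels, so no video
tracking noise model is attempted.  Choice outcomes come from a sticky
3-state ground-truth HMM (diagonal 0.92, emissions 19/53/75%); delay
exit latencies are state dependent (means 12.0 / 7.85 / 7.6 s by rising
success rate, sd 1 s), matching the reported inverse relation between
exit time and success probability.  IS event times are a thinned
non-homogeneous Poisson process at 0.5 Hz baseline with zone gains
(delay 1.0, choice 1.0, outer arm 1.35, reward 1.9 — inside the
reported credible intervals).  Label-window widths are truncated
log-normal solved so the [14, 724] ms truncated distribution has mean
100 ms and sd 92 ms; each window contains its event and overlapping
windows are clipped at the midpoint between their events.

What passing on this synthetic data shows: that each estimator recovers
the structure its own generative assumptions describe, at realistic
sizes and rates.  What it does not show: robustness to tracking
artifacts, electrode drift, non-Poisson IS clustering beyond the BIRD
structure, or waveform families richer than the single biexponential
shape.

## Known limitations

* Single-channel detection only; no laminar or multi-channel logic.
* The zone-gain model's absolute baseline/gain split is prior-dependent
  along the exact scale degeneracy (see above).
* Replay simulations are desk-scale; full-size defaults are provided but
  the comparisons in the suite are run at 25%.
* The behavioral-state HMM is a plain Bernoulli HMM; no covariate-
  dependent transitions.
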