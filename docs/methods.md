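# Methods

This note records the models implemented in `robustbmi`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## The MRNN decoder

The decoder is a continuous-time rate network of `N` units with state
`x`, rates `r = tanh(x)`, and an `M=2`-dimensional linear readout
`z = W_o r + b_z`. Unlike a standard RNN, the binned spike-count input
`u` (E electrodes, raw integer counts per Δt bin) does not enter
additively: it reparameterizes the recurrent weight matrix each bin
through a factorization with `F` multiplicative factors,

    J^u r = J_xf [ (J_fu u) ⊙ (J_fx r) ],

which is the full input-conditioned weight tensor `J_xf diag(J_fu u) J_fx`
computed without ever materializing it. `F` controls the complexity of
the input–state interaction; `F = N` by default. Dynamics are leaky:

    x ← (1 − Δt/τ) x + (Δt/τ) (J^u r + b_x),

a first-order Euler discretization; τ (default 100 ms) sets the output
smoothness and Δt (default 20 ms; 25–30 ms supported) is the count bin
width. Two networks are trained independently — one reads out normalized
2D position, one normalized velocity — and share a normalization: each
kinematic dimension is scaled by its maximum absolute value over the
training corpus (so targets lie in [−1, 1] and the inverse factors
γ_p, γ_v convert decoder output back to cm and cm/s). Velocity training
targets are central differences of position (one-sided at trial ends).

**Initialization.** The three factor matrices are Gaussian with variance
`g/fan-in` (g = 1): `g_xf/F`, `g_fu/E`, `g_fx/N`; `W_o`, `b_x`, `b_z`
start at zero.

**A note on initial states.** With `W_o = b_x = 0` and a zero initial
state, the multiplicative recurrence is exactly zero (`r ≡ 0` is
self-perpetuating) and no gradient reaches any weight except `b_z` — the
initialization sits on a saddle. Training therefore starts every
forward pass from a random hidden state (Gaussian, sd 0.5), drawn
afresh per sequence and per optimizer iteration. This does double duty:
it breaks the saddle, and it trains the network to converge from *any*
state — essential in closed-loop use, where the persistent hidden state
visits regions far from anything a fixed-initial-state network has
learned to recover from. The two-trial seed span (below) absorbs the
transient before any error is scored; held-out snapshot selection,
evaluation and closed-loop use all start from the deployment zero
state, which the trained network (nonzero `b_x`) leaves immediately.

## Training

**Sequences.** Five consecutive reaches of one day are concatenated into
one training sequence; the first two seed the hidden state (no error),
the last three are scored. Windows slide by one trial, so a day of n
trials yields n − 4 sequences and every trial past the first two is
learned from.

**Loss and optimizer.** Mean squared error between readout and
normalized kinematics over learn-span bins. Hessian-free optimization:
exact BPTT gradients; Gauss–Newton curvature applied matrix-free (an
R-op forward pass followed by the adjoint pass); conjugate gradient on
the damped system (G + λI)δ = −∇L; λ adapted by the Levenberg–Marquardt
reduction ratio (×1.5 / ÷1.5, start 0.1). Gradient and curvature are
both computed on the per-step minibatch; each minibatch draws from
*every* training day (≥ 1 sequence per day, about `minibatch_fraction`
of all sequences). Snapshots are taken every `snapshot_interval` steps
and the snapshot with the lowest held-out loss is returned; the held-out
set is the last 10 % of each day's sequences. Full-scale defaults follow
the reference configuration (200 steps, ≤ 50 CG iterations, minibatch
1/5); the desk-scale experiments below use 25–55 steps, 12 CG
iterations, and minibatch fractions of 0.05–0.1 so a full protocol runs
in minutes on one CPU.

**Augmentation.** At every optimizer step, each sampled sequence is
re-perturbed: a per-sequence gain η_trial ~ N(1, 0.045) and a
per-electrode gain η_c ~ N(1, 0.3) set a target total
n̂ = round(η_trial η_c n) for each electrode's spike count n, resampled
while n̂ ∉ [0, 2n] (which preserves the mean); surplus spikes are added
to uniformly random bins, deficits removed from random existing spikes.
This trains robustness to global modulation and per-electrode gain and
baseline changes. Perturbations are train-time only.

## The FIT Kalman filter

State z = [p_x, p_y, v_x, v_y, 1] with linear dynamics z' = Az + w,
observations y = Cz + q (y = binned counts). Velocity rows of A (and the
velocity block of W) are least-squares fits on consecutive state pairs
against [v_x, v_y, 1]; position rows are pinned to kinematic integration
p ← p + vΔt; C and Q regress counts on the full state (Q diagonally
loaded by 1e−6 so it stays invertible when electrodes outnumber bins).
Before fitting, training velocities are rotated to point from the cursor
at the target (magnitude preserved; zeroed inside the 4 × 4 cm
acceptance window) — the "intention" assumption. At decode time the
user's visual knowledge of the cursor is modelled by pinning the position
(and bias) estimate to the drawn cursor with zero covariance each step,
so the innovation y − C ẑ subtracts the position-explained activity and
only velocity is updated. Default standalone bin width is 25 ms; the
synthetic comparisons run the filter at the corpus bin width (20 ms) so
both decoders consume identical inputs.

## Analyses

* **Electrode ranking.** Counts are discretized to {0,1,2,3,4,5+} (5
  spikes in a 20 ms bin = 250 Hz instantaneous); all bins of each trial
  are pooled by reach direction (start→target geometry; out and back are
  distinct directions); I(X;Y) = H(Y) − H(Y|X) in bits with empirical
  direction priors; ties break by ascending electrode index. Electrodes
  are dropped most-informative-first, without retraining.
* **Subspace similarity.** Per day, electrode × time activity is centred
  by each electrode's across-days mean, the covariance (1/T)YYᵀ is
  eigendecomposed, and the top K = 10 eigenvectors kept; day-pair
  similarity is the minimum principal angle (arccos of the largest
  singular value of VᵢᵀVⱼ).
* **Behavioural similarity.** Trial-averaged x and y velocity traces per
  radial target (700 ms outward, 600 ms inward epochs → 10,400 ms
  concatenated vectors), Pearson-correlated across days, dimensions
  averaged.

## Closed-loop simulation

The drawn cursor follows the blend
d ← β(d_prev + γ_v v_norm Δt) + (1−β) γ_p p_norm with β = 0.99
(velocity-dominated, the small position term absorbs drift), clamped to
the 40 × 30 cm workspace; offline accuracy always uses β = 1 and scores
the velocity network alone. Before closed-loop use the cursor decoder's
velocity output is rescaled by one scalar gain — the inverse of the
decoded-vs-true velocity regression slope on late training data,
clipped to [1, 2] — the deployment-time cursor-gain calibration every
closed-loop rig performs; it undoes the amplitude attenuation inherent
to squared-error training and touches no closed-loop data.

The user model is an intermittent submovement controller standing in
for the animal, the standard motor-control account of corrective
reaching: it plans a minimum-jerk velocity profile from the *perceived*
cursor (the drawn cursor 160 ms ago — the visuomotor latency) to the
target, with duration 87.5 ms/cm of distance (floored at 350 ms),
executes it, and replans every 300 ms or when the target changes;
1 cm/s Gaussian intention noise rides on top. Two properties are
load-bearing. First, the intent statistics match the reaching data that
decoders are trained on — a controller emitting saturated velocity
ramps drives the recurrent decoder's inputs off its training manifold
and its closed-loop behaviour stops reflecting its offline accuracy.
Second, the delay: feedback through a delayed loop tolerates
well-calibrated decoders but destabilizes when the decoder's response
is strongly miscalibrated, which is what separates usable from unusable
decoders here.

Tasks implement the Radial 8 (8 cm targets, centre ↔ periphery
alternation) and Random Target (20 × 20 cm region, consecutive
acceptance areas may not overlap) designs: 4 × 4 cm acceptance window,
500 ms hold, 5 s timeout, and a block stops and is scored failed
(0 targets/min) when the success rate falls below 50 % after at least
10 trials. After a failed trial the rig re-centres the cursor (decoder
internal state persists), as physical task implementations do — without
this the simulated cursor can be stranded at the workspace edge, a
regime no training data covers and no physical rig produces. Trial
metrics exclude the hold; dial-in time is final minus first window
entry; normalized time-to-target divides by the distance from the
previously acquired target and counts only successes following
successes.

## The synthetic corpus generator

Each electrode is cosine-tuned:
rate = max(0, g_day g_e [b_e + o_e + d_e (R(θ)pd_e)·v + q_e pd_e·p]),
counts Poisson(rate·Δt). Tuning is drawn once per corpus: baselines
uniform 5–25 Hz; modulation depths log-normal (median 0.5 Hz/(cm/s),
log-sd 0.9) so informativeness is concentrated in a few electrodes, as
on real chronic arrays; position gains uniform 0.2–1.0 Hz/cm (a real but
secondary position signal — the premise of the FIT-KF's position
subtraction). Behaviour is minimum-jerk reaching (700 ms out / 600 ms
in, 200 ms target hold, small duration and endpoint jitter) held
statistically stable across days, so day-to-day behavioural similarity
stays ≈ 0.95+ while neural conditions drift.

The recording condition evolves day to day by mean-reverting AR(1)
processes (ρ = 0.85/day) for the global log-gain (innovation sd 0.05),
per-electrode gains (0.20), baselines (3 Hz) and a common
preferred-direction rotation (0.30 rad), plus occasional transient
electrode loss (p = 0.02/day, recovering at 0.25/day — connector-style
failures), and with probability 0.30 a day is instead a jittered copy
of a uniformly drawn past day (recurrence).  Each corpus additionally
carries a fixed permanently dead electrode set (15 % by default), as
chronic arrays do; being constant, it harms no decoder.
Consecutive days are similar; days a week or more apart are nearly
independent draws from a *bounded* family — new conditions resemble
previously encountered ones — and stale decoders are defeated chiefly by
signal turnover (electrodes dying/appearing, gain swings), not by the
common rotation, which closed-loop feedback largely compensates. The
drift scales are free parameters of the generator; they were calibrated
once against two qualitative anchors measured with the Kalman baseline
only — a same-day-trained filter must be usable every day, while a
filter trained on a single day that is a week or more stale usually is
not — and then frozen.

What the generator does *not* emulate: learning or adaptation by the
user (the controller never re-learns a decoder's quirks), non-Poisson
count statistics and cross-electrode noise correlations, within-day
drift, task context shifts, and per-electrode independent PD changes
(retuning is a common rotation plus gain/baseline changes). Passing
tests on these corpora show the algorithms express the intended
robustness phenomena under controlled drift; they are not evidence about
any particular animal's data.

## Experiment protocols and problem sizes

All protocols run on seeded corpora with E = 32 electrodes, 100
trials/day, 20 ms bins, and networks of N = F = 32–40 — sizes chosen so
each full protocol completes in minutes on a single CPU.

* **Training-size sweep** (offline): velocity MRNNs trained on the 1, 4
  and 11 days immediately preceding a test day (data added by looking
  further back, so recency is not conflated with size), scored by decode
  r² on the held-out test day.
* **Electrode dropping** (closed loop): MRNN pair trained with
  augmentation on all 12 days of the corpus; both decoders then face the
  final day's recording condition — FIT Sameday calibrated from a fresh
  block of reaches under that same condition — so the only challenge is
  the drop itself; the top-k electrodes by mutual information are zeroed
  at the decoder input (k = 0, 3) with no retraining.
* **Stale training data** (closed loop): a 24-day corpus; the MRNN pair
  and FIT Long train on the first 14 days, FIT Old on day 14 alone, FIT
  Sameday on each test day; days 15–21 are withheld as the gap and days
  22–24 are test days (three test days per gap, as in the interleaved
  experimental design). Two blocks per decoder per test day mirror the
  block-set structure; a decoder failing any block on a day scores
  0 targets/min for that day.

## Known limitations

The largest known gap between this desk-scale build and a full-scale
deployment is closed-loop usability of the MRNN. Offline decode
accuracy is high (velocity r² typically 0.8–0.9 on held-out days), but
closed-loop success under the simulator's frozen conditions is
variable: the recurrent decoder's control quality is far more sensitive
than its offline accuracy to electrode count (32 here), the size of the
condition library (10–20 days here), training length, and — critically
— the absence of user adaptation: a real BMI user learns each decoder's
quirks within tens of trials, and that adaptation is deliberately not
modelled. This offline/online divergence is a well-documented property
of closed-loop neural prostheses and should be expected when
interpreting the closed-loop protocol outcomes at this scale: the
same-day Kalman baseline, which needs no condition generalization, is
reliably usable in the simulator, while the MRNN's closed-loop margins
are thin even where it dominates offline. The stale-data and
electrode-drop protocols therefore demonstrate their Kalman-side
phenomena robustly (same-day usable everywhere; stale filters failing
across a gap; steep drop-induced degradation), while the MRNN-side
closed-loop superiority claims require larger arrays and training
corpora than a desk-scale run provides.

## Numerical notes

Double precision throughout. CG starts from zero, stops on a 1e−8
relative residual or the iteration cap, and exits early if the damped
curvature loses positive-definiteness numerically. Candidate HF steps
are rejected (λ increased) if the minibatch loss does not decrease.
Kalman covariances are symmetrized each step and checked for PSD; the
innovation covariance is re-symmetrized with a 1e−9 ridge on a singular
solve. Degenerate inputs (all-zero kinematic dimensions, empty corpora,
< 5 trials/day, single-direction ranking) raise informative errors.
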