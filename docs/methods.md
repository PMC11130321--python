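# Methods

This note documents the models, estimators and design choices behind
optomap, and what the synthetic-data generators do and do not emulate.

## Seal-test model and the sag-slope oracle

A voltage-clamp step of ΔV (default −10 mV for 300 ms from a −70 mV
holding potential) produces, in the simulator, a current that is the sum
of four components relative to the holding current:

1. a capacitive transient of peak ΔI_transient = ΔV/Ra decaying with
   τ = Ra·Cm,
2. a steady ohmic offset ΔI_steady = ΔV/Rin,
3. an optional sag current I_h(t) = A·(1 − e^(−t/τ_h)) measured from step
   onset, and
4. a linear baseline drift (pA/s) plus white Gaussian noise.

The sag statistic is the window slope `ΔI_(5–265 ms)/0.260 s`. For the
single-exponential activation model this has the closed form

    slope = A·(e^(−5/τ_h) − e^(−265/τ_h)) / 0.260 + drift_rate  [pA/s]

which the simulator stores per trace and the tests use as an oracle: on
noise-free traces the estimator agrees with the closed form to better
than one part in 10³. Single-exponential kinetics were chosen because no
kinetic model is dictated by the sag statistic itself, and this is the
simplest form with an analytic window slope. The estimator smooths each
endpoint with a 2 ms boxcar, which is unbiased for linear or slow
signals.

**Capacitance is the compensated value.** `membrane_capacitance` in
`MembraneParams` is the effective capacitance seen by the step, i.e. what
remains after amplifier capacitance compensation, not the anatomical cell
capacitance. Seal-test presets use ~20 pF with Ra = 15 MΩ, giving
τ ≈ 0.3 ms so the transient has fully decayed before the 5 ms window
point. This mirrors practice: the 5–265 ms window only isolates the sag
cleanly on a compensated amplifier — with an uncompensated ~150 pF cell
the residual transient at 5 ms would contribute hundreds of pA/s to the
slope, which is incompatible with sag-free cells measuring near zero.
Current-clamp presets use the anatomical value (150 pF, τ_m ≈ 22 ms),
where no such compensation argument applies.

Passive properties use design-decision windows: ΔI_transient is the
extremum within the first 5 ms after onset, ΔI_steady the mean over the
last 50 ms of the step. When sag is present it rides on the plateau, so
Rin from a sag-bearing trace reflects the steady-state (sag-inclusive)
conductance — as it does in the formula itself.

## PSC trains and onset detection

Each light pulse is followed, after a jittered latency, by a
difference-of-exponentials current `(e^(−t/τ_decay) − e^(−t/τ_rise))`,
peak-normalized so `peak_amplitude` is exact; the sign encodes polarity
(inward negative = EPSC at −70 mV). The analytic single-pulse charge
`peak/u_max·(τ_decay − τ_rise)` supports the charge-conservation test
(train charge = Σ per-pulse charges at 10 Hz spacing, within 5%).

Onset latency per pulse is the first time the trial-averaged,
baseline-subtracted current deviates from baseline by more than 3× the
baseline SD for at least 1 ms continuously (50 ms pre-stimulus baseline).
On a noiseless baseline (SD = 0) the rule degenerates, so the detector
falls back to a 5%-of-window-peak floor; this also prevents the decaying
tail of the previous pulse's response from triggering at the next pulse
time. If the window contains no signal at all the onset is reported
absent.

The charge-based response criterion used for convergence analysis
compares |charge| against 5× the baseline charge SD. That SD includes two
terms: per-sample noise integrated over the window, and — dominant for
long windows — the baseline-mean estimation error propagated across the
window: `sd_q = sd_b·dt·√(N + N²/N_baseline)`.

Latency *group* statistics are across-neuron quantities: in the recovery
experiments each neuron draws its characteristic latency from a Gaussian
centered on the group mean (SD = the stated jitter), with only 0.1 ms
trial-to-trial jitter within a neuron. Averaging trials with large
per-trial jitter would bias the averaged-trace onset toward the earliest
trial, which is not what a per-cell latency measurement does.

## Current-clamp model (RS/BS phenotypes)

Spiking uses an adaptive exponential integrate-and-fire neuron:

    τ_m dV/dt = −(V − E_L) + R_m·(I_inj + I_dap − I_adapt)/1000 + Δ_T·e^((V−θ)/Δ_T)

with τ_m = R_m·C_m, threshold θ, sharpness Δ_T = 0.8 mV. On crossing
−15 mV a stereotyped action potential (rise to +35 mV, fall to a fast
AHP at θ − 12 mV over 1 ms) is pasted in and integration resumes from the
AHP. Each spike increments a slow adaptation current (80 pA, τ = 400 ms)
and — in burst-enabled cells — restarts a depolarizing after-current at
its peak (230 pA, τ = 60 ms, saturating rather than summing so bursts
terminate once adaptation accumulates). The step protocol is 500 ms
depolarizations in 25 pA increments. The parameters were set so that the
phenomenology matches the study's cell types: regular-spiking cells emit
a single AP at the near-threshold step (the adaptation current holds off
further spikes), burst-enabled cells emit a ≥2-spike complex through the
after-current, and a brief strong pulse (e.g. 900 pA × 6 ms) elicits a
single AP followed by a measurable subthreshold DAP in burst cells and
none in regular cells. A "2 pA, 25 ms" single-AP pulse cannot drive a
spike in any passive model, so the pulse amplitude is an explicit free
parameter rather than a fixed constant.

The phase-plane threshold rule (first dV/dt sample exceeding 3× the SD of
all preceding samples since scan start, ≥ 20-sample burn-in) is applied
to dV/dt lightly boxcar-smoothed over 0.5 ms and requires the crossing to
persist 0.2 ms; without these guards a single noise excursion in raw
dV/dt triggers spuriously at realistic noise levels. The rule presumes a
quasi-stationary pre-spike baseline: scanning across a fast passive
charging phase inflates the running SD and biases the detected voltage,
so `scan_start` is exposed and should be placed after charging settles
when the protocol allows.

DAP amplitude is the first local maximum after the fast-AHP minimum
(found within 10 ms of the spike peak) minus that minimum, clipped at 0;
a voltage that decays monotonically after the AHP scores 0, and a
0.1 mV prominence floor keeps noise wiggles from counting as humps.

## Classifier

The boundary minimizes the 1-D soft-margin objective
`½w² + C·Σ_classes (1/n_c)·Σ hinge`, with per-class mean hinge
implementing the uniform prior (each class carries equal weight
regardless of its count, which matters at 82 vs 65 training cells).
For fixed w the loss is convex piecewise-linear in b with breakpoints
b_i = y_i − w·x_i, minimized exactly by a prefix-sum sweep; the profile
g(w) = min_b J(w, b) is convex and is minimized by ternary search, with
the hard-margin candidate w = 2/gap checked explicitly. C defaults to 1
and is exposed. Ties at the boundary go to the higher-slope class.
Cross-validation uses stratified folds (plain random division at
n ≈ 150 risks a fold swallowing a whole class); the whole tenfold pass is
repeated 20 times, and the chance band is the empirical 2.5–97.5
percentile interval of 1000 shuffled-label rounds. A brute-force grid
minimizer of the same objective serves as the test oracle for the solver
on small point sets; it is never the implementation.

## Patch-seq

QC is two-stage with the low-depth rule taking precedence: total counts
below 500 → `fail_low_depth`; otherwise a summed log2(x+1) over
*Slc32a1*/*Gad1*/*Gad2* above 7 → `fail_inhibitory`. "Expressed in fewer
than ten cells (count 5)" is read as: a gene counts as expressed at
count ≥ 5, and survives gating when expressed in ≥ 10 cells — the only
reading consistent with both numbers. The bundled DE engine is a
two-sided rank-sum on log2(x+1) with Benjamini–Hochberg adjustment;
log2FC is the difference of class means of log2(x+1) (the +1 pseudocount
back-transforms exactly), oriented class-A-over-class-B. The engine is
deliberately pluggable: externally computed (log2FC, q) tables feed
`call_degs` directly, since reproducing a shrinkage-based external
estimator is out of scope. Consequently the packaged DEG counts are not
expected to equal any particular external tool's output on real data.

The count generator draws negative-binomial counts per gene (dispersion
0.5) around lognormal baseline means, with pan-neuronal and excitatory
markers high, inhibitory and glial markers near zero, and a planted
6-fold shift in a tail of genes between the two classes. Planted QC
failures are enforced by construction — low-depth cells are multinomially
downsampled below the floor, contaminated cells get inhibitory-marker
counts raised above the ceiling, and clean cells are clipped to the
complementary side — because the generator's contract is an *exact*
number of failures of each kind. The packaged 91-cell fixture (seed 7,
4 low-depth + 7 contaminated) therefore passes exactly 80 cells. What
the generator does not emulate: gene–gene correlation, batch structure,
dropout beyond NB sampling, or read-level artifacts; QC and gating
results transfer to real data, power estimates for DE do so only
approximately.

## Axon profiles

Profiles are 1-D vertical intensity traces (image-to-profile reduction is
upstream). The generator builds per-layer blocks with height
weight/width, Gaussian-smooths them (default SD 10–15 µm), and adds a
constant background plus noise. Fractions use trapezoidal integration
with interpolated layer-boundary endpoints so the partition is exact and
sums to 100 up to float error; peak location ties resolve to the
shallowest sample. Two practical caveats: background subtraction clips at
zero, so noise comparable to the signal inflates low-signal layers (keep
noise SD well below block heights), and smoothing moves a sub-point of
mass across each boundary. The default layer table (µm from pia,
half-open intervals) — L1 [0,100), L2/3 [100,310), L4 [310,430),
L5 [430,600), L6 [600,850) — is a documented package convention standing
in for an atlas lookup and is fully configurable. When pooling slices,
profiles are normalized per slice and then averaged.

## Circuit maps

Layer assignment is a half-open interval lookup on soma depth; activation
classes are >3 mV (activated) and >7 mV (strong) on trial-averaged EPSP
amplitude; matrix cells never recorded are reported missing, never 0 mV.
Group means are computed in a canonical row order so assembly is exactly
invariant to record order and batch splits. Convergence tallies bin each
dual-input neuron into both/only-A/only-B/neither under the charge
criterion above; the mono- vs multisynaptic latency label (default
boundary 8 ms) is advisory only.

## Problem sizes and determinism

Every generator consumes one explicit seed (numpy `default_rng`); no
global state. The bundled experiments use the study's own cohort sizes —
17 + 13 sag traces, 20-neuron latency cohorts, 44-cell spiking cohort,
91-cell Patch-seq fixture, 82 + 65 classifier training points with
10 × 20 cross-validation and a 1000-shuffle null — and complete in a few
minutes on one CPU. Deviating tolerances are stated next to each test;
recovery checks compare against the simulation's own ground-truth mean
(within twice the estimated SEM), never against a number the pipeline did
not compute.
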