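# Methods

`cardiostop` simulates a cardiac-coupled stop-signal experiment with known
ground truth and implements the full analysis chain such an experiment
requires. This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data can and
cannot establish.

## Task and design model

A session consists of blocks of trials, one experimental condition per
block (counterbalanced order): distractor movement onsets coupled to
cardiac **systole** (R-peak + 290 ms), to **diastole** (R-peak + 0 ms), or
no distractors. Defaults: 3 blocks x 150 trials (100 go / 50 stop), go-cue
drawn uniformly 2.9-4.5 s after trial start subject to at least three
preceding heartbeats, 1.5 s response window, 1.0 s feedback, 0.5 s
inter-trial interval. The analytic trial span is therefore 5.4-7.0 s
(excluding the ITI). One distractor movement onset is generated per
pre-cue heartbeat at the condition's offset, perturbed by zero-mean
Gaussian trigger-latency jitter (default SD 70 ms, reproducing realized
timing SDs of ~65-72 ms).

The rule for reconciling the 2.9-4.5 s cue window with the three-beat
minimum at slow heart rates is under-determined by the design constants
alone; here the cue delay is redrawn (up to 100 times) and, failing that,
extended to 50 ms past the third beat and flagged. Flagged trials are rare
at the default heart rate and are excluded from span-bound checks.

### Staircase

The stop-signal delay (SSD) starts at 200 ms and moves by 50 ms per stop
trial — up after a successful stop, down after a commission — capped at
750 ms. The design constants specify no lower bound; a 50 ms floor (one
step above zero) keeps the delay positive. Separate, non-interacting
staircases run per condition. In closed loop against the race agent the
stop-trial response rate equilibrates at 50%.

### Race-model agent

Go finishing times are ex-Gaussian (defaults mu 400, sigma 40, tau 60 ms);
the stop process takes a fixed latency (default SSRT 220 ms; optional
small variance). On a stop trial a response occurs iff the go finishing
time is below SSD + SSRT. Go-process failures (default 8%, matching
realistic go-omission rates) produce omissions on go trials and
"successful" stops on stop trials; the staircase compensates, so the
response rate still tracks 50%.

## Cardiac model

RR intervals follow a stationary lag-1 autocorrelated Gaussian process
(phi = 0.5) with mean 60000/HR and variance calibrated so the expected
RMSSD equals the request: var = RMSSD^2 / (2(1 - phi)). Defaults HR
58.2 bpm, RMSSD 53.5 ms. Non-positive draws are resampled (negligible at
physiological settings); infeasible combinations (process SD above a third
of the mean RR) raise an error.

The ECG is rendered per beat as Gaussian P/Q/R/S/T deflections; P and T
timings scale with sqrt(RR/1000). The end of the T wave — the boundary
used for post-hoc systole/diastole coding — is defined as T-center + 2
T-widths, i.e. 350 ms x sqrt(RR/1000) after the R-peak, capped below the
RR interval. This is a documented stand-in: real T-end estimation is a
harder problem, but any monotone HR-adaptive rule supports the phase-coding
contract (systole = R to T-end inclusive, diastole = after T-end).

## EEG forward model

EEG is a linear superposition: event-locked ERP templates + an R-locked
cardiac field artifact (CFA) + white Gaussian noise (default SD 5 uV).
Each template is a Hann-squared bump confined to its latency window, with
a smooth Gaussian-in-angle scalp map and a per-condition gain:

| component | locked to | window (ms) | peak (uV) | gains (sys / dia / none) |
|---|---|---|---|---|
| HEP | R-peak | 300-400 | 2 | 1.0 / 0.5 / 1.0 |
| P2 | distractor onset | 200-300 | 4 | 0.75 / 1.25 / — |
| go potential | go-cue | 200-400 | 2 | equal |
| N2 | stop-signal | 200-300 | −4 | 1.0 / 0.5 / 1.0 |
| P3 | commission feedback | 300-400 | 5 | 1.5 / 1.0 / 1.0 |

Gain *directions* reproduce the reported condition effects (distractor P2
larger at diastole; stop N2 smaller at diastole; commission P3 larger at
systole; HEP smaller at diastole). The magnitudes are this package's own
choices: no microvolt values are published for these contrasts, so they
were fixed once, before any validation run, by a design power calculation
targeting reliable recovery in the scaled-down experiments described
below, and not revisited. The CFA is a scaled-down beat shape (6 uV QRS,
2 uV T) with a left-right dipolar scalp gradient, added at every R-peak.

The simulation intentionally reproduces two confounds of the real design:
jittered diastole-coupled P2 activity leaks into the heartbeat-locked
300-400 ms window, and movement-locked epochs cut at different cardiac
offsets carry different portions of the CFA. The corresponding corrections
(component deletion, CFA subtraction) are therefore load-bearing, not
decorative.

## Analysis chain

**ECG.** Zero-phase Hamming-window FIR band-pass 1-40 Hz (symmetric taps,
centered overlap-add convolution, ~1 Hz transition at the low edge).
R-peak detection: local maxima above half the 99.9th amplitude percentile
with a 250 ms refractory period — scale-invariant and sufficient for
synthetic ECG; it makes no claim on clinical data. HR = 60000/mean(RR);
RMSSD = sqrt(mean of squared successive RR differences). Per-beat R
amplitude (max within +/-1 sample of the peak) and T-wave area
(trapezoidal, 240-340 ms post R).

**EEG preprocessing.** 0.1 Hz second-order Butterworth high-pass
(zero-phase, forward-backward) plus 40 Hz Hamming FIR low-pass (zero-phase
by symmetry), then average reference. An FIR high-pass at 0.1 Hz would
need tens of seconds of impulse response; the IIR choice is documented
rather than hidden.

**Epoching.** Windows are half-open `[start, end)` in ms relative to the
event, 0-based sample indexing, baseline mean (−100-0 ms) subtracted per
channel. Heartbeat- and movement-locked potentials use only the first
three pre-cue events per trial. Epochs with any sample exceeding
+/-100 uV are rejected.

**CFA correction.** Random triggers are placed uniformly over the
distractor-encounter (pre-cue) periods and classified as systole or
diastole by their position in the cardiac cycle. Segments of −1000 to
2000 ms are averaged per phase after 100 ms pre-anchor baseline
correction. By default segments are anchored at the R-peak preceding each
trigger rather than at the trigger itself: a trigger-anchored average
smears the R-locked field over the phase window and cannot be subtracted
beat-by-beat, whereas the R-anchored per-phase average is an unbiased
estimate of the R-locked artifact (trigger anchoring is available as
`align="trigger"`). Subtraction applies the phase-appropriate template at
every R-peak over the artifact support (−50 to 450 ms, clipped to the
local RR), identically across conditions. On artifact-only data this
removes well over 90% of R-locked mean-square power; the residual comes
from baseline-window bleed of the QRS onset.

**Component removal.** The decomposition operates on the simulator's known
mixing (one component per injected source plus a residual), which is
lossless by construction; a blind decomposition can be slotted in the same
interface. Components are ranked by their symmetry with the ECG —
magnitude-squared coherence averaged over 0.5-10 Hz (Welch, 8 s segments)
by default, absolute Pearson correlation as the cheap alternative — and
identified by cosine similarity of their mixing weights against the
configurable spatial template bank (the reproducible stand-in for visual
topography inspection). Movement-locked components are deleted from the
heartbeat-locked trace and vice versa, mirroring the mutual-contamination
control. Constant components have undefined coherence and rank last.

**Behavior.** SSRT by the integration method: rank the n go RTs, take the
RT at rank ceil(n x p(respond|stop)) (clamped to [1, n]; ceiling is the
conservative quantile convention), subtract the central SSD. Omitted go
trials are assigned the maximum observed RT before ranking (switchable to
exclusion); the central SSD is the per-condition median (switchable to
mean). The median convention, combined with the 50 ms SSD grid, leaves a
small negative recovery bias (about −14 ms at default settings, within
the 15 ms validation bound); the mean convention removes most of it and
both are exposed because the underlying convention is genuinely
under-specified.

**Cluster statistics.** Dependent-samples t at every channel x sample;
electrodes within 5 cm are spatial neighbours; suprathreshold samples
(two-tailed parametric t critical value at the 0.05 cluster-forming level
— a conventional default, config-exposed, since no threshold is dictated
by the procedure itself) of the same sign are clustered by spatial plus
temporal adjacency; cluster score = summed t; the null distribution of
the maximal |summed t| comes from random sign flips of subject difference
maps (equivalent to within-subject condition swaps). Monte-Carlo p-values
use (count + 1)/(n + 1); when 2^n_subjects <= the requested permutation
count the full enumeration is used and p-values are exact. Zero-variance
samples map to a large signed sentinel rather than infinity.

**Condition effects.** Linear mixed models (statsmodels MixedLM) with
subject random intercepts; treatment coding against a configurable
reference (no-distractor by default, systole for the two-level movement
model). REML estimates are reported (lme4 convention); main-effects and
interaction candidates are additionally refit by ML and both AICs
reported without selecting between them. Singular fits fall back to
flagged within-subject paired contrasts.

## Validation problem sizes

Chosen as this package's own scaled-down study conditions:

* Staircase equilibrium: 2000 stop trials per condition.
* Null calibration of the cluster test: 500 datasets of 20 subjects x 8
  channels x 50 samples, 1000 permutations each.
* SSRT recovery: 100 replicates of 1000 go / 500 stop tracked trials.
* End-to-end effect recovery: 50 experiments of 10 subjects, each
  simulated as two cardiac-coupled blocks of 36 trials (18 go / 18 stop)
  on a 24-channel central montage subset at 250 Hz, analysed with the
  corrected traces (correlation-based component ranking, 200 CFA
  triggers) and 500-permutation cluster contrasts.

## What the synthetic data does and does not show

The generator provides exact ground truth, so passing tests demonstrate
that each procedure implements its contract: the staircase converges, the
integration estimator recovers a known SSRT, the CFA estimator recovers a
known artifact, the cluster test controls family-wise error on null data
and detects injected effects where they were injected. The synthetic data
are deliberately idealized: white (not 1/f) EEG noise, no ocular or
muscle artifacts, stationary heart rate dynamics, template-true component
topographies, an agent with context-independent race parameters. Passing
here therefore says nothing about detector robustness on clinical ECG,
about ICA separability of real sources, or about effect sizes in real
recordings — it validates the analysis logic, not the physiology.

## Known limitations

* The known-mixing decomposition sidesteps blind source separation;
  component ranking/deletion is exercised, ICA itself is not reimplemented.
* T-end estimation and the CFA alignment rule are documented stand-ins
  for under-specified procedures.
* The timing audit measures offsets against the nearest matching R-peak;
  an audit strictly against the preceding R would wrap small negative
  jitters of diastole-coupled events to almost a full RR interval.
* Condition-effect models assume Gaussian residuals and a single random
  intercept; no crossed or nested random-slope structures.
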