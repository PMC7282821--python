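# Methods

`pausekin` analyzes two kinds of data from studies of ribosome pausing
induced by frameshift-stimulating mRNA stem-loops (FSS): single-molecule
FRET movies of intersubunit rotation, and ensemble filter-binding time
courses of A-site tRNA delivery. Because such studies rarely deposit raw
traces, the package ships a synthetic-data generator that emulates the
experiments with known ground truth, so every analysis stage is testable
end to end.

## The physical model

The ribosome interconverts between a non-rotated (NR) and a rotated (R)
conformation of its small subunit. With an S6-cy5/L9-cy3 dye pair these
report at apparent FRET efficiencies of ~0.6 (NR) and ~0.4 (R), where
E = I_A / (I_A + I_D) per camera frame (100 ms). Three experiment designs
are modeled:

* **Equilibrium fluctuations.** A two-state continuous-time Markov chain
  with rates k(NR→R) and k(R→NR); stationary occupancy of R is
  π_R = k(NR→R) / (k(NR→R) + k(R→NR)). Pre-translocation complexes
  fluctuate at ~0.6/0.2 s⁻¹ (deacylated P-site tRNA) or ~0.8/0.2 s⁻¹
  (80% rotated).
* **Injection experiments.** The complex idles in NR; at t = 10 s
  EF-Tu·GTP·aa-tRNA and EF-G·GTP are delivered. The dwell from injection
  to the first NR→R transition (τ_bd) is the A-site-binding proxy; the
  dwell from that transition to the entry into a *stable* NR state —
  one lasting more than 4 s — is the translocation proxy (τ_trl).
  NR visits of ≤ 4 s inside the rotated phase are *excursions*
  (unproductive pre-translocation fluctuations). FSS-stalled complexes
  have median τ_bd/τ_trl of 18.2/10.7 s with excursions in 64% of traces;
  without the stem-loop the medians drop to 3.8/1.5 s and excursions to 6%.
* **Ensemble binding.** Bound fraction follows pseudo-first-order
  kinetics, bound(t) = A∞·(1 − e^(−k_app·t)), with k_app ~0.1–0.4 min⁻¹
  for stalled complexes.

## Synthetic data generator

Hidden paths are simulated exactly (Gillespie) in continuous time and
binned to frames by majority occupancy within each 100 ms frame,
mirroring camera integration. Emission per frame: E* = μ(state) +
N(0, σ_FRET) with σ_FRET = 0.08; I_A = T·E*, I_D = T·(1 − E*) plus
additive channel noise. The study does not constrain intensity
magnitudes, so T = 1000 a.u. and channel noise sd = 50 a.u. are arbitrary
round numbers that only set the scale. Photobleaching is single-step and
exponential per dye (default 0.02 s⁻¹ in the packaged scenarios):
acceptor bleach zeroes I_A and dequenches the donor to the full summed
intensity; donor bleach zeroes both. Post-bleach baselines are noise
around zero, so naive FRET there is numerically unstable — deliberately,
to exercise the QC truncation.

Injection traces draw the binding wait and the total rotated-phase span
from exponentials whose medians are the scenario parameters (the packaged
`dnax_slip` and `dnax_slip_dfss` scenarios carry the printed medians).
Excursions are Poisson arrivals within the rotated phase, capped at two
per trace (matching the observed "one or two"), with the arrival rate
calibrated so the *marginal* per-trace probability of at least one
excursion equals the scenario's `excursion_probability`: for span
S ~ Exp(k), P(≥1) = 1 − k/(k+λ), so λ = k·p/(1−p). This couples
excursions to longer rotated phases, as mechanism dictates — an arrival
process in time — rather than flipping a span-independent coin that would
place excursions into phases physically unable to host one. Excursion
dwells are exponential (mean 1.5 s, the equilibrium NR dwell scale)
truncated to [min(1 s, 0.4·available), 3.5 s]: the upper margin of 0.5 s
below the 4-s stability threshold keeps frame-boundary jitter from
promoting a truth excursion into an apparent translocation, and the lower
preference of ~10 frames reflects that reported excursion fractions are
fractions of *observed* (resolvable) excursions. Interleaving R pieces
are kept at least a few frames long so two excursions cannot merge.

One master seed per scenario; per-trace generators are spawned
deterministically (`numpy` `SeedSequence`), so identical scenario + seed
reproduce traces bit for bit, in any order.

### What the generator does not emulate

No blinking, spectral crosstalk, gamma-factor asymmetry, baseline drift,
or intensity heterogeneity between molecules; dwells are strictly
exponential (no kinetic heterogeneity, although the study's broad dwell
distributions suggest some); the injection is instantaneous. Passing
recovery tests therefore demonstrates correctness of the analysis under
the stated noise model, not robustness to every artifact of real movies.

## Trace processing

FRET is computed per frame up to the first detected bleach; frames whose
summed intensity falls below 10% of the reference total are marked
invalid rather than divided. The reference is the ensemble median of each
trace's initial frames — a per-trace reference fails for a molecule that
is dark from frame 0. Change points are found with a deterministic
CUSUM-type scan (split maximizing the standardized mean shift) plus
binary segmentation; donor bleach is a down-step of the summed intensity
to baseline, acceptor bleach a down-step of the acceptor channel with an
anti-correlated donor rise, searched only before the donor bleach. A
channel with more than one step above threshold (30% of the reference
total — above the 0.2·T inter-state swing, below any true bleach step)
is flagged multi-step; the selection policy keeps only traces whose
observed bleach events are single-step in both dyes, the standard
single-molecule certificate. One extra frame before each detected bleach
is trimmed from analysis: the frame straddling the bleach transition
carries a partial-intensity artifact. The photobleaching rate is the
censored exponential MLE, k = events / total observed time, with a
profile-likelihood CI.

## HMM idealization

A two-state Gaussian-emission HMM is fit by Baum-Welch, pooled across the
traces of one condition (shared state definitions and kinetics, as in the
study's ensemble-level 0.4/0.6 states), then each trace is idealized by
Viterbi. Numerical choices: scaled forward-backward, batched across
padded/masked traces; deterministic initialization (emission means at the
25th/75th percentiles of pooled FRET, uniform transitions) so refits need
no seed; tol 1e-6 relative log-likelihood, max 500 iterations; emission
sd floor 1e-3 to prevent variance collapse; label order canonical by
ascending mean (state 0 = R, state 1 = NR). Emissions are fit on
unsmoothed FRET — the study's 5-point smoothing applies to histograms
only, and smoothing before an HMM biases dwell times. FRET values are not
clamped to [0, 1]; out-of-range values carry information about the noise.

## Dwell kinetics

Injection traces are classified deterministically from the idealized
segments: τ_bd is the time from injection to the first NR→R transition,
the rotated phase then runs to the first transition into an NR segment
observed for more than 4.0 s (strictly; an NR visit of exactly 4.0 s is
an excursion). A trailing NR segment truncated before proving stability
leaves τ_trl censored rather than guessed; a trace already rotated at
injection is excluded as anomalous. Censored dwells carry their censoring
time so the Kaplan-Meier median (via `lifelines`) can be reported next to
the naive median — the study's estimator — whenever censoring is present;
under right censoring the naive median is biased low, never high.

Equilibrium rates are reported from the Baum-Welch soft-count transition
probabilities, k = −ln(p_stay)/Δt. The per-dwell censored MLE
(k = events/Σdurations, first segment kept as complete — the residual
dwell of a stationary exponential chain is exponential at the same rate —
trailing segment right-censored) is reported alongside. The soft-count
route is the headline because Viterbi dwell counting suffers a
missed-event merge bias when dwells approach the frame interval: at
0.6 s⁻¹, ~16% of NR dwells are shorter than 3 frames, their neighbors
merge, and the dwell-MLE rates come out ~18% low, while the soft-count
estimates stay within a few percent. Minimum dwell is one frame; no
sub-frame correction is attempted (a known deadtime bias, documented
below).

## Population analysis

FRET histograms over pre-bleach frames (bin width 0.01, not stated by the
study) are box-smoothed with a 5-point window, edge-renormalized so the
density keeps unit mass; per-frame weighting is the default, per-trace
weighting is offered (the study does not state which it used). The
two-Gaussian decomposition runs EM on frame-level samples (means free,
initialized at 0.4/0.6, so recovered peak positions double as QC) or
weighted least squares on a histogram; reported NR/R fractions are
component *areas* — the probabilistically meaningful occupancy — with
amplitudes available as a diagnostic. Overlapping components (mean
separation below one sd) are flagged. Known EM behavior: on data that are
truly single-Gaussian, the superfluous second component retains ~7–9%
weight (sklearn's EM does the same); fractions at extreme weights
(90/10) can err beyond 5 points on unlucky draws.

## Ensemble kinetics

The saturation model A∞(1 − e^(−k_app t)) is fit by bounded nonlinear
least squares on replicate-pooled points (per-replicate fits available),
with no baseline offset by default (the assays are background-subtracted;
an offset term is a switch). Relative binding is the ratio of replicate
means with first-order error propagation and a two-sample t-test — Welch
by default, safer for triplicates; classical pooled-variance Student form
as an option, since the study names only "Student t-test". Frameshifting
efficiency is the −1-frame signal over the P-site normalization signal,
as a percentage, flagged if it exceeds 1. Rate comparisons report
k_b/k_a with a log-scale delta-method CI.

## Problem sizes

Recovery checks run at the study's scales: 500 injection traces per
condition for dwell medians, 300 for excursion fractions, 200 equilibrium
traces for rates, 1000 for the bleach rate, 3000 frames for the
population decomposition, a 10,000 s path for stationary occupancy, and
triplicate 7-point time courses for binding. These match the trace counts
the study reports compiling.

## Known limitations

* **Frame-resolution detection floor.** Rotated phases shorter than
  ~4–5 frames (≲0.5 s) are invisible to any HaMMy-style idealization at
  100 ms: the Viterbi prior that suppresses noise flips also suppresses
  real sub-threshold events. In the no-FSS scenario, whose generative
  τ_trl median is 1.5 s, ~19% of rotated phases fall below this floor;
  the surviving traces have a median near 1.9–2.0 s, ~25–30% above the
  generative value. The same floor affects real experiments, whose
  printed medians are themselves detected-trace medians. The FSS-scenario
  medians (18.2/10.7 s) are essentially unaffected (<5% of spans are
  sub-resolution).
* The missed-event merge bias in dwell-based rate estimation (above) is
  reported, not corrected; no Colquhoun-Hawkes-style dead-time correction
  is attempted.
* The naive dwell median under photobleaching censoring is biased low;
  the KM median corrects it only for length censoring, not for traces
  whose events were never detected.
* EM decompositions are local optimizers; with the deterministic
  initializations used here they are reproducible, but global optimality
  is only verified against grid search on small cases.
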