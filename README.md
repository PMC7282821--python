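# pausekin

Kinetic analysis of ribosome pausing induced by frameshift-stimulating
mRNA stem-loops, for single-molecule FRET and ensemble binding data.

mRNA stem-loops that stimulate −1 programmed ribosomal frameshifting
(e.g. in the *E. coli* dnaX and HIV gag-pol mRNAs) stall the ribosome
when they reach the entrance of the mRNA channel. smFRET between labeled
ribosomal proteins (S6-cy5/L9-cy3) reads out the rotated (R, ~0.4 FRET)
vs non-rotated (NR, ~0.6 FRET) conformation of the small subunit, frame
by frame at 100 ms. `pausekin` implements the full analysis such
experiments need:

* **trace processing** — apparent FRET `E = I_A/(I_A+I_D)`, deterministic
  single-step photobleach detection in both dyes (the single-molecule
  certificate), trace selection with auditable rejection reasons, and a
  censored-MLE photobleaching rate;
* **state idealization** — a two-state Gaussian-emission hidden Markov
  model (Baum-Welch, pooled per condition; Viterbi per trace), the
  HaMMy-equivalent step;
* **dwell kinetics** — per-trace binding dwell τ_bd (injection → first
  NR→R) and translocation dwell τ_trl (first NR→R → stable NR lasting
  over 4 s), excursion counting, 2-s dwell histograms, naive and
  Kaplan-Meier medians, censored exponential rate MLEs, state occupancy;
* **population analysis** — smoothed FRET histograms and their
  two-Gaussian decomposition into NR/R fractions;
* **ensemble kinetics** — single-exponential fits of filter-binding time
  courses, `bound(t) = A∞(1−e^(−k_app t))`, relative-binding ratios with
  t-tests, frameshifting efficiency, rate fold changes;
* **synthetic data** — a generator that emulates the injection,
  equilibrium and binding experiments with known ground truth (Gillespie
  paths, frame binning, emission noise, single-step bleaching), so the
  whole pipeline is testable without any raw-data download.

The model core in the field's notation: a two-state CTMC with rates
k(NR→R), k(R→NR), stationary rotated occupancy
π_R = k(NR→R)/(k(NR→R)+k(R→NR)); Gaussian emissions
E_t ~ N(μ_state, σ); censored exponential MLE k̂ = n_events/Σt over
observed spans. See `docs/methods.md` for assumptions, parameter
defaults and known limitations.

## Worked example

Simulate an injection experiment on the no-stem-loop control scenario and
analyze it:

```bash
pausekin simulate --scenario dnax_slip_dfss --n 200 --seed 7 --out demo/
pausekin analyze injection --traces demo/traces.tsv --out demo/results/
```

The analyze step prints (abridged):

```
{
  "n_traces": 200,
  "n_accepted": 191,
  "hmm_means": [0.427, 0.600],
  "tau_bd":  {"median_s": 2.85, "ci": [2.10, 3.35], "km_median_s": 3.80, ...},
  "tau_trl": {"median_s": 2.0, "ci": [1.2, 2.5], ...},
  "excursions": {"fraction": 0.0, "ci": [0.0, 0.049], "n": 73}
}
```

Reading the numbers: this scenario bleaches both dyes at 0.02 s⁻¹, so
long dwells are right-censored — the naive median τ_bd (2.85 s) is
biased low, while the Kaplan-Meier median (3.80 s) lands on the
generative value of 3.8 s exactly as censoring theory predicts. The
translocation dwell median (2.0 s vs generative 1.5 s) carries the
100 ms detection floor discussed in `docs/methods.md`, and no short
pre-translocation excursions were detected among the 73 eligible traces
(they are generated in only 6% of traces without the stem-loop, and the
heavy bleaching here shrinks the eligible set). Swap in
`--scenario dnax_slip` to see the stalled kinetics (medians near 18 s
and 11 s, excursions in ~64% of traces).
`pausekin analyze equilibrium|population|binding` cover the other
experiment types; every run writes per-trace tables, an audit log and a
`summary.json` stamped with a config hash and seed.

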