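# Injection experiment: dnaX mRNA truncated before the stem-loop (no FSS).
# Fast A-site binding and translocation; excursions are rare (6% of traces).
name = "dnax_slip_dfss"
mode = "injection"
state_names = ["R", "NR"]
fret_means = [0.4, 0.6]
fret_sd = 0.08
# intensity scale and camera noise are not constrained by the study; these
# defaults are arbitrary round numbers (see docs/methods.md)
total_intensity = 1000.0
intensity_noise_sd = 50.0
frame_interval = 0.1
duration = 200.0
injection_time = 10.0
binding_wait_median = 3.8
translocation_median = 1.5
excursion_probability = 0.06
excursion_dwell_mean = 1.5
excursion_dwell_min = 1.0
donor_bleach_rate = 0.02
acceptor_bleach_rate = 0.02
stable_state_dwell = 4.0
n_traces = 500
seed = 0

[rate_matrix]
"NR->R" = 0.1824
"R->NR" = 0.4621
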