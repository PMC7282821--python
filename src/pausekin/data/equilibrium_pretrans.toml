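# Equilibrium fluctuation experiment: pre-translocation ribosomes with
# deacylated P-site tRNA, no EF-G.  R and NR interconvert at 0.2 s^-1
# (R->NR) and 0.6 s^-1 (NR->R); Cy5/Cy3 single-step bleaching at 0.02 s^-1.
name = "equilibrium_pretrans"
mode = "equilibrium"
state_names = ["R", "NR"]
fret_means = [0.4, 0.6]
fret_sd = 0.08
# intensity scale and camera noise are not constrained by the study; these
# defaults are arbitrary round numbers (see docs/methods.md)
total_intensity = 1000.0
intensity_noise_sd = 50.0
frame_interval = 0.1
duration = 200.0
donor_bleach_rate = 0.02
acceptor_bleach_rate = 0.02
n_traces = 200
seed = 0

[rate_matrix]
"NR->R" = 0.6
"R->NR" = 0.2
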