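# Ensemble filter-binding time course: EF-Tu-catalyzed Tyr-tRNA binding to
# ribosomes stalled by the HIV stem-loop at the mRNA-channel entrance.
# Apparent pseudo-first-order rate 0.1 min^-1; bound fraction normalized to
# the no-stem-loop control; triplicate measurements with 5% noise.
name = "hiv_ns_binding"
mode = "binding"
k_app = 0.1
amplitude = 1.0
t_points = [0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
n_replicates = 3
noise_sd = 0.05
seed = 0
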