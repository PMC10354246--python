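# Reference hyperparameters for the localization benchmark.
d: 181
m: 2
arena_radius: 1.0
length_scale: 0.1
view_radius_frac: 0.3

n_pi: 45000
n_gc: 1000
n_ovc: 1000
n_am: 1000
n_velocity: 500

tau_syn: 0.05
max_rate_low: 200.0
max_rate_high: 400.0
active_proportion: 0.1
voja_rate: 0.005
pes_rate: 0.01

dt: 0.001
duration: 120.0
cutoff: 0.2
n_landmarks: 10

tier: spiking
scale: 1.0
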