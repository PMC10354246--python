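# vsaslam

Simultaneous localization and mapping with vector-symbolic spatial
representations, implemented as a tested Python library plus CLI and run
entirely on synthetic environments.

Position, landmark identities, and composed semantic features are all
d-dimensional real vectors. A point `x` in the plane (or in 3-D) is encoded
as `phi(x) = IDFT(exp(i A x))` for a conjugate-symmetric frequency matrix
`A`; binding two encodings (circular convolution) adds the underlying
points, so a bank of `floor(d/2)` velocity-controlled oscillators — one per
independent Fourier coefficient, with the unit circle made attracting —
integrates self-motion directly in the encoded space. Landmark observations
are bound with the self-position estimate to form allocentric location
estimates, which train a heteroassociative memory (error-driven decoder
learning plus activity-gated encoder adaptation) keyed by composed feature
pointers such as `BLUE*TRIANGLE`. Re-encountering a mapped landmark unbinds
the recalled location from the egocentric observation to produce an
alternative self-position, and the difference corrects the integrator
(loop closure). Everything can run at three fidelity tiers — ideal state
equations, rate-mode neurons, or spiking LIF neurons — with identical
semantics.

## Layout

| module | contents |
| --- | --- |
| `vsaslam.vsa` | holographic algebra: bind / bundle / involution inverse / similarity, seeded vocabularies |
| `vsaslam.ssp` | continuous-space encoders, similarity maps, region encoding, rectified-density readout, MAP decoding, cleanup |
| `vsaslam.nef` | LIF tuning curves, ridge-solved decoders, synapses, the dynamics transform, PES/Voja learning |
| `vsaslam.pathint` | the velocity-controlled-oscillator bank (ideal/rate/spiking), grid-cell population |
| `vsaslam.slam` | observations, object-vector encoding, associative environment map, loop closure |
| `vsaslam.envsim` | arenas, band-limited random trajectories, the spiking velocity channel |
| `vsaslam.metrics` / `vsaslam.experiment` | ATE, integrated error, firing maps, the benchmark protocol |
| `vsaslam.cli` | `vsaslam simulate / run / query-map / firing-map` |

## CLI

```bash
# one 120-s simulation, decoded path to CSV, learned map to JSON
vsaslam simulate --seed 3 --out run.csv --map-out map.json

# the multi-seed localization benchmark at quarter scale
vsaslam run --scale 0.25 --seeds 3 --out metrics.csv

# query an exported map
vsaslam query-map --memory map.json --key "BLUE*TRIANGLE"
vsaslam query-map --memory map.json --region -0.5 -0.1 0.9 0.5

# firing-rate maps of example grid-cell neurons
vsaslam firing-map --population gc --duration 60 --out firing.csv
```

`configs/table1.yaml` holds the reference hyperparameters (d=181, 45k
path-integrator neurons, 50 ms synapses, 200–400 Hz rates, view radius
0.3× the arena radius, learning rates 1e-2 / 5e-3); `--scale` multiplies
every neuron count for desk-scale runs.

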