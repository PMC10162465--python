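# koopstream

Koopman eigenfunction features for bistable auditory-streaming neural
recordings.

## What this is for

In auditory triplet streaming (repeating *ABA–* tone patterns, one triplet
per 600 ms), listeners spontaneously alternate between hearing one
integrated stream and two segregated streams, reporting switches by button
press. `koopstream` implements a feature-extraction pipeline for
minutes-long multichannel intracranial (LFP-like) recordings made during
this task. It is intended for researchers analyzing neural correlates of
bistable perception — or any setting where slow, switching latent dynamics
modulate stimulus-locked oscillations — who need features extracted from
the neural data alone, agnostic to the behavioral report.

The pipeline approximates the Koopman operator of the underlying neural
dynamics: observations `y(t) ∈ R^nc` are delay-embedded
(`ỹ_k = [y_k, e^{-α} y_{k-1}, …, e^{-sα} y_{k-s}]`), reduced by a diffusion
map (Gaussian kernel `exp(-‖ỹ_i - ỹ_j‖²/ε²)` on a kNN graph, row-normalized
to a Markov matrix), and the leading eigenvectors form the dictionary for
extended dynamic mode decomposition. The result is a triple
`{(ω_j, v_j, φ_j)}` of eigenvalues, spatial modes and eigenfunction time
series with `y^(c)(t) ≈ Σ_j v_j^(c) φ_j(t)`. The spectrum organizes into
two branches at harmonics of the 1.67 Hz triplet rate: a slow-decaying
stimulus-encoding branch J1 and a faster-decaying perception-encoding
branch J2. J2 contains a purely real, slowly evolving eigenfunction φ⋆
whose two quasi-steady levels track the percept, and oscillators whose
instantaneous phase `ϕ_f(t) = angle(e^{i(2πf t - θ(t))})` shifts at
perceptual switches; the predictor
`p(t) = sin²((ϕ_{f;0.6s} - ϕ_{f;1.2s})/2)` crossing mean + 1 SD marks
predicted switch windows `[t* - 1.2 s, t* + RT]`.

A synthetic generator (`koopstream.synthetic`) produces surrogate
bistable-streaming blocks — phase-shifted triplet harmonics driven by a
latent two-state percept process with log-normal dwell times, slow drift,
noise, and RT-delayed button presses — so the entire pipeline is testable
without access to clinical data. See `docs/methods.md` for the model,
parameter choices and limitations.

## Worked example

```python
import numpy as np
from koopstream import SynthParams, PipelineConfig, run_pipeline
from koopstream.synthetic import simulate_block

params = SynthParams(block_duration=60.0, seed=1)
timeline, recording = simulate_block(params)

config = PipelineConfig(s=199, n_eigs=60, n_perm=999)   # desk scale
result = run_pipeline(recording, config, timeline)

d, b = result.decomposition, result.branches
print("dictionary size:", result.dictionary_cutoff)
print("J1 harmonics:", sorted({b.harmonic_of[j] for j in b.J1
                               if j in b.harmonic_of}))
print("phi* index %d, omega* = %.3f /s" % (b.phi_star_index, b.omega_star))
z = timeline.state_at(d.times)
print("corr(phi*, latent percept) = %.2f"
      % np.corrcoef(result.phi_star, z)[0, 1])
print("predicted switches:", len(result.prediction.predicted_times),
      "for", timeline.n_switches, "true switches")
print("permutation p = %.4f" % result.permutation["p"])
```

Output from this exact run:

```
dictionary size: 60
J1 harmonics: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
phi* index 7, omega* = -0.007 /s
corr(phi*, latent percept) = 0.97
predicted switches: 2 for 2 true switches
permutation p = 0.0200
```

The branch table shows the triplet-rate harmonics captured by a
persistent J1 pair each (with the leading ones duplicated by a
faster-decaying J2 pair); φ⋆ sits on J2 with a purely real, slowly
decaying eigenvalue, tracks the latent percept state (r = 0.97), and its
percept-split means differ under the constrained permutation test
(p = 0.02; this short two-switch block has limited permutation
granularity). Both predicted-switch windows align with true switches.

The same pipeline is scriptable from a shell:

```bash
koopstream simulate --out work --seed 1 --duration 60
koopstream run-all --lfp work/lfp.tsv --events work/events.tsv --out work/results
```

or stage by stage (`preprocess`, `embed`, `diffuse`, `edmd`, `branches`,
`predict`, `stats`) over the same working directory.

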