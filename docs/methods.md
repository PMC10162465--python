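# Methods

`koopstream` extracts spectral features of slow perceptual dynamics from
minutes-long multichannel neural recordings made during auditory triplet
streaming, and packages a synthetic generator of such recordings so the
entire pipeline can be exercised and validated without access to clinical
data.

## The model

The working assumption is that the recorded local field potentials
`y(t) ∈ R^nc` are observations of a smooth dynamical system `dx/dt = f(x)`
evolving on a low-dimensional manifold, and that perception corresponds to
two almost-invariant regions of that manifold: the trajectory dwells in one
region for the duration of a percept and transitions rapidly at perceptual
switches. The Koopman operator — the linear operator that advances
observation functions along the flow — gives access to this structure
through its eigenvalues `ω_j` (decay rate `Re ω_j`, frequency
`Im ω_j / 2π`), eigenfunctions `φ_j(t)` (time-varying features), and modes
`v_j` (per-channel weights), with the reconstruction

    y^(c)(t) ≈ Σ_j v_j^(c) φ_j(t).

The operator is approximated by extended dynamic mode decomposition (eDMD)
over a data-adapted dictionary: delay-embedded observations are reduced by
a diffusion map, whose leading eigenvectors form Fourier-like basis
functions on the embedded trajectory.

## Pipeline stages and the parameters that matter

1. **Preprocessing.** Each channel is standard-normalized within a sliding
   3-s centered window, smoothed by a centered boxcar of 10 ms (widened to
   an odd sample count, e.g. 11 samples at 1 kHz), and decimated to 200 Hz
   by keeping every n-th sample. Windows truncate at record boundaries —
   standalone inputs carry no pre/post-stimulus padding and fabricating
   edge data would bias the normalization. The order is fixed.
2. **Delay embedding.** Each retained sample is concatenated with `s`
   weighted past samples, lag ℓ weighted by `e^{-ℓα}`. Defaults `s = 799`
   (a 4-s history at 200 Hz) and `α = 0.001`. The first `s` samples are
   dropped. Larger `s` suppresses noise in the extracted features but
   smears the transitions of the slow feature over wider intervals.
3. **Diffusion maps.** A Gaussian kernel `exp(-d²/ε²)` on the
   union-symmetrized kNN graph (`knn = 192`), with `ε` set to the mean
   distance to each point's `kmin = 12` nearest neighbors (Euclidean
   distances; the kernel divides by `ε²` as a convention switch allows the
   un-squared variant). When built over delay coordinates, neighborhoods
   apply a Theiler window: rows whose time indices differ by at most the
   delay span `s` are excluded from each other's kNN lists. Consecutive
   delay rows share all but one sample, so without the exclusion the
   graph is dominated by a temporal chain whose eigenvectors are Fourier
   modes in time rather than functions of the underlying state; those
   chain modes masquerade as slow dynamics and, downstream, turn the
   percept feature into a spurious rotating pair. The exclusion is
   standard practice for neighbor searches in attractor reconstruction.
   Rows are normalized to a Markov matrix; no density normalization is
   applied. The eigenproblem is solved through the symmetric conjugate
   `D^{1/2} P D^{-1/2}` with a deterministic Lanczos start vector;
   eigenvectors are returned in the right-eigenvector convention,
   unit-normalized, sign-fixed (largest-magnitude entry positive).
4. **Dictionary selection.** Eigenvectors are kept up to the start of the
   first run of 3 consecutive *noise-like* vectors. A vector is noise-like
   when its spectral power within ±0.2 Hz of the triplet-rate harmonics is
   below 0.3 of total **and** its normalized spectral entropy exceeds 0.8.
   The entropy guard exists because percept- and drift-modulated
   components concentrate power in sidebands *near* (not at) the
   harmonics: their band concentration is low (~0.2) but their spectra are
   far from flat (entropy ≤ ~0.7 versus ≥ 0.84 for smoothed noise), and
   they carry exactly the perception-encoding content the dictionary must
   retain. If no noise run is found, all vectors are kept with a warning.
5. **eDMD.** The one-step least-squares operator over dictionary features
   (Gram/cross-moment construction, pseudoinverse). Near-constant
   dictionary columns are deflated and the features centered before the
   fit, with the exact invariant pair (λ = 1, constant eigenfunction)
   appended afterwards; without this, the Perron eigenvalue forms a
   near-degenerate, non-normal cluster with slowly decaying modes and the
   numerical eigenvectors mix. Eigenfunctions are unit-RMS with the first
   sample rotated to zero phase (conjugate pairs remain conjugate);
   eigenvalues are ordered by decreasing `Re(ln λ / Δt)`. Modes come from
   a per-channel least-squares fit of the preprocessed signal on the
   eigenfunctions (ridge fallback when ill-conditioned, logged).
6. **Branches.** Eigenvalues within ±0.2 Hz of an integer multiple of the
   1.67 Hz triplet rate are tagged with that harmonic. Per harmonic, the
   conjugate pair with real part closest to zero goes to the
   stimulus-encoding branch J1 and the next pair, when present, to the
   perception-encoding branch J2; the zero eigenvalue with *constant*
   eigenfunction (spread below 1e-6 of RMS — the deflated constant is
   exactly flat, whereas the slow percept feature can have near-zero
   decay but is far from constant) joins J1. The slow feature φ⋆ is the
   slowest-decaying eigenvalue whose frequency magnitude is below
   0.05 Hz and whose eigenfunction is numerically real (imaginary RMS
   < 1e-6 of total) and non-constant; it joins J2. When
   several qualify the slowest-decaying is chosen and the ambiguity is
   flagged. Everything to this point uses the neural data alone; the only
   behavior-aware step of feature extraction is the optional sign
   convention for φ⋆ (two-stream median above one-stream median).
7. **Switch prediction.** For the first J2 eigenfunction with positive
   frequency, the instantaneous phase relative to the nearest harmonic
   `f` is `ϕ(t) = angle(e^{i(2πft - θ(t))})`. Trailing circular means over
   one triplet (0.6 s) and two (1.2 s) feed the predictor
   `p = sin²((ϕ_{0.6} - ϕ_{1.2})/2)`; strict crossings of mean + 1 SD mark
   predicted switches, each opening the window `[t* - 1.2, t* + RT]` with
   an `RT + 1.2 s` refractory period (windows therefore never overlap).
   Presses are matched to containing windows greedily in time order;
   a press before `t*` counts as `bp`, after as `pb`; the order test is a
   1-df χ² against equal expected counts.
8. **Statistics.** Triplets are labeled by the percept in force at onset,
   with `⌈RT/0.6⌉` neutral triplets immediately preceding each press
   (this rule reproduces both published per-subject counts: 2 at RT 0.65 s
   and 6 at RT 3.22 s). The permutation test re-places the observed number
   of switches at random triplet boundaries (first switch pinned at the
   start of the block after RT, every same-label run longer than RT and
   retaining at least one solid triplet after neutral re-application,
   first percept a fair coin), recomputes the two-stream minus one-stream
   mean difference of φ⋆, and reports `p = (m+1)/(n+1)`; the constraint is
   asserted on every draw. KL divergence between percept-split φ⋆
   distributions uses 25 shared equal-width bins with 1e-10 additive
   smoothing, direction KL(two‖one); absolute values depend on this
   dialect. The motor-response control z-scores the 1.2-s φ⋆ segments
   preceding each predicted switch, projects them per transition direction
   onto their two leading principal components, and compares pb vs bp
   groups with rank-sum tests.

## The synthetic generator

Each channel is a sum of cosines at harmonics `m · 1.67 Hz` whose phases
shift by `Δφ_m` (default π/2 per harmonic) while the latent percept state
`z(t)` is in the two-stream state, multiplied by a slow drift envelope
(5% at a 45-s period) and embedded in additive white Gaussian noise;
button presses trail each latent switch by the subject's reaction time.
Percept encoding is by phase, not amplitude, because phase is the
discriminating signal the downstream predictor is built on. A constant
phase offset across harmonics is deliberately not a waveform time shift,
so the two percepts trace distinct loops in delay space.

Dwell times are log-normal with mean 25 s and SD 20 s, truncated below at
`RT + 2` triplets by resampling. These values emulate bistable streaming
behavior (a few switches per minute, strongly irregular durations) and
were chosen with a phenomenological constraint in mind: when the
alternation is too regular (low CV) or the harmonics dominate the noise,
a linear operator tends to represent the alternation as a coherent
low-frequency *conjugate pair* instead of the purely real slow
eigenfunction that characterizes irregular switching; realistic
irregularity and a realistic noise floor (noise SD 2.0, putting the
triplet-locked harmonics well below total broadband power) place the
generator in the regime the method is designed for. Recovery-style
evaluations summarize replicate blocks by their median, condition blocks
on containing at least one switch (a report-free block carries no
bistable information), score switch recovery against reported presses,
and count as false alarms only windows containing neither a press nor a
ground-truth latent switch — a switch within one reaction time of the
block end has no press to report.

What the generator does *not* emulate: 1/f background spectra, per-channel
noise correlations, evoked-potential waveform shape within a triplet,
latency jitter of button presses, and any stimulus acoustics. Passing
recovery tests on this generator therefore demonstrates the pipeline's
correctness under its stated assumptions, not performance on clinical
recordings.

## Numerical choices and degenerate inputs

- Windows (standardization, smoothing, circular means) truncate at
  boundaries; trailing circular means additionally mask samples whose
  window is incomplete, and zero resultant vectors are masked with a
  warning.
- Zero within-window SD, duplicate-only kNN data, isolated graph points,
  rank-deficient Gram matrices, and empty branches each have explicit
  error or warning paths rather than silent propagation.
- A constant predictor yields no predicted switches (strict threshold
  crossing); an all-noise diffusion basis reduces the dictionary to the
  constant vector with a warning.
- Eigenvector signs, eigenfunction scale and phase are fixed by explicit
  conventions (stated above) so that repeated runs are bit-identical; the
  Lanczos solver uses a deterministic start vector.
- Instantaneous phase is undefined (masked) where an eigenfunction's
  magnitude falls below 1e-12.

## Problem sizes used in the checks

The test-suite and acceptance studies run the pipeline at a reduced desk
scale chosen to exercise every stage faithfully: 60-s blocks at four
channels, a 1-s delay window (`s = 199`), and 60 diffusion eigenvectors,
with replicate blocks summarized by medians; bookkeeping checks that
depend on the full-scale geometry (sample and embedding counts, spans) run
at the full 300-s, `s = 799` configuration on a single channel. Permutation
calibration uses 50 runs of 999 permutations on a 100-triplet block.

## Known limitations

- The real-versus-complex character of the slow eigenvalue is decided at
  the resolution of one 5-ms step (`|λ| ≈ 0.999`); on short blocks with
  few, regular dwells it can tip to a rotating pair, in which case φ⋆
  selection honestly reports that no purely real slow eigenvalue exists.
- The dictionary cutoff is a hard threshold over an ordered spectrum that
  real data may interleave; the diagnostics (per-vector concentration,
  entropy, peak frequency) are returned so the cutoff can be audited.
- Out-of-sample extension of the diffusion basis (Nyström) is not
  implemented; features exist only at embedded sample times.
- KL divergence values are binning-dialect dependent and comparable only
  within a fixed configuration.
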