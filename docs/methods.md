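# Methods

`sparsepitch` implements a three-stage model of pitch perception: a
simplified auditory periphery, a sparse (L1-regularized) decomposition of the
auditory-nerve (AN) population response over a dictionary of spatiotemporal
atoms, and a Gaussian harmonic sieve that converts the sparse coefficients
into a pitch probability density.

## Stimuli

All internal stimuli are pressure waveforms in pascals at 100 kHz. Levels are
dB SPL re 20 µPa; a component at level L has peak amplitude
`20e-6 * 10**(L/20)` Pa. Complexes are sums of sinusoids at `k*f0 + Δf`
(sine phase by default, matching the zero-phase dictionary probes;
per-component phases and amplitude weights are configurable). Transposed
tones half-wave rectify a modulator at f0, low-pass it with a causal
4th-order Butterworth at 0.2 of each carrier frequency (the rectified DC is
retained), and multiply onto carriers at 4, 6.35 and 10.08 kHz. Iterated
rippled noise passes seeded white Gaussian noise through `n_itr`
delay-and-add (gain +1) or delay-and-subtract (gain −1) stages, then a
4th-order low-pass at 4 kHz; broadband levels are calibrated by RMS against
a sinusoid of the same SPL. IRN stimuli are generated 50 ms long so the
delay line is filled for delays up to 5 ms; the periphery analyses the
trailing 15 ms.

## Periphery

Each of N channels (default 200; 100 in the desk preset) applies

1. a 4th-order gammatone filter at its characteristic frequency (CF), with
   ERB bandwidth (Glasberg–Moore, `ERB(f) = 24.7*(4.37*f/1000 + 1)` Hz) and
   unit gain at CF, realised as a cascade of four identical complex
   one-pole sections;
2. in saturating mode, a memoryless `tanh` compression with knee 0.05 Pa
   (~68 dB SPL): tones at 30–45 dB stay effectively linear, a 90 dB tone
   saturates and spreads spatially across channels;
3. half-wave rectification (inner-hair-cell transduction);
4. a 1st-order low-pass at 1 kHz, which removes temporal fine structure
   gradually with frequency (≈10% transmission at 10 kHz), emulating the
   loss of AN phase locking.

CFs are ERB-number–spaced over [125, 20000] Hz. The simulation covers 15 ms;
the final 5 ms window is kept (the discarded 10 ms doubles as filter
settling), optionally decimated in time (anti-aliased), and divided by its
global maximum so the peak rate is 1. Normalization is global, not
per-channel: the pitch cue is the spatiotemporal pattern, not absolute rate.

This periphery is a compact stand-in for full cochlear simulators. It
reproduces the three properties the model's behaviour rests on — tonotopy,
gradual phase-locking loss, high-level saturation and spread — but not
adaptation, spontaneous rates, two-tone suppression or spike generation, so
quantitative AN-level detail (e.g. exact coefficient values of a given
decomposition) is not expected to transfer.

### Time decimation

The decimation factor matters scientifically, not computationally: the
solver's inner loop runs on the atom Gram matrix, so row count is nearly
free. Factors that low-pass the rate matrix below ~20 kHz destroy the
residual fine structure that discriminates neighbouring atoms in unresolved
territory. The desk preset therefore uses a factor of 2 (50 kHz effective
rate); the full-scale preset uses 1.

## Dictionary

Atoms are vectorized (column-major, time within channel), peak-normalized AN
responses to probe stimuli. The `sine` family probes with pure tones at M
frequencies, ERB-number–spaced over [125, 20000] Hz, at a fixed level
(default 30 dB SPL) or per-frequency random levels from a seeded uniform
interval; g phase-shifted copies per frequency (phases `2πk/g`) absorb
unknown stimulus phase, a simplified group-lasso scheme. The `stack` family
probes with six-harmonic complexes (amplitudes 1 to 1/6, 40 dB SPL), atom
frequencies capped at 20 kHz/6 so all partials stay in band.

Atom spacing must track the sieve template width at the harmonics being
probed. At M = 250 the spacing is ~0.15 ERB (≈166 Hz near 10 kHz), coarser
than the sieve σ at the fundamentals of interest, and estimates for
harmonics above ~10 collapse onto the spectral locus; M = 1000 (~0.04 ERB)
resolves them. The low-harmonic experiments (missing fundamental, level
invariance, transposed tones, IRN) run at M = 250; the resolved/unresolved
and pitch-shift experiments default to M = 1000.

Dictionaries are memoised in-process and can be cached on disk (`.npz`),
keyed by a content hash of the build parameters.

## Sparse coder

The decomposition solves the LASSO-style objective by iterative
soft-thresholding from h = 0:

    h_{k+1} = soft(h_k + (1/α) Dᵀ(v − D h_k), λ/(2α)),
    soft(x, t) = sign(x)·max(0, |x| − t),

with α = 1.05 × the top eigenvalue of DᵀD (power iteration). With threshold
λ/(2α) the fixed point minimises `½‖v − Dh‖² + (λ/2)‖h‖₁`; all oracles and
convergence checks use that objective. λ defaults to 0.01. λ = 0 reduces to
gradient descent to a least-squares solution, stopping on relative gradient
norm instead of objective change. Defaults: tol 1e-6 (relative objective
change), max_iter 5000, h⁰ = 0. Negative coefficients are clamped at exit
(atom weights are nonnegative by construction); an optional one-sided mode
thresholds with `max(0, x − t)` throughout. Phase groups are collapsed by
summation after clamping.

The implementation iterates on the Gram matrix (`G = DᵀD`, `c = Dᵀv`), which
is algebraically identical to the direct update and reduces per-iteration
cost from O(rows·M) to O(M²); equivalence to the direct form is tested.

## Harmonic sieve

The coefficient vector h (length M) is linearly interpolated onto a dense
candidate grid of P = 15M ERB-spaced points over [125, 20000] Hz. Row i of
the P×P sieve matrix scores candidate pitch f_i:

    G_ij = Σ_n exp(−(f_j − n·f_i)² / (2σ_i²)),  n·f_i ≤ 20 kHz,
    σ_i = 0.2·ERB(f_i)   (frequency in kHz inside the ERB formula).

`pdf = G·h̃ / Σ(G·h̃)` is a genuine unit-sum density (L1 normalization). The
pitch estimate is the density argmax — globally, or within a ±0.5-octave
geometric interval `[f·2^(−1/2), f·2^(1/2)]` when the psychoacoustic
one-octave readout convention applies. Local maxima are strict 3-point
maxima on the raw grid (plateaus take their left edge; argmax ties take the
lower frequency). Salience is the height ratio of the two tallest local
maxima within one octave; a single peak reports infinity.

Gaussians wider than the coefficient quantization are what lets the
fundamental beat its subharmonics: every subharmonic row matches the same
components, but σ grows with f_i, so the highest valid candidate collects
the most interpolated mass.

## Experiments and presets

Each runner synthesizes its battery, runs the pipeline, and returns a tidy
DataFrame plus summary; with an output directory it writes CSV results, a
JSON summary and the full JSON run configuration, making reruns
reproducible (bitwise for deterministic runs, seed-identical for stochastic
ones). Problem sizes: the desk preset (N = 100 channels, M = 250 atoms,
decimation 2) is the package's working scale for the deterministic
single-stimulus experiments; unresolved-territory runners use M = 1000; the
IRN battery uses 50 seeds with a g = 4 phase-group dictionary; the
transposed-tone battery pairs pure and transposed tones over an f0 grid
(100–500 Hz) and scores octave-folded hits within 2% of f0. High-level
stimuli (≥60 dB) run through the saturating periphery; dictionaries are
always built in the linear regime.

The framed musical-note pipeline divides a signal into `t_steps` hops,
analyses a 15 ms window anchored at each hop start, aggregates per-frame
coefficients (H_g) and densities (P_g), and averages P_g over time before
the final readout; note names are nearest equal-tempered semitones with
A4 = 440 Hz. Frames whose window would overrun the signal are dropped.

## Known limitations

- The periphery is a documented simplification; coefficient-level agreement
  with full cochlear models is out of reach by design, and pitch estimates
  are meaningful to about one dense-grid bin or 2%.
- Pitch salience saturates at a floor of ~1.2 once harmonics are fully
  unresolved (around the 17th): the 1st/2nd-peak ratio of a nearly flat
  density is noise-limited, so salience separates resolved from unresolved
  stimuli but does not resolve fine ordering within the unresolved regime.
- The candidate grid starts at 125 Hz; fundamentals below that (possible in
  the transposed-tone sweep) cannot be represented and count as misses.
- Synthetic notes exercise the framed pipeline end to end, but real
  recordings add inharmonicity, vibrato, attack transients and room
  acoustics that the synthetic battery does not emulate; passing tests show
  the machinery, not instrument-level accuracy.
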