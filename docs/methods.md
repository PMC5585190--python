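# Methods

`crossfreq` detects phase-amplitude coupling (PAC) — the dependence of a
high-frequency oscillation's amplitude envelope on the phase of a
low-frequency oscillation — in trial-epoched single-channel recordings
such as source-reconstructed MEG time courses. This note documents the
models, parameter choices, numerical conventions, and known limitations.

## Phase and amplitude extraction

For every analysis frequency the signal is band-pass filtered with a
fourth-order Butterworth (design order 4, realized as second-order
sections) applied forward and backward, giving zero net phase shift. The
Hilbert transform then yields the analytic signal; its argument is the
instantaneous phase (wrapped to [−π, π)) and its magnitude the amplitude
envelope.

Two bandwidth rules are used:

* **Phase bands** are fixed at center ± 1 Hz. The narrow band keeps the
  extracted waveform sinusoidal so its instantaneous phase is
  interpretable.
* **Amplitude bands** scale as center ± 0.4·center. An amplitude band
  must contain the modulation sidebands (center ± phase frequency) or the
  coupling is invisible regardless of its true strength; for a 60 Hz
  center the rule gives edges [36, 84] Hz, comfortably covering the
  sidebands of any 7–13 Hz phase. On the default 2 Hz amplitude grid the
  lowest admissible center for a 13 Hz phase is 34 Hz (0.4·34 = 13.6 Hz).

After filtering and the Hilbert transform, 500 ms is discarded from each
trial end (default `trim=0.5`), removing filter ringing and Hilbert edge
artifacts in one cut. Simulated short trials use the scaled rule
`min(0.1·trial_len, 0.5 s)` so sub-second trials remain analyzable. Note
that the ±1 Hz phase filter has a settling time of roughly one second;
the standard trim suffices for the statistics (phase estimates are robust
to small envelope transients) but envelope-precision tests evaluate the
settled trial interior.

Constant (dead-channel) trials are flagged degenerate rather than raised,
so batch runs survive them; the scalar estimators raise on degenerate
inputs where the quantity is genuinely undefined.

## Modulation-index estimators

All four estimators consume one phase series φ(n) and one envelope series
a(n) of equal length N:

* **MVL (Canolty)**: MI = |(1/N)·Σ a(n)·e^{iφ(n)}|. Scales linearly with
  the envelope, so it partly reflects high-frequency power rather than
  coupling; retained because of its wide use, and its confound is
  asserted (not worked around) in the tests.
* **MVL (Özkurt)**: MI = (1/√N)·|Σ a·e^{iφ}| / √(Σ a²). Amplitude-scale
  invariant; bounded by 1 (Cauchy–Schwarz).
* **PLV (Cohen)**: the envelope is demeaned (its DC offset otherwise
  dominates the Hilbert phase), its own analytic-signal phase φ_a is
  taken, and MI is the phase-locking value |(1/N)·Σ e^{i(φ−φ_a)}|.
* **KL (Tort)**: phases are partitioned into 18 equal bins (left-closed,
  right-open on [−π, π); exactly π folds into the last bin); P is the
  normalized mean amplitude per bin and MI = D_KL(P‖uniform)/log(18) ∈
  [0, 1]. Natural logarithms are used throughout (the normalized ratio is
  base-invariant); 0·log 0 ≡ 0; an empty bin raises a named error
  carrying the bin index, because the mean amplitude there is undefined.
  Bin counts of 9/18/36 give near-identical results on coupled data; 18
  is the default.

## Comodulograms and surrogates

The default grid sweeps phase 7–13 Hz (1 Hz steps) × amplitude 34–100 Hz
(2 Hz steps), a 7 × 34 grid whose every cell satisfies the sideband rule.
MI is computed per trial and averaged — trials are never concatenated,
which would create edge artifacts at the seams. The analysis window can
restrict the event-relative time range (the MEG-style defaults are
0.3–1.5 s post-stimulus against the 1.2 s baseline ending 0.3 s before
stimulus).

Surrogate normalization destroys the within-trial phase-amplitude pairing
by reassigning each trial's phase series to a different trial via a
random derangement (no trial keeps its own phase), recomputing the
trial-averaged MI per cell; 200 surrogates by default, reproducible from
a seed. The observed grid is standardized per cell as
(observed − surrogate mean)/surrogate SD; zero-spread cells are flagged
NaN. An alternative surrogate family that also shifts phase within trials
is not implemented. Surrogate draws are taken in a single pass over a
pairwise (phase-trial × amplitude-trial) MI matrix, so large ensembles
cost little beyond the first.

## Condition comparison

Per-subject comodulograms of two conditions are compared with a
cluster-based permutation test: a dependent-samples t per cell; cells
exceeding the two-tailed 5% t quantile are grouped into signed clusters
under 4-neighbour adjacency (diagonals excluded, the conservative choice
for 2-D grids); the cluster statistic is the maximum |t| within the
cluster (a cluster-mass statistic — |Σt| — is available via
`statistic="mass"`); the null distribution is the largest cluster
statistic under random within-subject condition swaps (sign flips of the
per-subject difference grids), 1000 permutations by default. The cluster
p-value is the proportion of permutations whose largest statistic reaches
the observed one. Sign patterns are drawn in ± pairs, which makes the
null — and hence every p-value — exactly invariant under exchanging the
two conditions. Zero-variance cells receive t = 0 (no evidence) rather
than ±∞.

## Sinusoidality diagnostic

Non-sinusoidal, sawtooth-like oscillations create spurious PAC through
their phase harmonics. The diagnostic measures, per phase frequency, the
mean trough-to-peak (rise) and peak-to-trough (decay) durations: cycle
landmarks come from the narrow-band instantaneous phase (peaks near phase
0, troughs near the ±π wrap), and the actual extrema are then located
within each half-cycle in a ≤ 40 Hz low-passed copy of the broadband
signal, because the extrema of a narrow-band signal are sinusoidal by
construction. A rise/decay ratio of 1 marks a symmetric waveform; a
paired t across subjects compares conditions. The 40 Hz cutoff for the
extremum-timing copy is a declared choice — low enough to suppress noise,
high enough to keep the waveform-shaping harmonics of a 7–13 Hz rhythm.

## Synthetic PAC generator

Each simulated trial sums three components:

* an **alpha rhythm**: white noise band-passed to fp ± 1 Hz (default
  fp = 10 Hz) and scaled to the RMS of a unit-amplitude sinusoid. A
  filtered-noise rhythm has physiologically realistic phase drift within
  and across trials; this also makes trial-shuffle surrogates meaningful,
  since every MI estimator is invariant to the constant phase offset that
  is all that distinguishes trials of a perfectly periodic carrier;
* a **gamma component**: white noise band-passed to the amplitude band
  (default 50–70 Hz), scaled to `gamma_rms` (default 1.0) times the alpha
  RMS, whose envelope is multiplied by the raised-cosine modulator
  1 − c·(1 − cos φ_alpha)/2 with depth c ∈ [0, 1] — maximal gain at the
  alpha peak, 1 − c at the trough. The equal-RMS default is calibrated so
  that the planted coupling dominates the bandwidth-dependent envelope
  biases of the MVL estimators and all four methods localize it on the
  full default grid;
* **white noise** scaled per trial so that 10·log10(P_signal/P_noise)
  exactly equals the requested SNR; by default the SNR is drawn uniformly
  from [−11.5, 0] dB per trial.

Defaults: fs = 1000 Hz, 64 trials of 1.2 s. Everything is reproducible
bit-for-bit from the seed.

The generator emulates narrow-band nested oscillations in stationary
noise. It does not emulate non-stationary power changes, evoked
transients, 1/f background spectra, peak-frequency drift across trials,
or non-sinusoidal waveform shapes — so passing tests demonstrate correct
estimator behavior under idealized coupling, not robustness to every
pathology of real recordings (the sinusoidality diagnostic exists
precisely because waveform shape is outside this generator's scope).

## Trial-length study

The study sweeps trial length 0.2–10 s (0.2 s steps by default),
regenerating 64-trial datasets for 20 independent seeds per length and
measuring the trial-averaged MI of each estimator at the planted
(10 Hz, 60 Hz) cell. Sub-second segments inflate all four estimators.
The stabilization length is defined per estimator as the shortest length
whose seed-averaged MI lies within 20% of its 10 s value with every
shorter length above that envelope; the study's headline number is the
largest such length across the four estimators. Trials too short for the
KL histogram to populate all 18 bins are dropped from the KL average.
Under the default noise conditions the two MVL variants stabilize at
about 1.0–1.2 s and PLV by 0.6 s, while the KL estimator's per-trial
histogram bias decays more slowly and reaches the 20% envelope only
around 1.4–1.8 s — a caveat worth remembering when computing per-trial
KL modulation indices on short epochs.

## Numerical conventions and problem sizes

Filters are applied as second-order sections (`sosfiltfilt`) for
stability of the very narrow phase bands. Phase exactly equal to π folds
to −π. The multitaper band-power estimator uses DPSS tapers with
time-half-bandwidth = smoothing × window (default ±8 Hz × 0.5 s → 7
tapers), sliding in 20 ms steps. Validation studies in the test suite use
the generator's reference conditions (64 trials × 1.2 s, 20 seeds for
detection and length studies; 16 synthetic subjects × 200 repetitions ×
1000 permutations for the cluster test's error-rate study) — sizes chosen
to make Monte-Carlo tolerances meaningful at interactive runtimes.

## Known limitations

* Only the four implemented estimators; no GLM-based, direct, directed,
  or transient PAC variants.
* One analysis window per condition; no time-resolved (sliding-window)
  comodulograms.
* Surrogates reassign phase across trials only; within-trial circular
  phase shifts are not offered.
* The rise/decay diagnostic needs at least 3 cycles of the lowest phase
  frequency per trial and a clear oscillation; it is a screening tool,
  not a waveform model.
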