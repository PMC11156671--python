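# Methods

`vocalstm` implements a complete spectro-temporal modulation (STM) analysis
of paired song/speech vocalizations — the modulogram transform, a paired
permutation contrast over the modulation plane, grouped cross-validated
linear decoding, listener-rating linkage, and a PLS/VIP comparison against
conventional acoustic features — together with a synthetic ripple corpus
that gives every stage a known ground truth. This note records the models,
the parameter choices that matter, and what the synthetic validation does
and does not establish.

## The modulogram transform

A waveform is resampled to 16 kHz and reduced to a short-time magnitude
spectrogram (Gaussian window, 50 ms; hop 10 ms; nfft 1024; linear frequency
axis to 7 kHz). Frames whose window straddles the signal onset or offset are
dropped: they are edge transients, and for clips of a few seconds they would
otherwise dominate the apparent temporal modulation content.

The modulogram is the 2D power spectrum of the mean-removed spectrogram —
by the Wiener–Khinchin theorem, identically the 2D Fourier transform of its
autocorrelation. Axes are spectral modulation Ω (cycles/kHz, density of
structure along frequency) and signed temporal modulation w (Hz, envelope
fluctuation rate; the sign distinguishes upward from downward sweeps). A
real spectrogram makes the plane point-symmetric, so it is folded to Ω ≥ 0
keeping both temporal signs; a ripple envelope cos(2π(w·t + Ω·f_kHz)) peaks
at (Ω, +w). Numerical choices:

- **Common grid across durations.** The 2D FFT is zero-padded so every
  vocalization is evaluated at the same modulation frequencies (multiples of
  the grid steps); longer signals use a finer FFT and are decimated back.
- **Tapering.** An RMS-normalized 2D Hann taper is applied before the FFT.
  Without it, sidelobe leakage from strong out-of-band structure (for the
  synthetic corpus, carrier–sideband beats at ≥ 25 Hz) piles up at the crop
  edges of the plane. The untapered path (`modulation_power`) satisfies
  exact Parseval and autocorrelation-oracle identities and is what the
  oracle tests exercise.
- **Normalization.** Total (untapered, uncropped) modulation power equals
  the population variance of the spectrogram.
- **Amplitude scale.** Two modes are supported. The *linear* magnitude mode
  is the study default (`analysis_grid()`): the synthetic carrier is
  spectrally flat, the envelope is exactly sinusoidal, and the transform
  obeys clean scaling covariance. The *log* (dB, floored at −80 dB re max)
  mode is conventional for natural recordings with a large spectral dynamic
  range; for the synthetic corpus, log compression introduces
  intermodulation images (products of the main ripple with the background
  texture) that displace statistical peaks, so it is not the default here.
- **Origin cell.** The (0, 0) cell encodes mean level, not modulation; it is
  excluded from statistics and decoding features.
- **Analysis grid.** The synthetic study runs on 0–8 cyc/kHz × ±10 Hz at
  0.25 cyc/kHz × 0.4 Hz (1683 cells) — fine enough to separate the song
  (3.5 cyc/kHz, 0.7 Hz) and speech (0.1 cyc/kHz, 6 Hz) signatures by many
  grid steps, small enough that the full pipeline runs in well under a
  minute. A finer 0–10 × ±15 grid at 0.1 × 0.16 sampling (`StmGrid()`
  defaults) is available for natural audio.

Within-speaker pairs are duration-matched before analysis: the longer
member is truncated to its first min-duration seconds, so the category
contrast is never confounded with duration.

## The synthetic ripple corpus

Each vocalization is a moving ripple: a dense multi-sine carrier
(components every 25 Hz from 25 to 7900 Hz — closer than the spectrogram's
frequency resolution, so the carrier itself is spectrally smooth, and
spanning essentially the whole representable band so no band edge falls
inside the analysis range) whose envelope is 1 + d·cos(2π(w·t + Ω·f_kHz) + φ).
Because each modulated component is exactly a carrier line plus two AM
sidebands at f_k ± w, the waveform is synthesized by placing those spectral
lines on the signal-length DFT grid and inverting — identical to the
time-domain sum up to a 1/duration-Hz frequency quantization, and fast
enough to build 630 vocalizations in a few seconds.

The corpus defaults are the frozen study conditions:

| parameter | default | meaning |
|---|---|---|
| societies × speakers | 21 × 15 | one song + one speech per speaker (630 recordings) |
| durations | U(2.5, 5) s | per-vocalization |
| song / speech centres | (3.5 cyc/kHz, 0.7 Hz) / (0.1 cyc/kHz, 6 Hz) | class signatures; temporal sign random per vocalization |
| `effect_size` | 1 | scales class separation about the midpoint; 0 = null corpus |
| society / speaker / vocalization jitter | sd (0.3, 0.5) / (0.35, 0.6) / (0.15, 0.25) | coordinate spread in (cyc/kHz, Hz); society and speaker offsets are shared within their unit |
| ripple depth | 0.7 ± 0.1 (clipped 0.2–0.8) | modulation strength |
| society clarity | N(1, 0.5) clipped [0.4, 1.7] | per-society multiplier on class separation |
| speaker clarity | N(1, 0.25) clipped [0.3, 1.8] | the same at speaker level |
| texture | 3 ripples, depth ≈ 0.04, random coordinates | broadband modulation background per vocalization |
| voice identity | carrier phases, smooth spectral tilt, coordinate offsets shared within speaker | what within-speaker pairing cancels |
| additive noise | −35 dB | broadband floor; waveforms RMS-normalized |

The clarity factors are the designed mechanism behind the behavioural
linkage: a society (or speaker) whose song and speech sit closer in the
modulation plane is *both* harder for the classifier and harder for
simulated listeners, so decoding accuracy and rating separation covary for
a structural reason, not by construction of either analysis. The texture
background matters statistically: without it the surrogate sounds are so
clean that microscopic systematic differences (global scale, shared tilt)
acquire enormous t-values and the contrast map saturates; texture supplies
the variance floor that real recordings have. These values were calibrated
once, jointly, so that the study sits in a realistic regime — decoding
accurate but off ceiling, listeners accurate but not saturated — and then
frozen; they are not tuned per analysis.

Simulated listeners rate each vocalization on the five-level
speaking(−1)…singing(+1) scale: a tanh read-out (gain 1.2) of the
projection of the corpus-standardized modulogram onto a template (the
FDR-masked contrast map), plus N(0, 0.3) judgment noise, quantized to the
permitted levels; 24 listeners by default. Standardizing cells before
projecting means listeners respond to deviations from what is typical
rather than to absolute power, which keeps a few high-energy recordings
from dominating the scale.

The synthetic acoustic table emulates a conventional 98-variable feature
set as noisy linear reads of standardized modulation-plane cells —
pitch/formant-type features load on the song region, rhythm-type features
on the speech region, fillers on random cells, and ~15% pure-noise negative
controls.

What the simulator does *not* emulate: phonemes, lyrics, melody, prosodic
contours, recording-channel variation, or any cross-cultural structure
beyond the clarity/jitter hierarchy. Passing tests therefore establish that
the pipeline recovers STM structure it is pointed at under realistic noise;
they say nothing about whether natural speech and song actually carry that
structure.

## Statistics

**Paired permutation contrast.** Per cell, a one-sample t on within-speaker
song-minus-speech differences; the null is built by random within-pair sign
flips (the sum of squared differences is flip-invariant, so all
permutations reduce to one matrix product); two-tailed add-one p-values;
Benjamini–Hochberg FDR jointly across all non-origin cells. Defaults: 10⁴
permutations, α = 0.001. Cells with zero-variance differences are excluded
(all-zero differences count as a true null, t = 0). Note the interaction of
the Monte-Carlo p floor (1/n_perm) with BH: at α = 0.001 over 1683 cells a
cell can only survive if hundreds of cells share the floor, so per-society
maps (n ≈ 15 pairs, where the exact sign-flip floor is 2⁻¹⁴) are run at
α = 0.05 with 5000 permutations — the corpus-level α would be statistically
unreachable at that n, not merely conservative.

**Peaks, overlap, k-means.** Peaks are local maxima of the signed statistic
inside the mask with a minimum grid separation. The society-overlap map
counts, per cell, the societies individually significant with the
corpus-level sign. k-means (k = 2, 20 restarts) clusters the strongest
positive and negative peak per society on (spectral, |temporal|)
coordinates — absolute temporal values because vocalizations are symmetric
between up- and down-sweeps. At 15 pairs per society the per-society peak
*locations* are variance-driven and scatter; the desk-scale k-means output
is therefore reported by temporal rate (slow/fast cluster) rather than
labelled song/speech.

**Decoding.** Leave-one-group-out linear SVM (one fold per society,
country, language family, subregion or region), features standardized with
training-fold statistics only, C = 1/(n·λ) with λ = 0.01 (λ selectable on a
held-out validation corpus over {0.1, 0.05, 0.01, 0.005, 0.001}, ties to
the stronger regularization). Accuracy is the unweighted mean over folds
(the pooled-prediction alternative is also reported); sensitivity is recall
of song, specificity recall of speech. Significance against the 50% chance
level uses the Wilcoxon signed-rank test with W = W⁺ (so 21 societies all
above chance give W = 231) and the rank-biserial correlation as effect
size, plus a bootstrap CI of the mean difference. Weight maps are z-scored
within each fold's weight vector, averaged across folds, and stored raw;
for region-recovery summaries the map is smoothed by 1.25 grid steps before
top-5% thresholding, because fold-averaged weight maps of standardized
high-dimensional features carry single-cell speckle while the
discriminative structure is spatially coherent.

**Behaviour linkage.** Per-speaker difference scores: cell-wise
(a−b)/(a+b) for nonnegative STM power, and (song−speech)/2 for signed
ratings. The ratio form applied to signed ratings would equal exactly 1 for
every speaker rated positive on song and negative on speech — a degenerate
score with no variance — so the rating score is normalized by the width of
the scale instead. Cell-wise Pearson correlation of STM against behavioural
differences across speakers, BH-FDR at 0.05; per-society accuracy–behaviour
and accuracy–duration relations use Pearson correlations.

**PLS/VIP.** One PLS1 regression per cell (scikit-learn NIPALS, predictors
and response standardized; 10 components by default, capped at
min(n−1, p)), mapping the correlation between fitted and observed STM
power, BH-FDR masked. The in-sample correlation (the conventional reading
of a fitted-vs-observed map) is optimistically biased; a k-fold
cross-validated variant (`cv=`) gives calibrated significance, and in both
modes the mask is restricted to positive correlations because "the model
fits" is a one-sided claim (under the null, cross-validated predictions
anticorrelate). VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); mean
squared VIP is 1 by construction and VIP > 1 flags important variables.
The four-way decoding comparison (STM / STM+acoustic / acoustic / acoustic
minus VIP-important variables) runs on identical folds and is tested with
Friedman (Kendall's W as effect size) and Conover's pairwise post hocs,
Bonferroni-corrected over the six pairs.

## Degenerate inputs and tie-breaks

Silence maps to the log floor; identical song/speech sets give t = 0
everywhere and an empty mask; a group with a single pair is skipped from
per-society analyses with a warning; single-class held-out groups get NaN
for the missing class's metric and produce no ROC; zero-variance responses
raise rather than return NaN silently; perfectly consistent rankings drive
the Conover residual factor to its floor (p → 0) rather than NaN; stereo
audio is reduced to the higher-RMS channel.

## Known limitations

- The modulation-domain parameters of the transform (window, hop, grid,
  amplitude scale) are a calibration, and peak coordinates shift by a grid
  step or so under resampling of these choices.
- Per-society statistics at ~15 pairs are power-limited; overlap counts and
  per-society peak locations at desk scale are indicative, not estimates of
  the corpus-scale quantities.
- In-sample PLS fit maps overstate significance; use the cross-validated
  variant when calibration matters.
- The acceptance-level numbers (decoding accuracy ≈ 93–95%, all societies
  above chance, behaviour correlations ≈ 0.5–0.8) characterize the
  synthetic study conditions, not any natural corpus.
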