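# Methods

This note documents the models, algorithms, and numerical choices
behind `finchsong`, in the order the measurement chain runs. The
package quantifies how faithfully a pupil songbird imitates its
tutor — the analysis used to characterize vocal-production defects
after experimental manipulation of the song system — on fully
synthetic Bengalese-finch-like song, so that every stage can be
verified against generator ground truth.

## 1. Synthetic song model

### Notes

A song note is synthesized as a *harmonic stack* mixed with
band-limited noise. The harmonic part is

    h(t) = Σ_{k=1..K} r^(k-1) · sin(2π k (f0 t + s t²/2)),

with K partials (`n_harmonics`), per-partial rolloff `r`, fundamental
`f0` (Hz) and linear sweep rate `s` (Hz/s). The noise part is white
Gaussian noise band-limited to 300–11025 Hz by a 4th-order
Butterworth-magnitude gain applied in the frequency domain. The two
parts are mixed at the energy ratio `(1 − noise_fraction) :
noise_fraction`, given 5-ms raised-cosine on/off ramps, and peak-scaled
to `amplitude_db` re full scale. Rendering rejects any spec whose
highest partial can exceed the Nyquist frequency.

`noise_fraction` is the single control of a note's Wiener entropy:
0 gives a clean harmonic stack (entropy ≈ −5 under the analysis
settings below), 1 gives near-flat-spectrum noise (entropy ≈ −0.3,
the 2-taper multitaper limit; see §3).

`noise_fraction_jitter` adds a uniform per-rendition perturbation to
`noise_fraction`. This matters for the degradation model: a note that
is produced *badly* is also produced *variably*. A purely additive
entropy shift with deterministic rendering cannot merge the
duration–entropy clusters of a bird's note types, because the
downstream clustering standardizes both axes and a compressed axis is
simply re-expanded. Observationally, non-crystallized song shows a
smeared duration–entropy scatter, not displaced tight clusters, so
spectral degradation is modeled as a shift *plus* an equal jitter.

### Syntax

Song syntax is a first-order Markov chain over *emission units*:
single notes and multi-note *chunks* emitted atomically (the classic
Bengalese finch structure in which a motif such as
`a b c d e f g e f g h i` contains the repeated chunk `e f g`). Each
bout walks the chain from a fixed initial unit until a target length
(drawn uniformly from `bout_length_range`, default 10–30 notes) is
reached. Notes are separated by silent gaps drawn uniformly from
`gap_ms_range` (default 20–80 ms); with 30 bouts per bird this yields
roughly 600 notes, comfortably above the scale at which the
sequence statistics stabilize. One to three introductory notes (a
short, quiet, noisy syllable) are prepended to each bout and flagged
in the ground truth so motif extraction can exclude them.

The default tutor repertoire has nine song-note types `a`–`i`:
six harmonic (noise fraction 0.03–0.06; fundamentals 600–1400 Hz;
durations 55–100 ms) and three broadband (noise fraction 0.55–0.65;
durations 40–65 ms), plus the intro note `x`. These ranges are
typical of adult Bengalese finch song, in which low-entropy harmonic
notes dominate crystallized motifs.

### Pupil derivation

A pupil is derived from the tutor by three independent mechanisms:

* **note acquisition** — each tutor note type is acquired with
  probability `note_copy_prob`; a pupil acquiring zero types is
  rejected (no singable repertoire);
* **substitution** — an unacquired type is either replaced everywhere
  by a random acquired label (`reuse`, the default, producing songs
  like `a i i i e g` in place of `a b c d e f g`) or removed
  (`drop`). After relabeling, merged emission units combine their
  transition rows (uniform average of rows, summed columns), so rows
  still sum to 1;
* **rewiring** — each transition's probability mass moves to a
  uniformly random unit with probability `transition_rewire_prob`;
  units left unreachable from the initial unit are pruned (reachable
  sets are closed under outgoing edges, so no renormalization is
  needed);
* **spectral degradation** — acquired notes' `noise_fraction` and
  `noise_fraction_jitter` increase by `entropy_shift` (clipped to 1).

All randomness flows through one `numpy.random.Generator`; the same
spec and seed reproduce a dataset byte-for-byte. WAV output is
16-bit PCM at 44.1 kHz, annotations are tab-separated text, and a
JSON manifest embeds the full spec.

## 2. Segmentation

A note is a continuous sound element demarcated by silent intervals.
The RMS envelope (5-ms centered window, 1-ms hop, dB re full scale,
−120 dB floor) is thresholded at −45 dB; runs above threshold are
candidate notes; runs separated by a sub-threshold gap shorter than
10 ms are merged; candidates shorter than 10 ms are dropped. The
defaults were fixed on the synthetic fixtures (the original analysis
delegates segmentation to an interactive tool without printing its
settings) and are exposed everywhere as parameters. Intervals are
half-open `[onset, offset)` in seconds; time-to-sample conversion
rounds half down. On clean synthetic bouts the recovered boundaries
sit within ~2.5 ms of ground truth (the envelope window's reach),
within the 5-ms tolerance used by the recovery tests. An optional
zero-phase Butterworth band-pass (documented replacement for the
interactive noise-filtering step of the original recording workflow)
can precede segmentation.

## 3. Acoustic features

All spectral features derive from a short-time multitaper power
spectrogram: 9.3-ms window (410 samples at 44.1 kHz), 1-ms hop,
FFT size 512, **two DPSS tapers with time–bandwidth 1.5** and power
averaged across tapers. The taper count is a deliberate choice: a
single-taper periodogram of white noise has per-frame spectral
flatness biased down to e^(−γ) ≈ 0.56 (Wiener entropy ≈ −0.58),
whereas the 2-taper average sits at exp(ψ(2) − ln 2) ≈ 0.76
(entropy ≈ −0.27), keeping broadband sound near the ideal value of 0
while preserving enough frequency resolution to resolve harmonics
spaced ≥ 600 Hz. Power is floored at 1e−12 × the frame maximum before
any logarithm; a floor *relative* to the frame keeps every spectral
feature exactly invariant to amplitude scaling.

Per note (frames strictly inside the segment boundaries; a note
shorter than one window contributes a single zero-padded frame and is
flagged):

* **duration** — offset − onset, ms;
* **amplitude** — mean over frames of the frame dB (mean rather than
  peak; the source analysis does not state which, and the mean is the
  steadier of the two);
* **Wiener entropy** — log(geometric/arithmetic mean) of power over
  300–11025 Hz, per frame; note value = median over frames. 0 for
  white noise, large-negative for tonal/harmonic sound;
* **pitch and goodness of pitch** — per frame, the real cepstrum of
  the log power spectrum is searched over quefrencies corresponding
  to 300–3000 Hz fundamentals; pitch is the parabolic-interpolated
  peak quefrency inverted, goodness is the peak height (high for
  periodic sound); medians over frames;
* **frequency modulation** — per frame, atan of the ratio of time- to
  frequency-derivative magnitude of the log spectrogram (gradients in
  index units), in degrees; median over frames;
* **mean frequency** — power-weighted spectral centroid over
  300–11025 Hz, median over frames.

Aggregating by the median makes the note values robust to onset
transients. The five features used by similarity (pitch, FM,
amplitude, entropy, goodness) are also kept per frame as the note's
*frame track*.

These definitions are SAP-style but not numerically identical to any
proprietary implementation (which uses multitaper spectral
derivatives and its own frame weighting); absolute feature values and
similarity percentages are comparable only within this package.

## 4. Duration–entropy maps and crystallization

A bird's *feature map* is the (duration, Wiener entropy) scatter of
up to 3000 notes (uniform seeded subsample beyond that). The
*cluster separation* score is the silhouette of a k-means partition
(k = 2 by default) of the standardized map: crystallized adult song —
tight per-type clusters with a clear harmonic/broadband entropy gap —
scores high; degraded or juvenile-like song, whose rendition
variability smears the map, scores low. All-identical input returns
0 with a warning.

## 5. Motif similarity

A *motif* is, per bout, the shortest contiguous window of
non-introductory notes containing every note type in the bird's
repertoire (union over bouts); bouts that never cover the repertoire
contribute their longest-coverage window, flagged. 30 motifs per bird
are sampled (with replacement if fewer exist).

Similarity between a tutor motif and a pupil motif is rank-based in
the five-feature frame space:

1. frames are z-scored against a reference pool (the tutor's whole
   song; ≥ 1000 frames required);
2. the null distance distribution is built from 2000 random reference
   frame pairs;
3. a tutor frame *matches* if its nearest pupil frame — searched
   within ±50 ms of its relative position after linearly normalizing
   the pupil motif to the tutor's length — lies at a distance whose
   *local similarity* (fraction of null distances exceeding it) is at
   least 0.5;
4. the motif score is the percentage of tutor frames that match.

Tutor frames are the denominator, so the score is asymmetric: a pupil
singing half the tutor's material scores ~50 against the tutor even
if everything it sings is tutor-like. Identity scores exactly 100.
The mean over 30 random motif pairings is the bird's similarity
score.

Per-feature percentage differences between birds use pooled note
medians over the sampled motifs:
`100 · |median_pupil − median_tutor| / |median_tutor|`, per feature;
entropy enters on its raw negative scale and the absolute values
appear only in this ratio. A zero tutor median makes the difference
undefined (reported as NaN).

## 6. Syntax metrics

Bouts are translated into label sequences (generator-oracle labels on
synthetic data; k-means labels on standardized duration, entropy,
pitch, and mean frequency otherwise, with pupil clusters matched to
tutor clusters by nearest centroid — the automated counterpart of
labeling note types by visual inspection). Introductory notes are
excluded.

The transition matrix counts adjacent within-bout pairs (never across
bout boundaries) and normalizes by the total transition count.
*Transition types* are the (from, to) pairs holding at least 5% of
all transitions — the threshold is applied to the **global share** by
default, the most literal reading of "transitions with less than 5%
probability"; a row-conditional mode is available via a flag. The 5%
pruning is applied to both birds before intersecting (the source
analysis is silent on this; symmetric treatment avoids inflating copy
rates with one-off pupil transitions):

    note copy rate       = 100 · |tutor types ∩ pupil types| / |tutor types|
    transition copy rate = 100 · |tutor transition types ∩ pupil transition types|
                                 / |tutor transition types|

## 7. Group statistics

* **Mann-Whitney U**, two-sided: exact permutation null (full
  enumeration over group assignments, midranks for ties) when the
  combined sample is ≤ 12; tie-corrected normal approximation
  otherwise.
* **Kruskal-Wallis H** with tie correction, chi-square p (df = k−1),
  for ≥ 3 groups.
* **Games-Howell** post hoc: per pair, Welch t with unpooled
  variances, Welch–Satterthwaite df, p from the studentized range
  distribution with q = t·√2 and k = number of groups. A pair with
  zero pooled standard error is flagged (p = 1 when the means are
  equal). Under a 3-group null with unequal variances the family-wise
  type-I error calibrates to 0.05 ± 0.02.

The rank-based omnibus paired with a means-based post hoc mirrors the
analysis convention this package reproduces; the pairing is
implemented as-is, not endorsed. Stars follow * p < 0.05,
** p < 0.01; no further multiple-testing correction is applied.

## 8. The standard experiment

`run_experiment` simulates one tutor (shared by all pupils, so the
group contrast is purely pupil-driven) and two pupil groups:

| group   | note_copy_prob | rewire | entropy_shift |
|---------|----------------|--------|---------------|
| control | 0.95           | 0.05   | 0.0           |
| lesion  | 0.55           | 0.30   | 0.25          |

with 8 birds per group and 30 bouts per bird. Each pupil is compared
with the tutor on motif similarity, both copy rates, pitch/entropy
percentage differences, and cluster separation; groups are compared
metric-by-metric (Mann-Whitney for two groups, Kruskal-Wallis +
Games-Howell beyond). Per-bird random generators are spawned from
`SeedSequence(master_seed)` in a fixed order, so each bird's song is
independent of which other birds are simulated, and identical
configs+seeds reproduce reports exactly. Plots (duration–entropy
scatters, mean ± SEM bars) are side outputs only.

`developmental_series` re-runs the experiment per stage with
group-spec overrides while reusing bird seeds, emulating recording
the same birds at successive ages.

The *adult* design (`design="adult"`, three groups by default:
control, strongly affected, weakly affected) has no shared tutor:
each bird first sings a crystallized "pre" song (an independent
rendition of the tutor model), then its "post" song is derived with
the group's degradation parameters and measured against its own pre
song — the pre-/post-manipulation comparison used for adult birds.
With three groups the omnibus is Kruskal-Wallis followed by
Games-Howell pairs.

## 9. What the synthetic data does and does not show

The generator reproduces the statistical structure the measurement
chain assumes: harmonic vs broadband notes, chunked first-order
syntax, silent-gap segmentation, parameterized imitation failure. It
does not model syrinx acoustics, amplitude/frequency micro-modulation,
cage noise or reverberation, call notes, or the developmental
dynamics of subsong; juvenile variability enters only through the
stylized shift-plus-jitter degradation. Passing tests therefore
demonstrate that the pipeline recovers known generative parameters
under clean recording conditions — not that it would match any
particular real-world similarity percentage. Absolute similarity
scores depend on the rank-based procedure defined here and are not
comparable to scores from other software.

## 10. Numerical conventions and problem sizes

* float32 STFT with pre-padded power-of-two FFT buffers; features
  aggregate in float64. Under amplitude rescaling every spectral
  feature is stable to ~1e−7 relative (FM, a gradient ratio, is the
  most sensitive at ~1e−6).
* Cepstral peak: parabolic interpolation, clipped to ±0.5 bins;
  quefrency search band [⌈sr/3000⌉, ⌊sr/300⌋] samples.
* k-means uses 10 restarts with a fixed seed; silhouette on
  standardized coordinates.
* Test and acceptance runs use the full experimental scale (8 birds ×
  30 bouts × 2 groups, 10 master seeds) for the end-to-end check, and
  scaled-down configurations (2–4 birds, 5–8 bouts) for integration
  tests whose point is logic rather than power; the null-calibration
  check permutes group labels over 12 identical-spec birds (400
  splits), which is the same final test under an exchangeable null at
  a fraction of the simulation cost.
* The Games-Howell calibration uses 2000 replicates of 3 × n=10
  normal groups with SDs (1, 2, 0.5).
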