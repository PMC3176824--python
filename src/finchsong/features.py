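"""Per-note acoustic features in the Sound Analysis style.

Seven features are computed for every segmented note: duration,
amplitude, pitch, frequency modulation (FM), Wiener entropy, goodness
of pitch, and mean frequency.  All spectral features derive from a
short-time multitaper power spectrogram:

* window 9.3 ms (410 samples at 44.1 kHz), 1-ms hop, FFT size 512;
* two DPSS tapers with time-bandwidth 1.5, power averaged across
  tapers (the classic multitaper configuration for song analysis;
  a single-taper periodogram has per-frame spectral flatness biased
  down to e^(-gamma) ~ 0.56 for white noise, whereas the 2-taper
  average sits at exp(psi(2) - ln 2) ~ 0.76, keeping the entropy of
  broadband sound near its ideal value of 0);
* analysis band 300-11025 Hz for entropy and spectral centroid;
* pitch search band 300-3000 Hz (cepstral peak with parabolic
  interpolation);
* note-level aggregation is the median over frames (robust to onset
  transients), except amplitude which is the mean frame dB.

Wiener entropy is log(geometric mean / arithmetic mean) of spectral
power: 0 for white noise, large and negative for pure tones and
harmonic stacks.  Goodness of pitch is the cepstral peak height, high
for periodic (harmonic) sound.  FM is the angle, in degrees, between
the time- and frequency-derivative magnitudes of the log spectrogram.

Power is floored at 1e-12 times the frame's maximum before any
logarithm, which keeps the entropy finite and makes every spectral
feature exactly invariant to amplitude scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .segmentation import AudioRecording, NoteSegment

__all__ = [
    "Spectrogram",
    "FrameFeatures",
    "AnnotatedBout",
    "FeatureMap",
    "spectrogram",
    "wiener_entropy",
    "pitch_and_goodness",
    "fm_angle",
    "mean_frequency",
    "extract_bout_features",
    "annotate_bout",
    "feature_map",
    "cluster_separation",
    "FEATURE_COLUMNS",
    "TRACK_FEATURES",
]

WINDOW_MS = 9.3
HOP_MS = 1.0
N_TAPERS = 2
TAPER_NW = 1.5
POWER_FLOOR_REL = 1e-12
ENTROPY_BAND_HZ = (300.0, 11025.0)
PITCH_BAND_HZ = (300.0, 3000.0)
AMPLITUDE_FLOOR_DB = -120.0

#: canonical column order of a note feature table
FEATURE_COLUMNS = [
    "duration_ms",
    "amplitude_db",
    "pitch_hz",
    "fm_deg",
    "wiener_entropy",
    "goodness_of_pitch",
    "mean_frequency_hz",
]

#: the five per-frame features used by motif similarity, in order
TRACK_FEATURES = ["pitch_hz", "fm_deg", "amplitude_db", "wiener_entropy", "goodness_of_pitch"]


def _window_samples(sample_rate: int) -> int:
    return max(256, round(WINDOW_MS * sample_rate / 1000.0))


def _hop_samples(sample_rate: int) -> int:
    return max(1, round(HOP_MS * sample_rate / 1000.0))


@lru_cache(maxsize=8)
def _tapers(window: int) -> np.ndarray:
    return dpss(window, TAPER_NW, Kmax=N_TAPERS).astype(np.float32)


@lru_cache(maxsize=8)
def _nfft(window: int) -> int:
    n = 1
    while n < window:
        n *= 2
    return n


def _multitaper_power(frames: np.ndarray) -> np.ndarray:
    """Taper-averaged power spectra for raw frames of shape (n, window)."""
    window = frames.shape[1]
    nfft = _nfft(window)
    tapers = _tapers(window)
    buf = np.zeros((frames.shape[0], nfft), dtype=np.float32)
    power: np.ndarray | None = None
    for taper in tapers:
        np.multiply(frames, taper, out=buf[:, :window])
        z = sfft.rfft(buf, axis=1)
        p = z.real**2 + z.imag**2
        power = p if power is None else power + p
    assert power is not None
    power /= len(tapers)
    return power


@dataclass
class Spectrogram:
    """Short-time multitaper power spectrogram."""

    power: np.ndarray      # (n_frames, n_bins), non-negative
    freqs: np.ndarray      # bin centers, Hz, up to Nyquist
    times: np.ndarray      # frame centers, s
    sample_rate: int
    padded: bool = False   # True if the signal was shorter than one window


def spectrogram(
    samples: np.ndarray | AudioRecording,
    sample_rate: int | None = None,
) -> Spectrogram:
    """Multitaper power spectrogram at a 1-ms hop.

    A signal shorter than one analysis window yields a single
    zero-padded frame with ``padded=True``.
    """
    if isinstance(samples, AudioRecording):
        sample_rate = samples.sample_rate
        samples = samples.samples
    if sample_rate is None:
        raise ValueError("sample_rate is required when passing a bare array")
    x = np.asarray(samples, dtype=np.float32)
    window = _window_samples(sample_rate)
    hop = _hop_samples(sample_rate)
    nfft = _nfft(window)
    padded = x.size < window
    if padded:
        frames = np.zeros((1, window), dtype=np.float32)
        frames[0, : x.size] = x
        starts = np.array([0])
    else:
        n_frames = (x.size - window) // hop + 1
        starts = np.arange(n_frames) * hop
        frames = np.ascontiguousarray(sliding_window_view(x, window)[::hop][:n_frames])
    power = _multitaper_power(frames)
    freqs = np.arange(nfft // 2 + 1) * (sample_rate / nfft)
    times = (starts + window / 2.0) / sample_rate
    return Spectrogram(power=power, freqs=freqs, times=times,
                       sample_rate=sample_rate, padded=padded)


# ---------------------------------------------------------------------------
# scalar feature operations on power spectra

def _as_frames(power: np.ndarray) -> np.ndarray:
    p = np.asarray(power, dtype=np.float64)
    if p.ndim == 1:
        p = p[None, :]
    if p.ndim != 2:
        raise ValueError("power must be a spectrum (1-D) or frames (2-D)")
    if (p < 0).any():
        raise ValueError("power must be non-negative")
    return p


def _band_mask(n_bins: int, freqs: np.ndarray | None, band: tuple[float, float] | None):
    if freqs is None or band is None:
        return slice(None)
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def _floored(p: np.ndarray) -> np.ndarray:
    rowmax = np.maximum(p.max(axis=1, keepdims=True), 1e-300)
    return np.maximum(p, POWER_FLOOR_REL * rowmax)


def wiener_entropy(
    power: np.ndarray,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] | None = ENTROPY_BAND_HZ,
) -> float:
    """log(geometric mean / arithmetic mean) of spectral power; <= 0.

    For 2-D input (frames x bins) the note-level value is the median
    across frames.  Frequencies outside ``band`` are ignored when bin
    frequencies are given.
    """
    p = _as_frames(power)
    if not p.any():
        raise ValueError("Wiener entropy is undefined for an all-zero spectrum")
    sel = _band_mask(p.shape[1], freqs, band)
    p = _floored(p)[:, sel]
    log_gmean = np.mean(np.log(p), axis=1)
    log_amean = np.log(np.mean(p, axis=1))
    return float(np.median(log_gmean - log_amean))


def mean_frequency(
    power: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] | None = ENTROPY_BAND_HZ,
) -> float:
    """Power-weighted spectral centroid, Hz; median across frames."""
    p = _as_frames(power)
    if not p.any():
        raise ValueError("mean frequency is undefined for an all-zero spectrum")
    sel = _band_mask(p.shape[1], freqs, band)
    pb = p[:, sel]
    fb = freqs[sel]
    weight = pb.sum(axis=1)
    weight = np.maximum(weight, 1e-300)
    centroid = (pb * fb).sum(axis=1) / weight
    return float(np.median(centroid))


def _cepstral_pitch(
    log_power: np.ndarray, sample_rate: int, nfft: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame cepstral pitch and goodness.

    The real cepstrum of each frame's log power spectrum is searched
    over the quefrency band corresponding to 300-3000 Hz
    fundamentals; pitch is the inverse of the (parabolically
    interpolated) peak quefrency, goodness the peak height.
    """
    cep = sfft.irfft(log_power, n=nfft, axis=1)
    q_min = max(2, int(np.ceil(sample_rate / PITCH_BAND_HZ[1])))
    q_max = min(nfft // 2 - 1, int(np.floor(sample_rate / PITCH_BAND_HZ[0])))
    band = cep[:, q_min : q_max + 1]
    idx = band.argmax(axis=1)
    rows = np.arange(band.shape[0])
    peak = band[rows, idx]
    # parabolic interpolation around the peak (interior peaks only)
    q = idx.astype(np.float64) + q_min
    interior = (idx > 0) & (idx < band.shape[1] - 1)
    if interior.any():
        c0 = band[rows[interior], idx[interior] - 1]
        c1 = peak[interior]
        c2 = band[rows[interior], idx[interior] + 1]
        denom = c0 - 2 * c1 + c2
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (c0 - c2) / denom, 0.0)
        q[interior] += np.clip(delta, -0.5, 0.5)
    pitch = sample_rate / q
    goodness = np.maximum(peak, 0.0)
    return pitch, goodness


def pitch_and_goodness(
    power: np.ndarray, sample_rate: int
) -> tuple[float, float]:
    """Cepstral pitch (Hz) and goodness of pitch; medians across frames."""
    p = _as_frames(power)
    nfft = 2 * (p.shape[1] - 1)
    log_power = np.log(_floored(p))
    pitch, goodness = _cepstral_pitch(log_power, sample_rate, nfft)
    return float(np.median(pitch)), float(np.median(goodness))


def _fm_frames(log_power: np.ndarray) -> np.ndarray:
    """Per-frame FM angle (degrees) from a note's log-power frames."""
    if log_power.shape[0] < 2:
        return np.zeros(log_power.shape[0])
    d_time, d_freq = np.gradient(log_power)
    mt = np.sqrt(np.mean(d_time**2, axis=1))
    mf = np.sqrt(np.mean(d_freq**2, axis=1))
    return np.degrees(np.arctan2(mt, np.maximum(mf, 1e-300)))


def fm_angle(power: np.ndarray) -> float:
    """Frequency-modulation angle in [0, 90] degrees; median over frames.

    atan of the ratio of time- to frequency-derivative magnitude of
    the log power spectrogram.  A single-frame note has no temporal
    derivative and returns 0 (with a warning).
    """
    p = _as_frames(power)
    if p.shape[0] < 2:
        warnings.warn("fm_angle of a single-frame note is 0 by convention")
        return 0.0
    return float(np.median(_fm_frames(np.log(_floored(p)))))


# ---------------------------------------------------------------------------
# batch per-bout extraction

@dataclass
class FrameFeatures:
    """Per-frame feature tracks for the notes of one recording.

    ``values`` holds, per frame, the five similarity features in
    :data:`TRACK_FEATURES` order; ``times`` are frame centers in
    seconds from the recording start; ``note_index`` maps each frame
    to its note's position in the segment list.
    """

    values: np.ndarray      # (n_frames, 5) float64
    times: np.ndarray       # (n_frames,)
    note_index: np.ndarray  # (n_frames,) int


def extract_bout_features(
    rec: AudioRecording, segments: list[NoteSegment]
) -> tuple[pd.DataFrame, FrameFeatures]:
    """Compute the seven note features and per-frame tracks for one bout.

    Frames are taken only inside note boundaries (1-ms hop); a note
    shorter than one analysis window contributes a single zero-padded
    frame and is flagged in the ``short_note`` column.
    """
    sr = rec.sample_rate
    window = _window_samples(sr)
    hop = _hop_samples(sr)
    nfft = _nfft(window)
    x = np.asarray(rec.samples, dtype=np.float32)

    starts_all: list[np.ndarray] = []
    counts: list[int] = []
    short_flags: list[bool] = []
    for seg in segments:
        i0, i1 = seg.sample_span(sr)
        i1 = min(i1, x.size)
        if i1 - i0 >= window:
            n_frames = (i1 - i0 - window) // hop + 1
            starts_all.append(i0 + np.arange(n_frames) * hop)
            counts.append(n_frames)
            short_flags.append(False)
        else:
            starts_all.append(np.array([i0]))
            counts.append(1)
            short_flags.append(True)
    if not segments:
        empty = pd.DataFrame(columns=FEATURE_COLUMNS + ["label", "short_note"])
        return empty, FrameFeatures(np.empty((0, 5)), np.empty(0), np.empty(0, dtype=int))

    starts = np.concatenate(starts_all)
    xpad = np.concatenate([x, np.zeros(window, dtype=np.float32)])
    frames = sliding_window_view(xpad, window)[starts]

    # amplitude from the raw (unwindowed) frames
    mean_sq = np.mean(frames.astype(np.float64) ** 2, axis=1)
    amp_db = 10.0 * np.log10(np.maximum(mean_sq, 10.0 ** (AMPLITUDE_FLOOR_DB / 10.0)))

    power = _multitaper_power(np.ascontiguousarray(frames)).astype(np.float64)
    freqs = np.arange(nfft // 2 + 1) * (sr / nfft)
    band = _band_mask(power.shape[1], freqs, ENTROPY_BAND_HZ)

    logp = np.log(_floored(power))
    pb = power[:, band]
    pb_sum = np.maximum(pb.sum(axis=1), 1e-300)
    entropy = np.mean(logp[:, band], axis=1) - np.log(pb_sum / pb.shape[1])
    centroid = (pb * freqs[band]).sum(axis=1) / pb_sum
    pitch, goodness = _cepstral_pitch(logp, sr, nfft)

    fm = np.empty(starts.size)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i in range(len(segments)):
        s, e = offsets[i], offsets[i + 1]
        fm[s:e] = _fm_frames(logp[s:e])

    note_index = np.repeat(np.arange(len(segments)), counts)
    rows = []
    for i, seg in enumerate(segments):
        s, e = offsets[i], offsets[i + 1]
        rows.append(
            {
                "duration_ms": seg.duration_ms,
                "amplitude_db": float(np.mean(amp_db[s:e])),
                "pitch_hz": float(np.median(pitch[s:e])),
                "fm_deg": float(np.median(fm[s:e])),
                "wiener_entropy": float(np.median(entropy[s:e])),
                "goodness_of_pitch": float(np.median(goodness[s:e])),
                "mean_frequency_hz": float(np.median(centroid[s:e])),
                "label": seg.label,
                "short_note": short_flags[i],
            }
        )
    notes = pd.DataFrame(rows)

    track = np.column_stack([pitch, fm, amp_db, entropy, goodness])
    times = (starts + window / 2.0) / sr
    return notes, FrameFeatures(track, times, note_index)


@dataclass
class AnnotatedBout:
    """One bout after segmentation, labeling, and featurization."""

    bird_id: str
    bout_id: int
    segments: list[NoteSegment]
    notes: pd.DataFrame           # seven features + label + short_note
    frames: FrameFeatures
    intro: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        if self.intro.size == 0:
            self.intro = np.zeros(len(self.segments), dtype=bool)

    def song_label_sequence(self) -> list[str]:
        return [
            seg.label or "?"
            for seg, fl in zip(self.segments, self.intro)
            if not fl
        ]


def annotate_bout(
    rec: AudioRecording,
    segments: list[NoteSegment],
    bird_id: str = "",
    bout_id: int = 0,
    intro: np.ndarray | None = None,
) -> AnnotatedBout:
    """Featurize segmented (optionally labeled) notes into an AnnotatedBout."""
    notes, frames = extract_bout_features(rec, segments)
    if intro is None:
        intro = np.zeros(len(segments), dtype=bool)
    return AnnotatedBout(bird_id, bout_id, segments, notes, frames, np.asarray(intro, dtype=bool))


# ---------------------------------------------------------------------------
# feature maps and crystallization

@dataclass
class FeatureMap:
    """Duration-entropy scatter of up to ``cap`` notes of one bird."""

    points: pd.DataFrame   # columns: duration_ms, wiener_entropy
    bird_id: str = ""
    stage: str = ""


def feature_map(
    notes: pd.DataFrame,
    cap: int = 3000,
    rng: np.random.Generator | None = None,
    bird_id: str = "",
    stage: str = "",
) -> FeatureMap:
    """Build a duration-vs-entropy map, subsampling to ``cap`` notes.

    Mirrors the standard practice of plotting 3000 notes per bird; if
    more notes are available a uniform random subsample (seeded) is
    taken.
    """
    if len(notes) < 1:
        raise ValueError("feature_map requires at least one note")
    cols = notes[["duration_ms", "wiener_entropy"]]
    if len(cols) > cap:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(cols), size=cap, replace=False)
        cols = cols.iloc[np.sort(idx)]
    return FeatureMap(points=cols.reset_index(drop=True), bird_id=bird_id, stage=stage)


def cluster_separation(
    fmap: FeatureMap, k: int = 2, random_state: int = 0
) -> float:
    """Silhouette score of a k-cluster partition of (duration, entropy).

    Points are standardized before clustering.  Higher scores mean
    better-separated note clusters, the signature of crystallized
    adult song; non-crystallized (juvenile-like or degraded) song
    yields overlapping clusters and a low score.  Degenerate input
    (all points identical) returns 0 with a warning.
    """
    pts = fmap.points[["duration_ms", "wiener_entropy"]].to_numpy(dtype=np.float64)
    if len(pts) < 2 * k:
        raise ValueError(f"cluster_separation needs at least 2k={2*k} points")
    std = pts.std(axis=0)
    if np.all(std < 1e-12):
        warnings.warn("all feature points identical; cluster separation is 0")
        return 0.0
    z = (pts - pts.mean(axis=0)) / np.maximum(std, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(z)
    if len(np.unique(labels)) < 2:
        warnings.warn("clustering produced a single cluster; separation is 0")
        return 0.0
    return float(silhouette_score(z, labels))
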