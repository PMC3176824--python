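"""Synthetic Bengalese-finch tutor and pupil song generator.

Bengalese finch song is a sequence of *notes* (continuous sound
elements separated by silent gaps) organized into *bouts*.  Notes and
fixed multi-note *chunks* are emitted under a first-order Markov
syntax.  Adult song notes are predominantly harmonic stacks (low
Wiener entropy, stable pitch); juvenile or degraded notes are
broadband (high entropy).

The generator produces tutor songs with this structure and derives
pupil songs by a parameterized imitation-failure model:

* each tutor note type is acquired independently with probability
  ``note_copy_prob``;
* unacquired types are replaced according to a substitution policy
  (default: reuse of a random acquired label, the way a deficient
  pupil sings an acquired note in place of the ones it failed to
  copy);
* each tutor transition is rewired to a random legal target with
  probability ``transition_rewire_prob``;
* acquired notes are spectrally degraded by adding ``entropy_shift``
  to their broadband-noise fraction.

Every stochastic operation is driven by an explicit
``numpy.random.Generator`` so identical specs and seeds give
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .segmentation import AudioRecording

__all__ = [
    "SyllableSpec",
    "SongSyntax",
    "TutorPupilSpec",
    "GroundTruth",
    "PupilDerivation",
    "render_syllable",
    "generate_bout",
    "derive_pupil",
    "write_dataset",
    "default_tutor_syllables",
    "default_tutor_syntax",
]

DEFAULT_SAMPLE_RATE = 44100
RAMP_MS = 5.0          # raised-cosine on/off ramps
NOISE_BAND_HZ = (300.0, 11025.0)   # band limit of the broadband component
LEAD_SILENCE_MS = 50.0  # silent padding at bout start/end

Unit = tuple[str, ...]


class SongSyntaxError(ValueError):
    """Raised for invalid or unusable song syntax."""


@dataclass(frozen=True)
class SyllableSpec:
    """Acoustic recipe for one note type.

    Parameters
    ----------
    label : str
        Single-character note-type id, unique within a repertoire.
    f0 : float
        Fundamental frequency, Hz.
    n_harmonics : int
        Number of harmonic partials (k * f0 for k = 1..n).
    harmonic_rolloff : float
        Per-partial amplitude decay: partial k has amplitude
        ``harmonic_rolloff ** (k - 1)``.
    noise_fraction : float
        Share of total energy carried by band-limited white noise, in
        [0, 1].  Directly controls the note's Wiener entropy.
    duration_ms : float
        Note length in milliseconds.
    amplitude_db : float
        Peak level, dB re full scale (<= 0 for unclipped audio).
    fm_sweep_hz_per_s : float
        Linear sweep rate of the fundamental, Hz per second.
    noise_fraction_jitter : float
        Half-width of a uniform per-rendition perturbation of
        ``noise_fraction`` (clipped to [0, 1] at render time).  Zero
        for crystallized adult notes; degraded song is modeled with a
        jitter equal to its entropy shift, so poorly produced notes
        are also *variably* produced and their duration-entropy
        clusters smear out.
    """

    label: str
    f0: float
    n_harmonics: int
    harmonic_rolloff: float
    noise_fraction: float
    duration_ms: float
    amplitude_db: float
    fm_sweep_hz_per_s: float = 0.0
    noise_fraction_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_fraction_jitter < 0:
            raise ValueError("noise_fraction_jitter must be >= 0")
        if len(self.label) != 1:
            raise ValueError(f"label must be one character, got {self.label!r}")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")

    def max_instantaneous_f0(self) -> float:
        dur_s = self.duration_ms / 1000.0
        return max(self.f0, self.f0 + self.fm_sweep_hz_per_s * dur_s)


@dataclass
class SongSyntax:
    """First-order Markov syntax over emission units (notes and chunks).

    ``transition_probs`` maps each unit (a tuple of labels; single
    notes are 1-tuples) to a categorical distribution over successor
    units.  Chunks are emitted atomically.  ``initial_unit`` is the
    first emission unit of every bout (``None`` means uniform over
    units).
    """

    alphabet: list[str]
    chunks: list[Unit]
    transition_probs: dict[Unit, dict[Unit, float]]
    intro_labels: list[str] = field(default_factory=list)
    gap_ms_range: tuple[float, float] = (20.0, 80.0)
    bout_length_range: tuple[int, int] = (10, 30)
    initial_unit: Unit | None = None

    def __post_init__(self) -> None:
        self.chunks = [tuple(c) for c in self.chunks]
        self.transition_probs = {
            tuple(u): {tuple(v): float(p) for v, p in row.items()}
            for u, row in self.transition_probs.items()
        }
        if self.initial_unit is not None:
            self.initial_unit = tuple(self.initial_unit)
        alpha = set(self.alphabet)
        for chunk in self.chunks:
            if not set(chunk) <= alpha:
                raise SongSyntaxError(f"chunk {chunk} uses labels outside the alphabet")
        for u, row in self.transition_probs.items():
            if not set(u) <= alpha:
                raise SongSyntaxError(f"unit {u} uses labels outside the alphabet")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise SongSyntaxError(f"transition row for {u} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise SongSyntaxError(f"negative transition probability in row {u}")
        if not self.gap_ms_range[0] > 0:
            raise SongSyntaxError("gap_ms_range minimum must be positive")
        if self.gap_ms_range[1] < self.gap_ms_range[0]:
            raise SongSyntaxError("gap_ms_range must be (min, max) with min <= max")
        lo, hi = self.bout_length_range
        if lo < 1 or hi < lo:
            raise SongSyntaxError("bout_length_range must be (min, max) with 1 <= min <= max")

    @property
    def units(self) -> list[Unit]:
        return list(self.transition_probs.keys())

    def song_labels(self) -> list[str]:
        """Alphabet labels excluding introductory-note labels."""
        intro = set(self.intro_labels)
        return [a for a in self.alphabet if a not in intro]

    def reachable_units(self, start: Unit | None = None) -> set[Unit]:
        """Units reachable (with positive probability) from ``start``."""
        if start is None:
            start = self.initial_unit
        frontier = [start] if start is not None else list(self.units)
        seen: set[Unit] = set(frontier)
        while frontier:
            u = frontier.pop()
            for v, p in self.transition_probs.get(u, {}).items():
                if p > 0 and v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return seen


@dataclass(frozen=True)
class TutorPupilSpec:
    """Generative parameters of one synthetic tutor-pupil experiment."""

    tutor_syntax: SongSyntax
    tutor_syllables: dict[str, SyllableSpec]
    note_copy_prob: float = 1.0
    substitution_policy: str = "reuse"   # "reuse" | "drop"
    transition_rewire_prob: float = 0.0
    entropy_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("note_copy_prob", "transition_rewire_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.entropy_shift < 0:
            raise ValueError("entropy_shift must be >= 0")
        if self.substitution_policy not in ("reuse", "drop"):
            raise ValueError(f"unknown substitution_policy {self.substitution_policy!r}")
        missing = set(self.tutor_syntax.alphabet) - set(self.tutor_syllables)
        if missing:
            raise ValueError(f"alphabet labels without syllable specs: {sorted(missing)}")


@dataclass
class GroundTruth:
    """Per-bout true note annotation: onsets, offsets, labels, intro flags."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    labels: list[str]
    intro: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=np.float64)
        self.offsets_s = np.asarray(self.offsets_s, dtype=np.float64)
        self.intro = np.asarray(self.intro, dtype=bool)
        n = self.onsets_s.size
        if not (self.offsets_s.size == n == len(self.labels) == self.intro.size):
            raise ValueError("GroundTruth arrays must have equal length")
        if n:
            if not np.all(self.offsets_s > self.onsets_s):
                raise ValueError("every offset must exceed its onset")
            if not np.all(self.onsets_s[1:] > self.offsets_s[:-1]):
                raise ValueError("segments must be non-overlapping with increasing onsets")

    def __len__(self) -> int:
        return self.onsets_s.size

    def song_labels(self) -> list[str]:
        """Label sequence excluding introductory notes."""
        return [l for l, i in zip(self.labels, self.intro) if not i]

    def realized_transitions(self) -> set[tuple[str, str]]:
        """Adjacent within-bout label pairs, introductory notes excluded."""
        seq = self.song_labels()
        return set(zip(seq[:-1], seq[1:]))


# ---------------------------------------------------------------------------
# rendering

@lru_cache(maxsize=256)
def _noise_band_gain(n: int, sample_rate: int) -> np.ndarray:
    """Butterworth-magnitude band-pass gain on the rfft grid of length n.

    4th-order band edges at the noise band limits; applied in the
    frequency domain so each noise token costs one FFT round trip.
    """
    low, high = NOISE_BAND_HZ
    high = min(high, 0.45 * sample_rate)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    with np.errstate(divide="ignore"):
        hp = 1.0 / np.sqrt(1.0 + (low / np.maximum(f, 1e-9)) ** 8)
    lp = 1.0 / np.sqrt(1.0 + (f / high) ** 8)
    return hp * lp


def _bandlimited_noise(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    spec *= _noise_band_gain(n, sample_rate)
    return np.fft.irfft(spec, n=n)


@lru_cache(maxsize=256)
def _harmonic_stack(spec: SyllableSpec, sample_rate: int, f0: float) -> np.ndarray:
    """Unit-RMS harmonic part of a syllable (deterministic, cached)."""
    n = round(spec.duration_ms * sample_rate / 1000.0)
    t = np.arange(n) / sample_rate
    base_phase = 2.0 * np.pi * (f0 * t + 0.5 * spec.fm_sweep_hz_per_s * t**2)
    harm = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        harm += spec.harmonic_rolloff ** (k - 1) * np.sin(k * base_phase)
    rms = np.sqrt(np.mean(harm**2))
    if rms > 0:
        harm = harm / rms
    harm.setflags(write=False)
    return harm


def render_syllable(
    spec: SyllableSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
    f0_jitter: float = 0.0,
) -> np.ndarray:
    """Render one note as a harmonic stack mixed with band-limited noise.

    The harmonic part is a sum of ``n_harmonics`` sinusoids at
    ``k * f0(t)`` with amplitudes ``harmonic_rolloff**(k-1)`` and a
    linear frequency sweep; the noise part is band-limited white
    noise.  Parts are mixed at the energy ratio
    ``(1 - noise_fraction) : noise_fraction``, 5-ms raised-cosine
    on/off ramps are applied, and the peak is scaled to
    ``amplitude_db`` re full scale.

    ``f0_jitter`` optionally perturbs the fundamental by a relative
    factor drawn uniformly from ``[-f0_jitter, +f0_jitter]`` (token-level
    pitch variability; off by default).
    """
    if sample_rate < 22050:
        raise ValueError(f"sample_rate must be >= 22050 Hz, got {sample_rate}")
    nyquist = sample_rate / 2.0
    if spec.max_instantaneous_f0() * spec.n_harmonics > nyquist:
        raise ValueError(
            f"syllable {spec.label!r}: harmonic {spec.n_harmonics} exceeds the "
            f"Nyquist frequency {nyquist:.0f} Hz (aliasing risk)"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    n = round(spec.duration_ms * sample_rate / 1000.0)

    f0 = spec.f0
    if f0_jitter > 0.0:
        f0 = f0 * (1.0 + rng.uniform(-f0_jitter, f0_jitter))
    nf = spec.noise_fraction
    if spec.noise_fraction_jitter > 0.0:
        nf = float(np.clip(
            nf + rng.uniform(-spec.noise_fraction_jitter, spec.noise_fraction_jitter),
            0.0, 1.0,
        ))

    out = np.zeros(n)
    if nf < 1.0:
        out += np.sqrt(1.0 - nf) * _harmonic_stack(spec, sample_rate, f0)
    if nf > 0.0:
        noise = _bandlimited_noise(n, sample_rate, rng)
        rms = np.sqrt(np.mean(noise**2))
        if rms > 0:
            out += np.sqrt(nf) * noise / rms

    # raised-cosine on/off ramps
    n_ramp = min(n // 2, round(RAMP_MS * sample_rate / 1000.0))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        out[:n_ramp] *= ramp
        out[-n_ramp:] *= ramp[::-1]

    peak = np.abs(out).max()
    if peak > 0:
        out *= 10.0 ** (spec.amplitude_db / 20.0) / peak
    return out


# ---------------------------------------------------------------------------
# bout generation

def _emit_unit_sequence(syntax: SongSyntax, rng: np.random.Generator) -> list[Unit]:
    units = syntax.units
    if not units:
        raise SongSyntaxError("syntax has no emission units")
    reachable = syntax.reachable_units()
    unreachable = [u for u in units if u not in reachable]
    if unreachable:
        raise SongSyntaxError(
            f"emission unit(s) unreachable under transition_probs: {unreachable}"
        )
    lo, hi = syntax.bout_length_range
    target = int(rng.integers(lo, hi + 1))
    if syntax.initial_unit is not None:
        current = syntax.initial_unit
    else:
        current = units[int(rng.integers(len(units)))]
    seq = [current]
    n_notes = len(current)
    while n_notes < target:
        row = syntax.transition_probs[current]
        targets = list(row.keys())
        probs = np.array([row[v] for v in targets])
        probs = probs / probs.sum()
        current = targets[int(rng.choice(len(targets), p=probs))]
        seq.append(current)
        n_notes += len(current)
    return seq


def generate_bout(
    syntax: SongSyntax,
    syllables: dict[str, SyllableSpec],
    rng: np.random.Generator,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    f0_jitter: float = 0.0,
) -> tuple[AudioRecording, GroundTruth]:
    """Generate one bout of song audio with exact ground-truth annotation.

    The Markov chain over emission units is walked from the initial
    unit until the sampled bout length (in notes) is reached; chunks
    are emitted atomically.  Introductory notes, when the syntax
    declares an intro label, are prepended as 1-3 repeats and flagged
    in the ground truth.  Notes are separated by silent gaps drawn
    uniformly from ``gap_ms_range``.
    """
    missing = set(syntax.alphabet) - set(syllables)
    if missing:
        raise ValueError(f"no SyllableSpec for alphabet labels: {sorted(missing)}")

    unit_seq = _emit_unit_sequence(syntax, rng)
    labels: list[str] = []
    intro_flags: list[bool] = []
    if syntax.intro_labels:
        intro_label = syntax.intro_labels[0]
        for _ in range(int(rng.integers(1, 4))):
            labels.append(intro_label)
            intro_flags.append(True)
    for unit in unit_seq:
        labels.extend(unit)
        intro_flags.extend([False] * len(unit))

    lead = round(LEAD_SILENCE_MS * sample_rate / 1000.0)
    pieces: list[np.ndarray] = [np.zeros(lead)]
    onsets, offsets = [], []
    cursor = lead
    lo_gap, hi_gap = syntax.gap_ms_range
    for i, label in enumerate(labels):
        if i > 0:
            gap = round(rng.uniform(lo_gap, hi_gap) * sample_rate / 1000.0)
            pieces.append(np.zeros(gap))
            cursor += gap
        wave = render_syllable(syllables[label], sample_rate, rng=rng, f0_jitter=f0_jitter)
        pieces.append(wave)
        onsets.append(cursor / sample_rate)
        cursor += wave.size
        offsets.append(cursor / sample_rate)
    pieces.append(np.zeros(lead))
    audio = AudioRecording(np.concatenate(pieces), sample_rate, source_path="synthetic")
    truth = GroundTruth(np.array(onsets), np.array(offsets), labels, np.array(intro_flags))
    return audio, truth


# ---------------------------------------------------------------------------
# pupil derivation

@dataclass
class PupilDerivation:
    """Result of deriving a pupil from a tutor spec."""

    syntax: SongSyntax
    syllables: dict[str, SyllableSpec]
    acquired: set[str]
    substitution: dict[str, str]

    def __iter__(self):
        # allow tuple-unpacking as (syntax, syllables, acquired)
        return iter((self.syntax, self.syllables, self.acquired))


def _merge_mapped_rows(
    syntax: SongSyntax, mapping: dict[str, str | None]
) -> dict[Unit, dict[Unit, float]]:
    """Apply a label mapping to all units and merge duplicates.

    Rows of units that collapse onto the same mapped unit are averaged
    uniformly; columns mapping to the same unit are summed, so every
    merged row still sums to 1.
    """
    def map_unit(u: Unit) -> Unit:
        out = tuple(mapping[l] for l in u if mapping[l] is not None)
        return out

    grouped: dict[Unit, list[dict[Unit, float]]] = {}
    for u, row in syntax.transition_probs.items():
        mu = map_unit(u)
        if not mu:
            continue
        new_row: dict[Unit, float] = {}
        for v, p in row.items():
            mv = map_unit(v)
            if not mv:
                continue
            new_row[mv] = new_row.get(mv, 0.0) + p
        total = sum(new_row.values())
        if total > 0:
            new_row = {v: p / total for v, p in new_row.items()}
            grouped.setdefault(mu, []).append(new_row)
    merged: dict[Unit, dict[Unit, float]] = {}
    for mu, rows in grouped.items():
        combined: dict[Unit, float] = {}
        for row in rows:
            for v, p in row.items():
                combined[v] = combined.get(v, 0.0) + p / len(rows)
        merged[mu] = combined
    return merged


def derive_pupil(spec: TutorPupilSpec, rng: np.random.Generator) -> PupilDerivation:
    """Derive a pupil's syntax and repertoire from a tutor spec.

    Each non-introductory tutor note type is acquired independently
    with ``note_copy_prob``.  Unacquired types are substituted (policy
    "reuse": replaced everywhere by a random acquired label; policy
    "drop": removed from every emission unit).  Each transition is
    rewired to a uniformly random unit with
    ``transition_rewire_prob``, and acquired notes' noise fraction is
    increased by ``entropy_shift`` (clipped to 1).
    """
    syntax = spec.tutor_syntax
    intro = set(syntax.intro_labels)
    song_types = [a for a in syntax.alphabet if a not in intro]
    acquired = {a for a in song_types if rng.random() < spec.note_copy_prob}
    if not acquired:
        raise SongSyntaxError(
            "pupil acquired zero song-note types (no singable repertoire)"
        )

    mapping: dict[str, str | None] = {a: a for a in syntax.alphabet}
    substitution: dict[str, str] = {}
    acquired_list = sorted(acquired)
    for a in song_types:
        if a in acquired:
            continue
        if spec.substitution_policy == "reuse":
            sub = acquired_list[int(rng.integers(len(acquired_list)))]
            mapping[a] = sub
            substitution[a] = sub
        else:  # drop
            mapping[a] = None

    probs = _merge_mapped_rows(syntax, mapping)

    # rewire transitions: each row entry moves its mass to a random unit
    units = list(probs.keys())
    if spec.transition_rewire_prob > 0 and len(units) > 1:
        rewired: dict[Unit, dict[Unit, float]] = {}
        for u, row in probs.items():
            new_row: dict[Unit, float] = {}
            for v, p in row.items():
                if rng.random() < spec.transition_rewire_prob:
                    v = units[int(rng.integers(len(units)))]
                new_row[v] = new_row.get(v, 0.0) + p
            rewired[u] = new_row
        probs = rewired

    initial = syntax.initial_unit
    if initial is not None:
        mapped_initial = tuple(mapping[l] for l in initial if mapping[l] is not None)
        initial = mapped_initial if mapped_initial in probs else next(iter(probs))

    # prune units unreachable from the initial unit (reachable sets are
    # closed under outgoing edges, so rows need no renormalization)
    probe = SongSyntax(
        alphabet=syntax.alphabet,
        chunks=[],
        transition_probs=probs,
        intro_labels=list(syntax.intro_labels),
        gap_ms_range=syntax.gap_ms_range,
        bout_length_range=syntax.bout_length_range,
        initial_unit=initial,
    )
    reachable = probe.reachable_units()
    probs = {u: row for u, row in probs.items() if u in reachable}
    if not probs:
        raise SongSyntaxError("pupil syntax collapsed to zero reachable units")
    emitted = sorted({l for u in probs for l in u})
    if not set(emitted) - intro:
        raise SongSyntaxError("pupil emits no song notes (intro only)")

    chunks = [c for c in ({tuple(mapping[l] for l in c if mapping[l] is not None)
                           for c in syntax.chunks}) if len(c) > 1 and c in probs]
    pupil_alphabet = emitted + sorted(intro & set(syntax.alphabet))
    pupil_syntax = SongSyntax(
        alphabet=pupil_alphabet,
        chunks=chunks,
        transition_probs=probs,
        intro_labels=list(syntax.intro_labels),
        gap_ms_range=syntax.gap_ms_range,
        bout_length_range=syntax.bout_length_range,
        initial_unit=initial if initial in probs else next(iter(probs)),
    )

    # spectral degradation: acquired notes get noisier AND more variable
    # (a degraded note is also inconsistently produced, which is what
    # smears the duration-entropy clusters of non-crystallized song)
    shift = spec.entropy_shift
    pupil_syllables: dict[str, SyllableSpec] = {}
    for label in pupil_alphabet:
        base = spec.tutor_syllables[label]
        if label in intro or shift == 0.0:
            pupil_syllables[label] = base
        else:
            pupil_syllables[label] = replace(
                base,
                noise_fraction=min(1.0, base.noise_fraction + shift),
                noise_fraction_jitter=min(1.0, base.noise_fraction_jitter + shift),
            )
    realized_acquired = set(emitted) & acquired
    return PupilDerivation(pupil_syntax, pupil_syllables, realized_acquired, substitution)


# ---------------------------------------------------------------------------
# dataset writing

def _spec_to_dict(spec: TutorPupilSpec) -> dict:
    syn = spec.tutor_syntax
    return {
        "tutor_syntax": {
            "alphabet": syn.alphabet,
            "chunks": [" ".join(c) for c in syn.chunks],
            "transition_probs": {
                " ".join(u): {" ".join(v): p for v, p in row.items()}
                for u, row in syn.transition_probs.items()
            },
            "intro_labels": syn.intro_labels,
            "gap_ms_range": list(syn.gap_ms_range),
            "bout_length_range": list(syn.bout_length_range),
            "initial_unit": " ".join(syn.initial_unit) if syn.initial_unit else None,
        },
        "tutor_syllables": {
            l: vars(s).copy() for l, s in sorted(spec.tutor_syllables.items())
        },
        "note_copy_prob": spec.note_copy_prob,
        "substitution_policy": spec.substitution_policy,
        "transition_rewire_prob": spec.transition_rewire_prob,
        "entropy_shift": spec.entropy_shift,
        "seed": spec.seed,
    }


def write_dataset(
    spec: TutorPupilSpec,
    n_bouts: int,
    out_dir: str | Path,
    role: str = "pupil",
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> dict:
    """Write a synthetic song dataset: WAVs, annotations, and a manifest.

    ``role`` selects whose song is rendered: ``"tutor"`` uses the
    tutor syntax and syllables directly; ``"pupil"`` first derives the
    pupil via :func:`derive_pupil`.  Audio is written as 44.1-kHz
    16-bit mono WAV; annotations as tab-separated text (onset_s,
    offset_s, label, intro); the manifest embeds the full spec and
    seed for exact reproduction.  Returns the manifest dict.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    if role not in ("tutor", "pupil"):
        raise ValueError(f"role must be 'tutor' or 'pupil', got {role!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    if role == "pupil":
        syntax, syllables, acquired = derive_pupil(spec, rng)
    else:
        syntax, syllables = spec.tutor_syntax, spec.tutor_syllables
        acquired = set(syntax.song_labels())

    files = []
    realized_transitions: set[tuple[str, str]] = set()
    for b in range(n_bouts):
        audio, truth = generate_bout(syntax, syllables, rng, sample_rate=sample_rate)
        wav_name = f"{role}_bout{b:03d}.wav"
        ann_name = f"{role}_bout{b:03d}.txt"
        audio.to_wav(out / wav_name)
        with open(out / ann_name, "w") as fh:
            fh.write("onset_s\toffset_s\tlabel\tintro\n")
            for on, off, lab, fl in zip(truth.onsets_s, truth.offsets_s,
                                        truth.labels, truth.intro):
                fh.write(f"{on:.6f}\t{off:.6f}\t{lab}\t{int(fl)}\n")
        realized_transitions |= truth.realized_transitions()
        files.append({"wav": wav_name, "annotation": ann_name})

    manifest = {
        "role": role,
        "n_bouts": n_bouts,
        "sample_rate": sample_rate,
        "bit_depth": 16,
        "files": files,
        "acquired_labels": sorted(acquired),
        "realized_transitions": sorted(f"{a}>{b}" for a, b in realized_transitions),
        "spec": _spec_to_dict(spec),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# the standard synthetic repertoire
#
# Nine song-note types a-i plus a short, quiet introductory note "x".
# Six types are harmonic stacks (low Wiener entropy, the adult
# phenotype) and three are broadband (high entropy), spanning the
# duration/frequency ranges typical of Bengalese finch notes.

def default_tutor_syllables() -> dict[str, SyllableSpec]:
    specs = [
        #           label  f0     nh  roll  noise  dur    amp    sweep
        SyllableSpec("a",  700.0,  8, 0.75, 0.04,  55.0,  -8.0,  400.0),
        SyllableSpec("b", 1100.0,  7, 0.70, 0.03,  70.0,  -7.0, -600.0),
        SyllableSpec("c",  900.0,  9, 0.80, 0.06,  90.0,  -9.0,  200.0),
        SyllableSpec("d", 1400.0,  6, 0.65, 0.04,  60.0,  -8.0,    0.0),
        SyllableSpec("e",  600.0, 10, 0.85, 0.05,  80.0,  -6.0,  300.0),
        SyllableSpec("f", 1250.0,  7, 0.70, 0.55,  45.0,  -9.0, -900.0),
        SyllableSpec("g",  800.0,  9, 0.75, 0.03, 100.0,  -7.0,  150.0),
        SyllableSpec("h", 1600.0,  5, 0.60, 0.60,  40.0, -10.0,    0.0),
        SyllableSpec("i", 1000.0,  6, 0.70, 0.65,  65.0,  -9.0,  500.0),
        SyllableSpec("x", 2500.0,  2, 0.50, 0.70,  25.0, -20.0,    0.0),
    ]
    return {s.label: s for s in specs}


def default_tutor_syntax() -> SongSyntax:
    """Markov syntax patterned on the motif a b c d (e f g)(e f g) h i."""
    A = ("a",); B = ("b",); C = ("c",); D = ("d",)
    EFG = ("e", "f", "g"); H = ("h",); I = ("i",)
    probs: dict[Unit, dict[Unit, float]] = {
        A: {B: 0.9, EFG: 0.1},
        B: {C: 0.9, D: 0.1},
        C: {D: 1.0},
        D: {EFG: 1.0},
        EFG: {EFG: 0.45, H: 0.55},
        H: {I: 0.9, A: 0.1},
        I: {A: 0.8, EFG: 0.2},
    }
    return SongSyntax(
        alphabet=list("abcdefghix"),
        chunks=[EFG],
        transition_probs=probs,
        intro_labels=["x"],
        gap_ms_range=(20.0, 80.0),
        bout_length_range=(10, 30),
        initial_unit=A,
    )
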