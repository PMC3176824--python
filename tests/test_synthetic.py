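"""Generator: syllable rendering, bout syntax, pupil derivation, datasets."""

import numpy as np
import pytest
from scipy.io import wavfile

from finchsong import (
    GroundTruth,
    SongSyntax,
    SyllableSpec,
    TutorPupilSpec,
    derive_pupil,
    generate_bout,
    render_syllable,
    spectrogram,
    wiener_entropy,
    write_dataset,
)
from finchsong.synthetic import SongSyntaxError

from conftest import SR, harmonic_spec


class TestRenderSyllable:
    def test_sample_count_matches_duration(self):
        wave = render_syllable(harmonic_spec(duration_ms=100.0), SR)
        assert wave.size == 4410

    def test_rendered_pitch_matches_f0(self):
        """A noise-free 600 Hz stack must have its FFT comb at 600 Hz."""
        wave = render_syllable(harmonic_spec(f0=600.0, n_harmonics=3), SR)
        spec = np.abs(np.fft.rfft(wave))
        peak_hz = np.fft.rfftfreq(wave.size, 1 / SR)[spec.argmax()]
        # the strongest partial is some k*600; fundamental spacing holds
        assert peak_hz % 600.0 < 6.0 or 600.0 - (peak_hz % 600.0) < 6.0
        S = spectrogram(wave, SR)
        from finchsong import pitch_and_goodness
        pitch, _ = pitch_and_goodness(S.power, SR)
        assert pitch == pytest.approx(600.0, rel=0.01)

    def test_pure_noise_entropy_near_flat_limit(self):
        wave = render_syllable(harmonic_spec(noise_fraction=1.0), SR,
                               rng=np.random.default_rng(0))
        S = spectrogram(wave, SR)
        assert wiener_entropy(S.power, S.freqs) >= -0.5

    def test_peak_amplitude_matches_spec(self):
        wave = render_syllable(harmonic_spec(amplitude_db=-12.0), SR)
        assert np.abs(wave).max() == pytest.approx(10 ** (-12 / 20), rel=1e-6)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            render_syllable(harmonic_spec(f0=5000.0, n_harmonics=6), SR)

    def test_sweep_pushing_harmonic_past_nyquist_rejected(self):
        spec = harmonic_spec(f0=5000.0, n_harmonics=4,
                             fm_sweep_hz_per_s=60000.0, duration_ms=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            render_syllable(spec, SR)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="22050"):
            render_syllable(harmonic_spec(), 16000)

    @pytest.mark.parametrize("bad", [
        dict(noise_fraction=1.5),
        dict(duration_ms=0.0),
        dict(n_harmonics=0),
    ])
    def test_invalid_spec_fields_rejected(self, bad):
        with pytest.raises(ValueError):
            harmonic_spec(**bad)

    def test_entropy_strictly_increasing_in_noise_fraction(self):
        entropies = []
        for nf in (0.0, 0.25, 0.5, 0.75, 1.0):
            wave = render_syllable(harmonic_spec(noise_fraction=nf), SR,
                                   rng=np.random.default_rng(5))
            S = spectrogram(wave, SR)
            entropies.append(wiener_entropy(S.power, S.freqs))
        assert all(a < b for a, b in zip(entropies, entropies[1:]))


class TestGenerateBout:
    def test_deterministic_chain_emits_in_order(self):
        syntax = SongSyntax(
            alphabet=["a", "b", "c"],
            chunks=[],
            transition_probs={("a",): {("b",): 1.0}, ("b",): {("c",): 1.0},
                              ("c",): {("a",): 1.0}},
            bout_length_range=(3, 3),
            initial_unit=("a",),
        )
        syllables = {l: harmonic_spec(l, duration_ms=40.0) for l in "abc"}
        _, truth = generate_bout(syntax, syllables, np.random.default_rng(0))
        assert truth.labels == ["a", "b", "c"]

    def test_worked_motif_transitions_are_subset(self, tutor_syntax, tutor_syllables):
        """Realized tutor transitions stay inside the declared syntax graph."""
        allowed = {("a", "b"), ("b", "c"), ("b", "d"), ("c", "d"), ("d", "e"),
                   ("e", "f"), ("f", "g"), ("g", "e"), ("g", "h"), ("h", "i"),
                   ("h", "a"), ("i", "a"), ("i", "e"), ("a", "e")}
        rng = np.random.default_rng(2)
        for _ in range(10):
            _, truth = generate_bout(tutor_syntax, tutor_syllables, rng)
            assert truth.realized_transitions() <= allowed

    def test_two_state_markov_frequencies_recovered(self):
        """Empirical transition frequencies match the matrix (LLN check)."""
        syntax = SongSyntax(
            alphabet=["a", "b"],
            chunks=[],
            transition_probs={("a",): {("a",): 0.7, ("b",): 0.3},
                              ("b",): {("a",): 0.4, ("b",): 0.6}},
            bout_length_range=(10, 10),
            initial_unit=("a",),
        )
        syllables = {l: harmonic_spec(l, duration_ms=20.0, f0=800.0,
                                      n_harmonics=3) for l in "ab"}
        rng = np.random.default_rng(42)
        counts = {("a", "a"): 0, ("a", "b"): 0, ("b", "a"): 0, ("b", "b"): 0}
        for _ in range(1000):
            _, truth = generate_bout(syntax, syllables, rng)
            for pair in zip(truth.labels[:-1], truth.labels[1:]):
                counts[pair] += 1
        from_a = counts[("a", "a")] + counts[("a", "b")]
        from_b = counts[("b", "a")] + counts[("b", "b")]
        assert counts[("a", "a")] / from_a == pytest.approx(0.7, abs=0.03)
        assert counts[("b", "b")] / from_b == pytest.approx(0.6, abs=0.03)

    def test_unreachable_unit_raises_naming_it(self):
        syntax = SongSyntax(
            alphabet=["a", "b", "z"],
            chunks=[],
            transition_probs={("a",): {("b",): 1.0}, ("b",): {("a",): 1.0},
                              ("z",): {("a",): 1.0}},
            bout_length_range=(3, 3),
            initial_unit=("a",),
        )
        syllables = {l: harmonic_spec(l, duration_ms=40.0) for l in "abz"}
        with pytest.raises(SongSyntaxError, match="z"):
            generate_bout(syntax, syllables, np.random.default_rng(0))

    def test_ground_truth_is_consistent(self, tutor_bout):
        audio, truth = tutor_bout
        assert np.all(truth.offsets_s > truth.onsets_s)
        assert np.all(truth.onsets_s[1:] > truth.offsets_s[:-1])
        assert truth.offsets_s[-1] < audio.duration_s
        # intro notes are flagged and precede all song notes
        flags = truth.intro
        assert not np.any(flags[np.argmin(flags):])

    def test_invalid_transition_row_rejected(self):
        with pytest.raises(SongSyntaxError, match="sums to"):
            SongSyntax(alphabet=["a"], chunks=[],
                       transition_probs={("a",): {("a",): 0.9}})


class TestDerivePupil:
    def test_perfect_copy_is_identity(self, tutor_syntax, tutor_syllables):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=1.0)
        syntax, syllables, acquired = derive_pupil(spec, np.random.default_rng(0))
        assert acquired == set(tutor_syntax.song_labels())
        assert syntax.transition_probs == tutor_syntax.transition_probs
        assert syllables == tutor_syllables

    def test_acquired_count_matches_binomial_expectation(
        self, tutor_syntax, tutor_syllables
    ):
        """Mean acquired types over many seeds ~ 9 * note_copy_prob."""
        counts = []
        for s in range(10000):
            spec = TutorPupilSpec(tutor_syntax, tutor_syllables,
                                  note_copy_prob=0.5, seed=s)
            try:
                _, _, acquired = derive_pupil(spec, np.random.default_rng(s))
            except SongSyntaxError:
                continue  # zero-acquisition draws are rejected by contract
            counts.append(len(acquired))
        assert np.mean(counts) == pytest.approx(4.5, abs=0.1)

    def test_reuse_policy_eliminates_unacquired_labels(
        self, tutor_syntax, tutor_syllables
    ):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables,
                              note_copy_prob=0.4, seed=11)
        rng = np.random.default_rng(11)
        syntax, syllables, acquired = derive_pupil(spec, rng)
        unacquired = set(tutor_syntax.song_labels()) - acquired
        for _ in range(5):
            _, truth = generate_bout(syntax, syllables, rng)
            assert not (set(truth.song_labels()) & unacquired)

    def test_zero_acquisition_raises(self, tutor_syntax, tutor_syllables):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=0.0)
        with pytest.raises(SongSyntaxError, match="zero"):
            derive_pupil(spec, np.random.default_rng(0))

    def test_entropy_shift_degrades_acquired_notes(
        self, tutor_syntax, tutor_syllables
    ):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=1.0,
                              entropy_shift=0.3)
        _, syllables, acquired = derive_pupil(spec, np.random.default_rng(0))
        for label in acquired:
            assert syllables[label].noise_fraction == pytest.approx(
                min(1.0, tutor_syllables[label].noise_fraction + 0.3)
            )

    def test_rewired_syntax_rows_still_sum_to_one(
        self, tutor_syntax, tutor_syllables
    ):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=0.7,
                              transition_rewire_prob=0.5, seed=3)
        syntax, _, _ = derive_pupil(spec, np.random.default_rng(3))
        for row in syntax.transition_probs.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)


class TestWriteDataset:
    def test_file_counts_and_manifest(self, tmp_path, tutor_syntax, tutor_syllables):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=0.8,
                              seed=5)
        manifest = write_dataset(spec, 3, tmp_path, role="pupil")
        assert len(manifest["files"]) == 3
        assert len(list(tmp_path.glob("*.wav"))) == 3
        assert len(list(tmp_path.glob("*bout*.txt"))) == 3
        assert (tmp_path / "manifest.json").exists()

    def test_wav_is_16bit_44100(self, tmp_path, tutor_syntax, tutor_syllables):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, seed=5)
        manifest = write_dataset(spec, 1, tmp_path, role="tutor")
        sr, data = wavfile.read(tmp_path / manifest["files"][0]["wav"])
        assert sr == 44100
        assert data.dtype == np.int16

    def test_same_spec_and_seed_is_byte_identical(
        self, tmp_path, tutor_syntax, tutor_syllables
    ):
        spec = TutorPupilSpec(tutor_syntax, tutor_syllables, note_copy_prob=0.8,
                              entropy_shift=0.2, seed=9)
        m1 = write_dataset(spec, 2, tmp_path / "run1", role="pupil")
        m2 = write_dataset(spec, 2, tmp_path / "run2", role="pupil")
        for e1, e2 in zip(m1["files"], m2["files"]):
            b1 = (tmp_path / "run1" / e1["wav"]).read_bytes()
            b2 = (tmp_path / "run2" / e2["wav"]).read_bytes()
            assert b1 == b2

    def test_ground_truth_validation_rejects_overlap(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            GroundTruth(np.array([0.0, 0.05]), np.array([0.06, 0.1]),
                        ["a", "b"], np.array([False, False]))
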