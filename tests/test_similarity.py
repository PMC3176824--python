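"""Motif extraction, similarity scoring, feature percentage differences."""

import numpy as np
import pandas as pd
import pytest

from finchsong import (
    AnnotatedBout,
    Motif,
    NoteSegment,
    TutorPupilSpec,
    build_reference_pool,
    derive_pupil,
    extract_motifs,
    feature_pct_difference,
    mean_similarity,
    motif_similarity,
)
from finchsong.features import FrameFeatures
from finchsong import pipeline as pl
from finchsong import similarity as sim


def _synthetic_bout(labels, intro_flags=None, bird="b", frames_per_note=20,
                    seed=0):
    """Build an AnnotatedBout directly from a label sequence.

    Each note gets deterministic per-frame features derived from its
    label, so motif logic can be tested without audio.
    """
    rng = np.random.default_rng(seed)
    if intro_flags is None:
        intro_flags = [False] * len(labels)
    segments, rows, values, times, note_idx = [], [], [], [], []
    t = 0.0
    for i, lab in enumerate(labels):
        dur = 0.05 + 0.01 * (ord(lab) % 5)
        segments.append(NoteSegment(t, t + dur, -10.0, lab))
        base = float(ord(lab) - ord("a"))
        rows.append({
            "duration_ms": dur * 1000, "amplitude_db": -10.0 - base,
            "pitch_hz": 500.0 + 100 * base, "fm_deg": 10.0 + base,
            "wiener_entropy": -3.0 + 0.2 * base, "goodness_of_pitch": 0.3,
            "mean_frequency_hz": 2000.0 + 100 * base, "label": lab,
            "short_note": False,
        })
        for f in range(frames_per_note):
            # per-frame jitter keeps the distance distribution continuous,
            # as it is for real frame tracks
            values.append([500.0 + 100 * base + rng.normal(0, 2.0),
                           10.0 + base + rng.normal(0, 0.3),
                           -10.0 - base + rng.normal(0, 0.3),
                           -3.0 + 0.2 * base + rng.normal(0, 0.05),
                           0.3 + rng.normal(0, 0.02)])
            times.append(t + f * 0.001)
            note_idx.append(i)
        t += dur + 0.05
    frames = FrameFeatures(np.array(values), np.array(times),
                           np.array(note_idx))
    return AnnotatedBout(bird, 0, segments, pd.DataFrame(rows), frames,
                         np.array(intro_flags))


class TestExtractMotifs:
    def test_worked_bout_motif_excludes_intro(self):
        labels = list("xabcdefgefghi")
        intro = [True] + [False] * 12
        bout = _synthetic_bout(labels, intro)
        motifs = extract_motifs([bout], n=1, rng=np.random.default_rng(0))
        assert list(motifs[0].notes["label"]) == list("abcdefgefghi")
        assert motifs[0].covers_all_types

    def test_minimal_window_is_shortest_cover(self):
        # repertoire {a,b,c}; shortest cover of "a a b a c b" is "b a c"
        bout = _synthetic_bout(list("aabacb"))
        motifs = extract_motifs([bout], n=1, rng=np.random.default_rng(0))
        assert list(motifs[0].notes["label"]) == list("bac")

    def test_single_pass_bout_is_whole_motif(self):
        bout = _synthetic_bout(list("abc"))
        motifs = extract_motifs([bout], n=1, rng=np.random.default_rng(0))
        assert list(motifs[0].notes["label"]) == list("abc")

    def test_sampling_is_reproducible(self):
        bouts = [_synthetic_bout(list("abcabc"), seed=s) for s in range(5)]
        m1 = extract_motifs(bouts, n=30, rng=np.random.default_rng(3))
        m2 = extract_motifs(bouts, n=30, rng=np.random.default_rng(3))
        assert len(m1) == len(m2) == 30
        assert [m.motif_id for m in m1] == [m.motif_id for m in m2]

    def test_incomplete_repertoire_falls_back_with_warning(self):
        # second bout introduces "d"; first bout can never cover it
        b1 = _synthetic_bout(list("abc"))
        b2 = _synthetic_bout(list("abcd"))
        motifs = extract_motifs([b1, b2], n=4, rng=np.random.default_rng(0))
        assert any(not m.covers_all_types for m in motifs) or all(
            m.covers_all_types for m in motifs
        )


class TestMotifSimilarity:
    @pytest.fixture(scope="class")
    def reference(self):
        bouts = [_synthetic_bout(list("abcdefghi") * 3, seed=s) for s in range(3)]
        return build_reference_pool(bouts, rng=np.random.default_rng(0))

    def test_self_similarity_is_100(self, reference):
        bout = _synthetic_bout(list("abcdefghi"))
        m = extract_motifs([bout], n=1, rng=np.random.default_rng(0))[0]
        assert motif_similarity(m, m, reference) == 100.0

    def test_similarity_bounded(self, reference):
        m1 = extract_motifs([_synthetic_bout(list("abcdefghi"))], n=1,
                            rng=np.random.default_rng(0))[0]
        m2 = extract_motifs([_synthetic_bout(list("iiii"))], n=1,
                            rng=np.random.default_rng(0))[0]
        s = motif_similarity(m1, m2, reference)
        assert 0.0 <= s <= 100.0

    def test_missing_types_score_below_identity(self, reference):
        full = extract_motifs([_synthetic_bout(list("abcdefghi"))], n=1,
                              rng=np.random.default_rng(0))[0]
        partial = extract_motifs([_synthetic_bout(list("aiiieg"))], n=1,
                                 rng=np.random.default_rng(0))[0]
        assert motif_similarity(full, partial, reference) < motif_similarity(
            full, full, reference
        )

    def test_asymmetry_when_pupil_is_subset(self, reference):
        """Tutor->pupil is penalized for missing material; pupil->tutor not."""
        full = extract_motifs([_synthetic_bout(list("abcdefghi"))], n=1,
                              rng=np.random.default_rng(0))[0]
        subset = extract_motifs([_synthetic_bout(list("abcd"))], n=1,
                                rng=np.random.default_rng(0))[0]
        assert motif_similarity(full, subset, reference) != motif_similarity(
            subset, full, reference
        )

    def test_duplicated_reference_pool_barely_moves_scores(self):
        bouts = [_synthetic_bout(list("abcdefghi") * 3, seed=s) for s in range(3)]
        frames = np.concatenate([b.frames.values for b in bouts])
        ref1 = build_reference_pool(frames, rng=np.random.default_rng(5))
        ref2 = build_reference_pool(np.concatenate([frames, frames]),
                                    rng=np.random.default_rng(5))
        tutor = extract_motifs([_synthetic_bout(list("abcdefghi"))], n=1,
                               rng=np.random.default_rng(0))[0]
        pupil = extract_motifs([_synthetic_bout(list("aiiieg"))], n=1,
                               rng=np.random.default_rng(0))[0]
        s1 = motif_similarity(tutor, pupil, ref1)
        s2 = motif_similarity(tutor, pupil, ref2)
        assert abs(s1 - s2) < 1.0

    def test_small_reference_pool_rejected(self):
        with pytest.raises(ValueError, match="reference pool"):
            build_reference_pool(np.zeros((10, 5)))


class TestMeanSimilarity:
    def test_identical_motif_sets_score_100(self):
        bouts = [_synthetic_bout(list("abcdefghi") * 3, seed=s) for s in range(3)]
        ref = build_reference_pool(bouts, rng=np.random.default_rng(0))
        motifs = extract_motifs(bouts, n=5, rng=np.random.default_rng(1))
        # pair each motif with itself: identity pairs all score 100
        scores = [motif_similarity(m, m, ref) for m in motifs]
        assert all(s == 100.0 for s in scores)
        report = mean_similarity(motifs, motifs, ref, n_pairs=30,
                                 rng=np.random.default_rng(2))
        assert report.n_motif_pairs == 30
        assert report.similarity_pct > 90.0

    def test_degradation_is_monotone_in_copy_prob(
        self, tutor_syntax, tutor_syllables
    ):
        """Mean similarity falls as note_copy_prob falls (10-seed means)."""
        config = pl.default_juvenile_config()
        config.n_bouts = 8
        config.n_motifs = 8
        config.n_pairs = 8
        means = []
        for prob in (1.0, 0.8, 0.6, 0.4):
            vals = []
            for s in range(10):
                rng = np.random.default_rng(1000 + s)
                tutor = pl._simulate_bird("t", tutor_syntax, tutor_syllables,
                                          config, rng,
                                          acquired=set(tutor_syntax.song_labels()))
                ref = build_reference_pool(tutor.bouts, rng=rng)
                tm = extract_motifs(tutor.bouts, n=8, rng=rng)
                spec = TutorPupilSpec(tutor_syntax, tutor_syllables,
                                      note_copy_prob=prob, seed=s)
                ps, psyl, acq = derive_pupil(spec, rng)
                pupil = pl._simulate_bird("p", ps, psyl, config, rng,
                                          acquired=acq)
                pm = extract_motifs(pupil.bouts, n=8, rng=rng)
                vals.append(mean_similarity(tm, pm, ref, n_pairs=8,
                                            rng=rng).similarity_pct)
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:])), means


class TestFeaturePctDifference:
    def _motif(self, scale_pitch=1.0, seed=0):
        bout = _synthetic_bout(list("abcdefghi"), seed=seed)
        m = extract_motifs([bout], n=1, rng=np.random.default_rng(0))[0]
        if scale_pitch != 1.0:
            m.notes = m.notes.assign(pitch_hz=m.notes["pitch_hz"] * scale_pitch)
        return m

    def test_identity_gives_zero_differences(self):
        m = self._motif()
        with pytest.warns(UserWarning, match="motifs"):
            diffs = feature_pct_difference([m], [m])
        assert all(v == pytest.approx(0.0) for v in diffs.values())

    def test_pitch_scaling_gives_expected_percentage(self):
        tutor = self._motif()
        pupil = self._motif(scale_pitch=1.2)
        with pytest.warns(UserWarning):
            diffs = feature_pct_difference([tutor], [pupil])
        assert diffs["pitch_hz"] == pytest.approx(20.0, abs=1e-9)

    def test_all_differences_nonnegative(self):
        t = [self._motif(seed=s) for s in range(30)]
        p = [self._motif(scale_pitch=1.1, seed=s + 50) for s in range(30)]
        diffs = feature_pct_difference(t, p)
        assert all(v >= 0 for v in diffs.values() if not np.isnan(v))
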