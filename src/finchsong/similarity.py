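"""Motif extraction and tutor-pupil song similarity scoring.

A *song motif* is the song sequence containing all of a bird's
note types, excluding introductory notes.  Similarity between a tutor
motif and a pupil motif is scored from the five per-frame acoustic
features (pitch, FM, amplitude, Wiener entropy, goodness of pitch) in
an asymmetric, rank-based procedure:

1. every frame of both motifs is z-scored feature-wise against a
   reference frame pool (normally the tutor's whole song);
2. the local distance between a tutor frame and a pupil frame is the
   Euclidean distance in the 5-dimensional z-space;
3. the *local similarity* of an observed distance is the fraction of
   random reference frame-pair distances that exceed it (a rank
   statistic in [0, 1]);
4. the motif score is the percentage of tutor frames whose best
   matching pupil frame — searched within a +/-50 ms relative-position
   window after linear length normalization — has local similarity
   >= 0.5.

Tutor frames are the denominator, so the comparison is asymmetric:
a pupil that sings only half the tutor's material scores low against
the tutor while the reverse comparison may score high.  This is a
SAP-style procedure (five features, asymmetric, percent scale), not a
re-implementation of any proprietary similarity engine; absolute
percentages are comparable only within this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import AnnotatedBout, FEATURE_COLUMNS

__all__ = [
    "Motif",
    "ReferencePool",
    "SimilarityReport",
    "extract_motifs",
    "build_reference_pool",
    "motif_similarity",
    "mean_similarity",
    "feature_pct_difference",
]

MATCH_WINDOW_S = 0.05       # +/- window for frame matching, seconds
LOCAL_SIMILARITY_CUTOFF = 0.5
N_REFERENCE_PAIRS = 2000    # null frame-pair distances sampled from the pool
MIN_REFERENCE_FRAMES = 1000


@dataclass
class Motif:
    """One extracted motif: ordered notes plus per-frame feature track."""

    bird_id: str
    motif_id: int
    notes: pd.DataFrame          # note-level features incl. label
    frames: np.ndarray           # (n_frames, 5) in TRACK_FEATURES order
    frame_times: np.ndarray      # seconds from motif onset
    covers_all_types: bool = True

    def __post_init__(self) -> None:
        if len(self.notes) < 1:
            raise ValueError("a motif must contain at least one note")

    @property
    def duration_s(self) -> float:
        if self.frame_times.size == 0:
            return 0.0
        return float(self.frame_times[-1] - self.frame_times[0])


def _minimal_cover_window(labels: list[str], targets: set[str]) -> tuple[int, int, bool]:
    """Shortest contiguous [i, j) window of ``labels`` covering ``targets``.

    Falls back to the longest-coverage (then shortest) window when no
    window covers every target; the third return value says whether
    full coverage was achieved.
    """
    n = len(labels)
    best: tuple[int, int] | None = None
    counts: dict[str, int] = {}
    have = 0
    i = 0
    for j in range(n):
        lab = labels[j]
        if lab in targets:
            counts[lab] = counts.get(lab, 0) + 1
            if counts[lab] == 1:
                have += 1
        while have == len(targets):
            if best is None or (j + 1 - i) < (best[1] - best[0]):
                best = (i, j + 1)
            lab_i = labels[i]
            if lab_i in targets:
                counts[lab_i] -= 1
                if counts[lab_i] == 0:
                    have -= 1
            i += 1
    if best is not None:
        return best[0], best[1], True
    # fallback: window with maximal distinct coverage, shortest first
    best_cov = 0
    best_win = (0, n)
    for i in range(n):
        seen: set[str] = set()
        for j in range(i, n):
            if labels[j] in targets:
                seen.add(labels[j])
            cov = len(seen)
            if cov > best_cov or (cov == best_cov and (j + 1 - i) < (best_win[1] - best_win[0])):
                best_cov = cov
                best_win = (i, j + 1)
    return best_win[0], best_win[1], False


def extract_motifs(
    bouts: list[AnnotatedBout],
    n: int = 30,
    rng: np.random.Generator | None = None,
) -> list[Motif]:
    """Sample ``n`` motifs from a bird's labeled bouts.

    Within each bout the candidate motif is the shortest contiguous
    note window containing every non-introductory note type in the
    bird's repertoire (union over all bouts); introductory notes are
    excluded.  Bouts that never cover the full repertoire contribute
    their longest-coverage window, flagged via
    ``covers_all_types=False``.  ``n`` candidates are sampled with
    replacement when fewer exist.
    """
    if not bouts:
        raise ValueError("extract_motifs requires at least one bout")
    if rng is None:
        rng = np.random.default_rng(0)
    repertoire: set[str] = set()
    for bout in bouts:
        repertoire.update(bout.song_label_sequence())
    repertoire.discard("?")
    if not repertoire:
        raise ValueError("bouts carry no labeled song notes")

    candidates: list[Motif] = []
    for bout in bouts:
        keep = [i for i, fl in enumerate(bout.intro) if not fl]
        labels = [bout.segments[i].label or "?" for i in keep]
        if not labels:
            continue
        i0, i1, full = _minimal_cover_window(labels, repertoire)
        note_idx = keep[i0:i1]
        frame_sel = np.isin(bout.frames.note_index, note_idx)
        frames = bout.frames.values[frame_sel]
        times = bout.frames.times[frame_sel]
        t0 = times[0] if times.size else 0.0
        candidates.append(
            Motif(
                bird_id=bout.bird_id,
                motif_id=len(candidates),
                notes=bout.notes.iloc[note_idx].reset_index(drop=True),
                frames=frames,
                frame_times=times - t0,
                covers_all_types=full,
            )
        )
    if not candidates:
        raise ValueError("no motif candidates found")
    if not any(m.covers_all_types for m in candidates):
        warnings.warn(
            "no bout contains every note type; using longest-coverage windows"
        )
    replace = len(candidates) < n
    idx = rng.choice(len(candidates), size=n, replace=replace)
    return [candidates[i] for i in idx]


@dataclass
class ReferencePool:
    """Frame pool defining the z-space and the null distance distribution."""

    mean: np.ndarray
    std: np.ndarray
    null_distances: np.ndarray   # sorted

    def zscore(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.mean) / self.std

    def local_similarity(self, distances: np.ndarray) -> np.ndarray:
        """Fraction of reference frame-pair distances exceeding each value."""
        ranks = np.searchsorted(self.null_distances, distances, side="left")
        return 1.0 - ranks / self.null_distances.size

    @property
    def match_distance(self) -> float:
        """Distance at which local similarity drops below the 0.5 cutoff."""
        return float(np.quantile(self.null_distances, LOCAL_SIMILARITY_CUTOFF))


def build_reference_pool(
    bouts: list[AnnotatedBout] | np.ndarray,
    rng: np.random.Generator | None = None,
    n_pairs: int = N_REFERENCE_PAIRS,
) -> ReferencePool:
    """Build the z-scoring and null-distance reference from a frame pool.

    Accepts annotated bouts (their note frames are pooled) or a raw
    (n, 5) frame array.  Requires at least 1000 frames so that the
    null distance distribution is well populated.
    """
    if isinstance(bouts, np.ndarray):
        frames = bouts
    else:
        if not bouts:
            raise ValueError("empty reference pool")
        frames = np.concatenate([b.frames.values for b in bouts], axis=0)
    if frames.shape[0] < MIN_REFERENCE_FRAMES:
        raise ValueError(
            f"reference pool has {frames.shape[0]} frames; "
            f">= {MIN_REFERENCE_FRAMES} required"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    mean = frames.mean(axis=0)
    std = frames.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    z = (frames - mean) / std
    i = rng.integers(frames.shape[0], size=n_pairs)
    j = rng.integers(frames.shape[0], size=n_pairs)
    dist = np.sqrt(((z[i] - z[j]) ** 2).sum(axis=1))
    return ReferencePool(mean=mean, std=std, null_distances=np.sort(dist))


def motif_similarity(
    tutor: Motif,
    pupil: Motif,
    reference: ReferencePool,
    window_s: float = MATCH_WINDOW_S,
) -> float:
    """Asymmetric percent similarity of a pupil motif to a tutor motif.

    Returns the percentage of tutor frames (the denominator — hence
    asymmetric) whose best-matching pupil frame within a ``window_s``
    relative-position window (after linearly normalizing the pupil
    motif to the tutor's length) has local similarity >= 0.5.
    """
    zt = reference.zscore(tutor.frames)
    zp = reference.zscore(pupil.frames)
    if zt.shape[0] == 0 or zp.shape[0] == 0:
        raise ValueError("motifs must contain at least one frame")
    t_t = tutor.frame_times
    # linear length normalization: map pupil frame times onto tutor time
    p_dur = pupil.frame_times[-1] if pupil.frame_times[-1] > 0 else 1.0
    t_dur = t_t[-1] if t_t[-1] > 0 else 1.0
    t_p = pupil.frame_times * (t_dur / p_dur)

    cutoff = reference.match_distance
    matched = 0
    # pupil frames are time-sorted; walk the window with searchsorted
    lo = np.searchsorted(t_p, t_t - window_s, side="left")
    hi = np.searchsorted(t_p, t_t + window_s, side="right")
    for i in range(zt.shape[0]):
        a, b = lo[i], hi[i]
        if a >= b:
            continue
        d2 = ((zp[a:b] - zt[i]) ** 2).sum(axis=1)
        if d2.min() <= cutoff * cutoff:
            matched += 1
    return 100.0 * matched / zt.shape[0]


@dataclass
class SimilarityReport:
    """Mean percent similarity over sampled motif pairs."""

    similarity_pct: float
    n_motif_pairs: int
    pair_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_pct <= 100.0:
            raise ValueError("similarity_pct must lie in [0, 100]")


def mean_similarity(
    tutor_motifs: list[Motif],
    pupil_motifs: list[Motif],
    reference: ReferencePool,
    n_pairs: int = 30,
    rng: np.random.Generator | None = None,
) -> SimilarityReport:
    """Score ``n_pairs`` random (tutor, pupil) motif pairings; report the mean."""
    if not tutor_motifs or not pupil_motifs:
        raise ValueError("need at least one motif on each side")
    if rng is None:
        rng = np.random.default_rng(0)
    ti = rng.choice(len(tutor_motifs), size=n_pairs,
                    replace=len(tutor_motifs) < n_pairs)
    pi = rng.choice(len(pupil_motifs), size=n_pairs,
                    replace=len(pupil_motifs) < n_pairs)
    scores = np.array(
        [motif_similarity(tutor_motifs[a], pupil_motifs[b], reference)
         for a, b in zip(ti, pi)]
    )
    return SimilarityReport(float(scores.mean()), int(n_pairs), scores)


def feature_pct_difference(
    tutor_motifs: list[Motif],
    pupil_motifs: list[Motif],
) -> dict[str, float]:
    """Per-feature percentage difference between pupil and tutor motifs.

    For each of the seven note features ``f``:
    ``100 * |median_f(pupil notes) - median_f(tutor notes)| /
    |median_f(tutor notes)|``, with notes pooled across the supplied
    motifs.  A zero tutor median makes the difference undefined; it
    is reported as NaN.  Fewer than 30 motifs on either side is
    allowed but flagged with a warning.
    """
    if len(tutor_motifs) < 30 or len(pupil_motifs) < 30:
        warnings.warn(
            f"feature_pct_difference computed from {len(tutor_motifs)} tutor / "
            f"{len(pupil_motifs)} pupil motifs (30 expected)"
        )
    tutor_notes = pd.concat([m.notes for m in tutor_motifs], ignore_index=True)
    pupil_notes = pd.concat([m.notes for m in pupil_motifs], ignore_index=True)
    report: dict[str, float] = {}
    for col in FEATURE_COLUMNS:
        mt = float(tutor_notes[col].median())
        mp = float(pupil_notes[col].median())
        if mt == 0.0:
            report[col] = float("nan")
        else:
            report[col] = 100.0 * abs(mp - mt) / abs(mt)
    return report
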