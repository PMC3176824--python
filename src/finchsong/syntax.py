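"""Song syntax metrics: note labeling, transition matrices, copy rates.

Bouts are translated into alphabet sequences (one letter per note
type).  The transition probability matrix counts adjacent within-bout
note pairs; its *transition types* are the (from, to) pairs holding at
least 5% of all transitions (rarer ones are neglected as one-off
variants).  Imitation fidelity is then summarized by two percentages:

* song-note copy rate — share of tutor note types that appear in the
  pupil's song;
* transition copy rate — share of tutor transition types reproduced
  by the pupil (both sides pruned at the same 5% threshold).

The 5% pruning is applied to the global share of all transitions by
default; a row-conditional mode is available via ``conditional=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .segmentation import NoteSegment
from .synthetic import GroundTruth

__all__ = [
    "TransitionMatrix",
    "CopyRateReport",
    "NoteLabeler",
    "oracle_labels",
    "label_notes",
    "transition_matrix",
    "transition_types",
    "note_copy_rate",
    "transition_copy_rate",
    "copy_rate_report",
    "read_bout_sequences",
    "write_bout_sequences",
]

DEFAULT_MIN_TRANSITION_PROB = 0.05

#: note features used for cluster-mode labeling
LABELING_FEATURES = ["duration_ms", "wiener_entropy", "pitch_hz", "mean_frequency_hz"]


# ---------------------------------------------------------------------------
# labeling

def oracle_labels(
    segments: Sequence[NoteSegment], truth: GroundTruth
) -> list[str]:
    """Label segmented notes from generator ground truth by best overlap.

    Each segment receives the label of the ground-truth note with the
    largest temporal overlap; segments overlapping nothing get "?".
    """
    labels: list[str] = []
    for seg in segments:
        overlaps = np.minimum(seg.offset_s, truth.offsets_s) - np.maximum(
            seg.onset_s, truth.onsets_s
        )
        if overlaps.size == 0 or overlaps.max() <= 0:
            labels.append("?")
        else:
            labels.append(truth.labels[int(np.argmax(overlaps))])
    return labels


class NoteLabeler:
    """K-means note-type labeler in standardized feature space.

    Fit on the tutor's notes; pupil notes are then assigned the label
    of the nearest tutor centroid, which matches pupil clusters to
    tutor clusters by centroid proximity (the automated counterpart of
    labeling note types by visual inspection with a shared alphabet).
    """

    def __init__(self, k: int, random_state: int = 0) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.random_state = random_state
        self._mean: np.ndarray | None = None
        self._std: np.ndarray | None = None
        self._centroids: np.ndarray | None = None

    def _standardize(self, features: pd.DataFrame) -> np.ndarray:
        x = features[LABELING_FEATURES].to_numpy(dtype=np.float64)
        if self._mean is None:
            self._mean = x.mean(axis=0)
            std = x.std(axis=0)
            self._std = np.where(std < 1e-12, 1.0, std)
        return (x - self._mean) / self._std

    def fit(self, features: pd.DataFrame) -> list[str]:
        """Cluster the (tutor) notes and return their labels."""
        if self.k > len(features):
            raise ValueError(f"k={self.k} exceeds the {len(features)} notes available")
        z = self._standardize(features)
        km = KMeans(n_clusters=self.k, n_init=10, random_state=self.random_state)
        assignments = km.fit_predict(z)
        self._centroids = km.cluster_centers_
        return [chr(ord("a") + int(c)) for c in assignments]

    def transform(self, features: pd.DataFrame) -> list[str]:
        """Assign each (pupil) note the label of the nearest tutor centroid."""
        if self._centroids is None:
            raise RuntimeError("labeler must be fit on tutor notes first")
        z = self._standardize(features)
        d2 = ((z[:, None, :] - self._centroids[None, :, :]) ** 2).sum(axis=2)
        return [chr(ord("a") + int(c)) for c in d2.argmin(axis=1)]


def label_notes(
    features: pd.DataFrame,
    mode: str = "cluster",
    k: int | None = None,
    truth_labels: Sequence[str] | None = None,
) -> list[str]:
    """Label one bird's notes, by generator oracle or by clustering.

    ``mode="oracle"`` copies the supplied ground-truth labels;
    ``mode="cluster"`` runs k-means on standardized duration, Wiener
    entropy, pitch, and mean frequency.  For tutor-pupil labeling with
    a shared alphabet use :class:`NoteLabeler` directly.
    """
    if mode == "oracle":
        if truth_labels is None:
            raise ValueError("oracle mode requires truth_labels")
        if len(truth_labels) != len(features):
            raise ValueError("truth_labels length must match the note count")
        return list(truth_labels)
    if mode == "cluster":
        if k is None:
            raise ValueError("cluster mode requires k")
        return NoteLabeler(k).fit(features)
    raise ValueError(f"unknown labeling mode {mode!r}")


# ---------------------------------------------------------------------------
# transition machinery

@dataclass
class TransitionMatrix:
    """Within-bout adjacent-pair counts and global transition probabilities."""

    alphabet: list[str]
    counts: np.ndarray       # (k, k) int, counts[i, j] = #(alphabet[i] -> alphabet[j])
    probs: np.ndarray        # counts / total transitions (sums to 1 overall)
    n_bouts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.alphabet, columns=self.alphabet)

    def conditional_probs(self) -> np.ndarray:
        """Row-normalized (next-note given current-note) probabilities."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(row_sums > 0, self.counts / row_sums, 0.0)
        return cond


def transition_matrix(bouts: Iterable[Sequence[str]]) -> TransitionMatrix:
    """Count adjacent within-bout label pairs and normalize globally.

    Pairs never span bout boundaries.  If every bout has length one
    there are no transitions; an empty (all-zero) matrix is returned
    with a warning.
    """
    bouts = [list(b) for b in bouts]
    if not bouts:
        raise ValueError("transition_matrix requires at least one bout")
    alphabet = sorted({lab for bout in bouts for lab in bout})
    index = {lab: i for i, lab in enumerate(alphabet)}
    k = len(alphabet)
    counts = np.zeros((k, k), dtype=np.int64)
    for bout in bouts:
        for a, b in zip(bout[:-1], bout[1:]):
            counts[index[a], index[b]] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no transitions found (all bouts have length 1)")
        probs = np.zeros_like(counts, dtype=np.float64)
    else:
        probs = counts / total
    return TransitionMatrix(alphabet, counts, probs, n_bouts=len(bouts))


def transition_types(
    tm: TransitionMatrix,
    min_prob: float = DEFAULT_MIN_TRANSITION_PROB,
    conditional: bool = False,
) -> set[tuple[str, str]]:
    """Transition types: (from, to) pairs at or above ``min_prob``.

    ``min_prob=0`` keeps every observed transition.  With
    ``conditional=True`` the threshold applies to row-conditional
    probabilities instead of the global share of all transitions.
    """
    probs = tm.conditional_probs() if conditional else tm.probs
    if min_prob <= 0:
        mask = tm.counts > 0
    else:
        mask = probs >= min_prob
    out: set[tuple[str, str]] = set()
    for i, j in zip(*np.nonzero(mask)):
        if tm.counts[i, j] > 0:
            out.add((tm.alphabet[i], tm.alphabet[j]))
    return out


# ---------------------------------------------------------------------------
# copy rates

def _note_types(bouts: Iterable[Sequence[str]]) -> set[str]:
    return {lab for bout in bouts for lab in bout}


def note_copy_rate(
    tutor_bouts: Iterable[Sequence[str]],
    pupil_bouts: Iterable[Sequence[str]],
) -> float:
    """Percentage of tutor note types appearing anywhere in the pupil's song."""
    tutor_types = _note_types(tutor_bouts)
    if not tutor_types:
        raise ValueError("tutor bouts contain no note types")
    pupil_types = _note_types(pupil_bouts)
    return 100.0 * len(tutor_types & pupil_types) / len(tutor_types)


def transition_copy_rate(
    tutor_bouts: Iterable[Sequence[str]],
    pupil_bouts: Iterable[Sequence[str]],
    min_prob: float = DEFAULT_MIN_TRANSITION_PROB,
    conditional: bool = False,
) -> float:
    """Percentage of tutor transition types reproduced by the pupil.

    Both birds' transition sets are pruned at the same ``min_prob``
    before intersecting (symmetric treatment avoids inflating the
    rate with one-off pupil transitions).
    """
    tutor_bouts = [list(b) for b in tutor_bouts]
    pupil_bouts = [list(b) for b in pupil_bouts]
    tutor_set = transition_types(transition_matrix(tutor_bouts), min_prob, conditional)
    if not tutor_set:
        raise ValueError(
            f"tutor has no transition types at min_prob={min_prob}"
        )
    pupil_set = transition_types(transition_matrix(pupil_bouts), min_prob, conditional)
    return 100.0 * len(tutor_set & pupil_set) / len(tutor_set)


@dataclass
class CopyRateReport:
    """Song-note and transition copy rates with their raw type counts."""

    note_copy_rate_pct: float
    transition_copy_rate_pct: float
    tutor_note_types: int
    copied_note_types: int
    tutor_transition_types: int
    copied_transition_types: int

    def __post_init__(self) -> None:
        for rate in (self.note_copy_rate_pct, self.transition_copy_rate_pct):
            if not 0.0 <= rate <= 100.0:
                raise ValueError("copy rates must lie in [0, 100]")
        if self.copied_note_types > self.tutor_note_types:
            raise ValueError("copied note types cannot exceed tutor note types")
        if self.copied_transition_types > self.tutor_transition_types:
            raise ValueError("copied transition types cannot exceed tutor's")


def copy_rate_report(
    tutor_bouts: Iterable[Sequence[str]],
    pupil_bouts: Iterable[Sequence[str]],
    min_prob: float = DEFAULT_MIN_TRANSITION_PROB,
    conditional: bool = False,
) -> CopyRateReport:
    """Compute both copy rates and the underlying type counts."""
    tutor_bouts = [list(b) for b in tutor_bouts]
    pupil_bouts = [list(b) for b in pupil_bouts]
    tutor_types = _note_types(tutor_bouts)
    pupil_types = _note_types(pupil_bouts)
    tutor_trans = transition_types(transition_matrix(tutor_bouts), min_prob, conditional)
    pupil_trans = transition_types(transition_matrix(pupil_bouts), min_prob, conditional)
    shared_trans = tutor_trans & pupil_trans
    return CopyRateReport(
        note_copy_rate_pct=100.0 * len(tutor_types & pupil_types) / len(tutor_types),
        transition_copy_rate_pct=(
            100.0 * len(shared_trans) / len(tutor_trans) if tutor_trans else 0.0
        ),
        tutor_note_types=len(tutor_types),
        copied_note_types=len(tutor_types & pupil_types),
        tutor_transition_types=len(tutor_trans),
        copied_transition_types=len(shared_trans),
    )


# ---------------------------------------------------------------------------
# plain-text bout sequences (one bout per line, space-separated labels)

def write_bout_sequences(path, bouts: Iterable[Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for bout in bouts:
            fh.write(" ".join(bout) + "\n")


def read_bout_sequences(path) -> list[list[str]]:
    out: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            labels = line.split()
            if labels:
                out.append(labels)
    return out
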