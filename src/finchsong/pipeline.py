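"""End-to-end synthetic tutor-pupil song experiments.

``run_experiment`` reproduces the structure of a virus-injection
song-learning study on fully synthetic data: a tutor song model is
rendered to audio, pupil groups are derived from it with
group-specific imitation-failure parameters (note copy probability,
transition rewiring, entropy shift), every bird's song is then pushed
through the measurement pipeline (segmentation -> features -> motif
similarity, copy rates, feature differences, cluster separation), and
the groups are compared with nonparametric statistics.

The default juvenile design mirrors a control-vs-lesion contrast:

* ``control`` (intact imitation): note_copy_prob 0.95, rewire 0.05,
  no entropy shift;
* ``lesion`` (degraded imitation): note_copy_prob 0.55, rewire 0.30,
  entropy shift 0.25 — pupils drop or substitute harmonic note types,
  scramble transitions, and sing noisier copies.

Randomness is driven by one master seed: per-bird generators are
spawned from ``numpy.random.SeedSequence(master_seed)`` in a fixed
order (tutor first, then groups in declared order, birds in index
order), so any bird's song is reproducible independently of which
other birds are simulated.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation as seg
from . import similarity as sim
from . import stats as st
from . import syntax as syn
from .features import AnnotatedBout, annotate_bout, cluster_separation, feature_map
from .synthetic import (
    GroundTruth,
    SyllableSpec,
    SongSyntax,
    TutorPupilSpec,
    default_tutor_syllables,
    default_tutor_syntax,
    derive_pupil,
    generate_bout,
)

__all__ = [
    "GroupSpec",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "developmental_series",
    "default_juvenile_config",
    "METRICS",
]

#: per-bird metrics computed by run_experiment
METRICS = [
    "similarity_pct",
    "note_copy_rate_pct",
    "transition_copy_rate_pct",
    "pitch_diff_pct",
    "entropy_diff_pct",
    "cluster_separation",
]


@dataclass
class GroupSpec:
    """Imitation parameters shared by all birds of one group."""

    name: str
    n_birds: int
    note_copy_prob: float
    transition_rewire_prob: float = 0.0
    entropy_shift: float = 0.0
    substitution_policy: str = "reuse"


@dataclass
class ExperimentConfig:
    """Full specification of one synthetic experiment."""

    groups: list[GroupSpec]
    design: str = "juvenile"           # "juvenile" (pupils vs tutor) | "adult" (pre vs post)
    n_bouts: int = 30                  # bouts recorded per bird
    n_motifs: int = 30                 # motifs sampled per bird
    n_pairs: int = 30                  # motif pairs scored per comparison
    n_feature_notes: int = 3000        # cap for duration-entropy maps
    min_transition_prob: float = 0.05  # pruning threshold for transition types
    labeling: str = "oracle"           # "oracle" | "cluster"
    threshold_db: float = seg.DEFAULT_THRESHOLD_DB
    min_gap_ms: float = seg.DEFAULT_MIN_GAP_MS
    min_note_ms: float = seg.DEFAULT_MIN_NOTE_MS
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_juvenile_config(seed: int = 0, out_dir: str | None = None) -> ExperimentConfig:
    """The standard two-group juvenile design (8 birds per group)."""
    return ExperimentConfig(
        groups=[
            GroupSpec("control", 8, note_copy_prob=0.95,
                      transition_rewire_prob=0.05, entropy_shift=0.0),
            GroupSpec("lesion", 8, note_copy_prob=0.55,
                      transition_rewire_prob=0.30, entropy_shift=0.25),
        ],
        seed=seed,
        out_dir=out_dir,
    )


def default_adult_config(seed: int = 0, out_dir: str | None = None) -> ExperimentConfig:
    """Three-group adult design: each bird's post-manipulation song is
    compared with its own pre-manipulation song (control, strongly
    affected, and weakly affected groups)."""
    return ExperimentConfig(
        design="adult",
        groups=[
            GroupSpec("control", 7, note_copy_prob=1.0,
                      transition_rewire_prob=0.02, entropy_shift=0.0),
            GroupSpec("high", 5, note_copy_prob=0.6,
                      transition_rewire_prob=0.30, entropy_shift=0.25),
            GroupSpec("low", 9, note_copy_prob=0.95,
                      transition_rewire_prob=0.05, entropy_shift=0.03),
        ],
        seed=seed,
        out_dir=out_dir,
    )


@dataclass
class ExperimentReport:
    """Per-bird metrics, group statistics, and provenance."""

    birds: pd.DataFrame
    group_stats: pd.DataFrame
    config: ExperimentConfig
    config_hash: str

    def group_means(self, metric: str) -> pd.Series:
        return self.birds.groupby("group", sort=False)[metric].mean()


# ---------------------------------------------------------------------------
# simulation of one bird

@dataclass
class _BirdSong:
    """Everything measured from one simulated bird."""

    bird_id: str
    bouts: list[AnnotatedBout]
    label_seqs: list[list[str]]    # intro excluded
    notes: pd.DataFrame
    acquired: set[str]


def _label_segments(
    segments: list[seg.NoteSegment], truth: GroundTruth
) -> np.ndarray:
    """Attach oracle labels to segments in place; return intro flags."""
    labels = syn.oracle_labels(segments, truth)
    intro = np.zeros(len(segments), dtype=bool)
    for i, (s, lab) in enumerate(zip(segments, labels)):
        s.label = lab
        overlaps = np.minimum(s.offset_s, truth.offsets_s) - np.maximum(
            s.onset_s, truth.onsets_s
        )
        if overlaps.size and overlaps.max() > 0:
            intro[i] = bool(truth.intro[int(np.argmax(overlaps))])
    return intro


def _simulate_bird(
    bird_id: str,
    syntax: SongSyntax,
    syllables: dict[str, SyllableSpec],
    config: ExperimentConfig,
    rng: np.random.Generator,
    acquired: set[str] | None = None,
) -> _BirdSong:
    bouts: list[AnnotatedBout] = []
    label_seqs: list[list[str]] = []
    for b in range(config.n_bouts):
        audio, truth = generate_bout(syntax, syllables, rng)
        segments = seg.segment_notes(
            audio,
            threshold_db=config.threshold_db,
            min_gap_ms=config.min_gap_ms,
            min_note_ms=config.min_note_ms,
        )
        intro = _label_segments(segments, truth)
        bout = annotate_bout(audio, segments, bird_id=bird_id, bout_id=b, intro=intro)
        bouts.append(bout)
        label_seqs.append(bout.song_label_sequence())
    notes = pd.concat([b.notes for b in bouts], ignore_index=True)
    if acquired is None:
        acquired = {lab for s in label_seqs for lab in s}
    return _BirdSong(bird_id, bouts, label_seqs, notes, acquired)


def _relabel_by_cluster(tutor: _BirdSong, pupils: list[_BirdSong], k: int) -> None:
    """Replace oracle labels with k-means labels matched across birds."""
    song_mask = ~np.concatenate([b.intro for b in tutor.bouts])
    labeler = syn.NoteLabeler(k)
    tutor_labels = labeler.fit(tutor.notes[song_mask])
    _assign_labels(tutor, tutor_labels)
    for pupil in pupils:
        mask = ~np.concatenate([b.intro for b in pupil.bouts])
        labels = labeler.transform(pupil.notes[mask])
        _assign_labels(pupil, labels)


def _assign_labels(bird: _BirdSong, song_labels: list[str]) -> None:
    it = iter(song_labels)
    bird.label_seqs = []
    for bout in bird.bouts:
        for segment, is_intro in zip(bout.segments, bout.intro):
            if not is_intro:
                segment.label = next(it)
        bout.notes["label"] = [s.label for s in bout.segments]
        bird.label_seqs.append(bout.song_label_sequence())
    bird.notes = pd.concat([b.notes for b in bird.bouts], ignore_index=True)


# ---------------------------------------------------------------------------
# experiment drivers

def _measure_pupil(
    tutor: _BirdSong,
    tutor_motifs: list[sim.Motif],
    reference: sim.ReferencePool,
    pupil: _BirdSong,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    pupil_motifs = sim.extract_motifs(pupil.bouts, n=config.n_motifs, rng=rng)
    report = sim.mean_similarity(
        tutor_motifs, pupil_motifs, reference, n_pairs=config.n_pairs, rng=rng
    )
    rates = syn.copy_rate_report(
        tutor.label_seqs, pupil.label_seqs, min_prob=config.min_transition_prob
    )
    diffs = sim.feature_pct_difference(tutor_motifs, pupil_motifs)
    fmap = feature_map(pupil.notes, cap=config.n_feature_notes, rng=rng,
                       bird_id=pupil.bird_id)
    return {
        "similarity_pct": report.similarity_pct,
        "note_copy_rate_pct": rates.note_copy_rate_pct,
        "transition_copy_rate_pct": rates.transition_copy_rate_pct,
        "pitch_diff_pct": diffs["pitch_hz"],
        "entropy_diff_pct": diffs["wiener_entropy"],
        "cluster_separation": cluster_separation(fmap, k=2),
        "acquired_fraction": len(pupil.acquired & set(tutor.acquired))
        / max(1, len(tutor.acquired)),
    }


def _compare_groups(birds: pd.DataFrame) -> pd.DataFrame:
    """Between-group tests per metric (Mann-Whitney for two groups,
    Kruskal-Wallis omnibus plus Games-Howell pairs for more)."""
    rows: list[dict] = []
    group_names = list(dict.fromkeys(birds["group"]))
    for metric in METRICS:
        samples = [
            st.GroupSample(g, birds.loc[birds["group"] == g, metric].to_numpy())
            for g in group_names
        ]
        if len(samples) < 2:
            continue
        if len(samples) == 2:
            res = st.mann_whitney_u(samples[0], samples[1])
            tests = [res]
        else:
            tests = [st.kruskal_wallis(samples)] + st.games_howell(samples)
        for res in tests:
            rows.append(
                {
                    "metric": metric,
                    "comparison": res.comparison,
                    "method": res.method,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "stars": res.stars,
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full generate -> measure -> compare experiment.

    The tutor song model is shared by every pupil; each pupil is an
    independent draw of the group's imitation-failure process.  Each
    pupil is compared with the tutor on motif similarity, song-note
    and transition copy rates, pitch and entropy percentage
    differences, and duration-entropy cluster separation; groups are
    then compared metric-by-metric.

    In the adult design (``config.design == "adult"``) there is no
    shared tutor: each bird's pre-manipulation song (an independent
    rendition of the tutor model) is the reference its own
    post-manipulation song is measured against, emulating the
    pre-/post-injection comparison of crystallized adult song.
    """
    if not config.groups:
        raise ValueError("config.groups must not be empty")
    if config.design not in ("juvenile", "adult"):
        raise ValueError(f"unknown design {config.design!r}")
    t0 = time.perf_counter()
    log: list[str] = [f"config_hash={config.config_hash()} seed={config.seed}"]
    master = np.random.SeedSequence(config.seed)
    n_birds_total = sum(g.n_birds for g in config.groups)
    children = master.spawn(1 + n_birds_total)
    tutor_rng = np.random.default_rng(children[0])

    tutor_syntax = default_tutor_syntax()
    tutor_syllables = default_tutor_syllables()
    adult = config.design == "adult"
    k_types = len(tutor_syntax.song_labels())
    if not adult:
        tutor = _simulate_bird("tutor", tutor_syntax, tutor_syllables, config,
                               tutor_rng, acquired=set(tutor_syntax.song_labels()))
        reference = sim.build_reference_pool(tutor.bouts, rng=tutor_rng)
        tutor_motifs = sim.extract_motifs(tutor.bouts, n=config.n_motifs,
                                          rng=tutor_rng)
        log.append(
            f"tutor: bouts={len(tutor.bouts)} notes={len(tutor.notes)} "
            f"motifs={len(tutor_motifs)} t={time.perf_counter() - t0:.2f}s"
        )
    else:
        tutor = None

    rows: list[dict] = []
    child_idx = 1
    pupil_songs: list[tuple[GroupSpec, _BirdSong, np.random.Generator]] = []
    for group in config.groups:
        for b in range(group.n_birds):
            rng = np.random.default_rng(children[child_idx])
            child_idx += 1
            spec = TutorPupilSpec(
                tutor_syntax=tutor_syntax,
                tutor_syllables=tutor_syllables,
                note_copy_prob=group.note_copy_prob,
                substitution_policy=group.substitution_policy,
                transition_rewire_prob=group.transition_rewire_prob,
                entropy_shift=group.entropy_shift,
                seed=int(children[child_idx - 1].generate_state(1)[0] % 2**31),
            )
            bird_id = f"{group.name}_{b:02d}"
            if adult:
                # the bird's own crystallized pre-manipulation song is
                # the reference for its post-manipulation song
                pre = _simulate_bird(f"{bird_id}_pre", tutor_syntax,
                                     tutor_syllables, config, rng,
                                     acquired=set(tutor_syntax.song_labels()))
            p_syntax, p_syllables, acquired = derive_pupil(spec, rng)
            pupil = _simulate_bird(bird_id, p_syntax, p_syllables, config, rng,
                                   acquired=acquired)
            pupil_songs.append((group, pupil, rng))
            log.append(
                f"{bird_id}: bouts={len(pupil.bouts)} notes={len(pupil.notes)} "
                f"acquired={len(acquired)} t={time.perf_counter() - t0:.2f}s"
            )
            if adult:
                if config.labeling == "cluster":
                    _relabel_by_cluster(pre, [pupil], k_types)
                reference = sim.build_reference_pool(pre.bouts, rng=rng)
                pre_motifs = sim.extract_motifs(pre.bouts, n=config.n_motifs,
                                                rng=rng)
                metrics = _measure_pupil(pre, pre_motifs, reference, pupil,
                                         config, rng)
                rows.append({"bird": bird_id, "group": group.name, **metrics})
                tutor = pre  # scatter plots show the last pre-song bird

    if not adult:
        if config.labeling == "cluster":
            _relabel_by_cluster(tutor, [p for _, p, _ in pupil_songs], k_types)
        for group, pupil, rng in pupil_songs:
            metrics = _measure_pupil(tutor, tutor_motifs, reference, pupil,
                                     config, rng)
            rows.append({"bird": pupil.bird_id, "group": group.name, **metrics})

    birds = pd.DataFrame(rows)
    group_stats = _compare_groups(birds)
    log.append(f"done: birds={len(birds)} tests={len(group_stats)} "
               f"t={time.perf_counter() - t0:.2f}s")
    report = ExperimentReport(birds, group_stats, config, config.config_hash())
    if config.out_dir is not None:
        _write_outputs(report, tutor, pupil_songs, log)
    return report


def developmental_series(
    config: ExperimentConfig,
    stages: list[tuple[str, dict[str, dict[str, float]]]],
) -> pd.DataFrame:
    """Similarity-to-tutor per bird at successive developmental stages.

    ``stages`` is a list of ``(stage_label, overrides)`` where
    ``overrides`` maps group names to GroupSpec field updates (e.g.
    a rising ``note_copy_prob``).  Bird seeds are reused across
    stages, so each bird is "the same bird recorded later".  Returns
    a tidy frame with per-bird similarity and the per-stage
    between-group Mann-Whitney p-value.
    """
    if len(stages) < 2:
        raise ValueError("developmental_series needs >= 2 stages")
    frames: list[pd.DataFrame] = []
    for stage_label, overrides in stages:
        groups = []
        for g in config.groups:
            upd = overrides.get(g.name, {})
            groups.append(
                GroupSpec(
                    name=g.name,
                    n_birds=g.n_birds,
                    note_copy_prob=upd.get("note_copy_prob", g.note_copy_prob),
                    transition_rewire_prob=upd.get(
                        "transition_rewire_prob", g.transition_rewire_prob
                    ),
                    entropy_shift=upd.get("entropy_shift", g.entropy_shift),
                    substitution_policy=g.substitution_policy,
                )
            )
        stage_config = ExperimentConfig(
            groups=groups,
            design=config.design,
            n_bouts=config.n_bouts,
            n_motifs=config.n_motifs,
            n_pairs=config.n_pairs,
            n_feature_notes=config.n_feature_notes,
            min_transition_prob=config.min_transition_prob,
            labeling=config.labeling,
            threshold_db=config.threshold_db,
            min_gap_ms=config.min_gap_ms,
            min_note_ms=config.min_note_ms,
            seed=config.seed,
            out_dir=None,
        )
        report = run_experiment(stage_config)
        stage_birds = report.birds.copy()
        stage_birds["stage"] = stage_label
        pvals = report.group_stats.query("metric == 'similarity_pct'")["p_value"]
        stage_birds["similarity_group_p"] = float(pvals.iloc[0]) if len(pvals) else float("nan")
        frames.append(stage_birds)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# side outputs (tables and plots; never inputs to any computation)

def _write_outputs(
    report: ExperimentReport,
    tutor: _BirdSong,
    pupil_songs: list[tuple[GroupSpec, _BirdSong, np.random.Generator]],
    log: list[str] | None = None,
) -> None:
    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if log:
        (out / "run.log").write_text("\n".join(log) + "\n")
    header = f"# config_hash: {report.config_hash}\n"
    for name, frame in (("birds.csv", report.birds), ("group_stats.csv", report.group_stats)):
        with open(out / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    with open(out / "config.json", "w") as fh:
        json.dump({"config_hash": report.config_hash, **asdict(report.config)},
                  fh, indent=2, default=str)
    try:
        _write_plots(report, tutor, pupil_songs, out)
    except Exception as exc:  # plots are best-effort side outputs
        (out / "plot_errors.log").write_text(f"{exc}\n")


def _write_plots(report, tutor, pupil_songs, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # duration-entropy scatter, tutor plus one example bird per group
    examples = {"tutor": tutor}
    for group, pupil, _ in pupil_songs:
        examples.setdefault(group.name, pupil)
    fig, axes = plt.subplots(1, len(examples), figsize=(4 * len(examples), 3.2),
                             sharex=True, sharey=True)
    for ax, (name, bird) in zip(np.atleast_1d(axes), examples.items()):
        ax.scatter(bird.notes["duration_ms"], bird.notes["wiener_entropy"],
                   s=4, alpha=0.4)
        ax.set_title(name)
        ax.set_xlabel("duration (ms)")
    np.atleast_1d(axes)[0].set_ylabel("Wiener entropy")
    fig.tight_layout()
    fig.savefig(out / "duration_entropy.png", dpi=110)
    plt.close(fig)

    # group mean +/- SEM bars for each metric
    fig, axes = plt.subplots(2, 3, figsize=(11, 6))
    for ax, metric in zip(axes.ravel(), METRICS):
        stats = report.birds.groupby("group", sort=False)[metric].agg(["mean", "sem"])
        ax.bar(stats.index, stats["mean"], yerr=stats["sem"], capsize=4,
               color=["#4878d0", "#d65f5f"][: len(stats)])
        ax.set_title(metric, fontsize=9)
    fig.tight_layout()
    fig.savefig(out / "group_metrics.png", dpi=110)
    plt.close(fig)
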