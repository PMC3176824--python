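# finchsong

Quantifying how faithfully a pupil songbird imitates its tutor.

Bengalese finches learn their song from a tutor during a juvenile
sensitive period, and experimental manipulations of the song system
(for example, perturbing gene expression in the premotor nucleus RA)
degrade that imitation in characteristic ways: harmonic, low-entropy
song notes drop out of the repertoire, sequence syntax scrambles, and
the duration–entropy clusters of a crystallized song smear out.
`finchsong` implements the complete measurement chain used to
quantify these defects — and a synthetic tutor/pupil song generator
with exact ground truth, so every stage of the chain is testable
without real recordings:

* **generation** — harmonic-stack / broadband notes under a chunked
  first-order Markov syntax; pupils derived from tutors by
  parameterized note-copy failure, label substitution, transition
  rewiring, and spectral degradation;
* **segmentation** — amplitude-threshold note detection over silent
  intervals (a *song note* is a continuous sound element demarcated
  by silence);
* **features** — the seven per-note acoustics used in song analysis:
  duration, amplitude, pitch, frequency modulation (FM), Wiener
  entropy, goodness of pitch (PG), and mean frequency, from a 2-taper
  multitaper spectrogram (9.3-ms window, 1-ms hop);
* **similarity** — asymmetric, rank-based motif similarity on the
  five-feature frame tracks (percentage of tutor frames matched by
  the pupil), plus per-feature percentage differences;
* **syntax** — transition probability matrices over labeled note
  sequences; song-note copy rate (share of tutor note types the
  pupil sings) and transition copy rate (share of tutor transition
  types at ≥ 5% probability the pupil reproduces);
* **statistics** — Mann-Whitney U (exact at small n), Kruskal-Wallis,
  and Games-Howell post-hoc comparisons.

The key quantities, for tutor note types T and pupil note types P:

    note copy rate       = 100 · |T ∩ P| / |T|
    transition copy rate = 100 · |trans(T) ∩ trans(P)| / |trans(T)|,   trans(·) pruned at 5%
    Wiener entropy       = log(geometric mean / arithmetic mean) of spectral power

See `docs/methods.md` for the full model and every numerical choice.

## Worked example

Run the standard juvenile experiment: one synthetic tutor, a control
pupil group (note copy probability 0.95) and a lesion-like group
(0.55, plus transition rewiring and an entropy shift), 8 birds per
group, 30 bouts per bird:

```python
from finchsong import default_juvenile_config, run_experiment
from finchsong.pipeline import METRICS

report = run_experiment(default_juvenile_config(seed=1))
print(report.birds.groupby("group")[METRICS].mean().round(2))
print(report.group_stats[["metric", "p_value", "stars"]])
```

```
         similarity_pct  note_copy_rate_pct  transition_copy_rate_pct  pitch_diff_pct  entropy_diff_pct  cluster_separation
group
control           71.54               95.83                     77.50            3.53              0.36                0.69
lesion            39.26               52.78                     16.25           10.15             53.57                0.49

                  metric   p_value stars
          similarity_pct  0.000939    **
      note_copy_rate_pct  0.000729    **
transition_copy_rate_pct  0.000875    **
          pitch_diff_pct  0.052030    ns
        entropy_diff_pct  0.000939    **
      cluster_separation  0.013587     *
```

Reading the output: control pupils score ~72% motif similarity to the
tutor, sing ~96% of its note types and ~78% of its transition types,
and keep tight duration–entropy clusters (separation 0.69). Lesion
pupils drop to ~39% similarity, copy only half the note types and a
sixth of the transition types, diverge strongly in entropy (54% vs
0.4% difference to tutor), and their clusters smear (0.49). The
Mann-Whitney comparisons separate the groups on every metric except
the pitch difference, where the contrast at this effect size is
marginal.

The same experiment is available from a shell:

```bash
finchsong run-all --out-dir results/run1 --seed 1
finchsong generate --out-dir data/pupil --role pupil --note-copy-prob 0.55
finchsong segment data/pupil/pupil_bout000.wav --out notes.tsv
```

`run-all` writes per-bird metrics (`birds.csv`), group tests
(`group_stats.csv`), the exact configuration, and the scatter/bar
plots.

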