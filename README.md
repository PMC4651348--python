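# flockstudy

Simulation and analysis toolkit for avian observer studies of medical images.

Pigeons can be trained by differential food reinforcement to classify breast
histopathology patches as benign or malignant and mammogram regions as
containing or lacking microcalcifications, and — crucially — to generalize
those discriminations to images they have never seen. Running such a study
involves a great deal of carefully counterbalanced machinery: stimulus sets
expanded by rotations and flips, hue-normalized monochrome variants, images
compressed to fixed byte-size ratios, difficulty-balanced training/testing
splits, daily sessions mixing differentially reinforced training trials with
nondifferentially reinforced probes, and an analysis stack running from
scored accuracy through ensemble ("flock-sourcing") ROC analysis.

`flockstudy` implements that machinery as a tested, reusable pipeline, with a
synthetic observer model standing in for the birds so that every stage can be
exercised end to end without animal data.

## What is in the box

- **`stimulus_prep`** — orientation augmentation (the six rigid views of a
  square patch), resizing to the display resolution (308 × 308), reduction to
  grayscale followed by repainting with a single hue (default 290°, the
  average hue of an H&E stain) so no class-specific color survives,
  between-class brightness/contrast equalization, JPEG re-encoding to a
  target fraction of the lossless byte size (e.g. 0.07 ≈ 15:1, 0.04 ≈ 27:1),
  and provably optimal difficulty-balanced set partitioning.
- **`session_engine`** — counterbalanced cohort configs, training sessions
  (144 trials/day for histology, 120 for mammograms), novel-stimulus test
  sessions (168- and 140-trial compositions), the 6-cycle × 4-day
  compression-testing schedule, correction-trial logic, and the adaptive
  observing-response requirement.
- **`observer_sim`** — a binormal signal-detection observer with an
  exponential learning curve *d(t) = d′max·(1 − e^(−t/τ))*, per-stimulus
  difficulty offsets shared across a cohort, lapses, and an
  exemplar-memorization channel that reproduces the rote-learning signature
  (trained stimuli above chance, novel stimuli at chance).
- **`analysis`** — scored accuracy with correction trials excluded, exact
  one-tailed binomial tests against chance, Dunn–Šidák adjustment, the flock
  score (per-stimulus count of 'malignant' votes across a cohort of K
  observers, an ordinal score on {0..K}), empirical ROC curves, trapezoidal
  AUC (identically the Mann–Whitney pair statistic), DeLong paired AUC
  comparisons, and familiar-vs-novel generalization gaps with Wilson
  intervals.
- **`io` / `cli`** — seeded synthetic histology- and mammogram-like image
  fixtures with emulated human difficulty scores, strict CSV/JSON-Lines
  record round-trips, and a `flockstudy` command-line front end.

## Worked example: flock sourcing

```python
from flockstudy.cli import run_simulation, flock_summary

records, manifest = run_simulation(
    {"seed": 5, "n_per_class": 24, "side": 32, "n_days": 12}
)
summary = flock_summary(records, day=12)
print(round(summary["flock_auc"], 3))
for bird, res in summary["individual"].items():
    print(bird, round(res["auc"], 3))
```

prints

```
1.0
bird1 0.854
bird2 0.792
bird3 0.792
bird4 0.896
```

Each of the four simulated observers discriminates well above chance (AUCs
0.79–0.90, computed from their binary judgments on the 48 stimuli of day 12),
but summing the four votes per stimulus into the ordinal flock score and
sweeping its five thresholds yields an ensemble AUC of 1.0 — pooling
independent-but-correlated judgments recovers discrimination no individual
achieves. `summary["flock_vs_individual"]` carries the DeLong paired test of
the flock against every bird, Dunn–Šidák adjusted over the family of four.

The same pipeline is available from the shell:

```sh
flockstudy simulate --config cfg.yaml --out runs/
flockstudy flock-roc --records runs/records.csv --day 12 --out summary.json
```

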