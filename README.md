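# gesturesync

Analysis of gesture–speech synchrony under delayed auditory feedback
(DAF), for researchers studying the perceptual–motor coupling of hand
gesture and speech. When speakers hear their own voice played back at a
~150 ms delay, speech becomes disfluent; the question is what happens to
the *timing* of co-speech gestures. This package implements the full
measurement and inference chain for that question on motion-capture +
speech recordings, and ships a synthetic session generator so every stage
is testable without any data download.

## What it computes

For each annotated gesture event, four kinematic anchors are extracted
from the 240 Hz hand trajectory (zero-phase 33 Hz Butterworth on
position, central-difference speed/acceleration): the event **onset**,
**peak acceleration**, **peak velocity** and **peak deceleration**. The
speech anchor is the event's **peak pitch** (maximum voiced F0 in the
event window). The synchrony offset for anchor *a* is

    D_a = (t_a − t_peak_pitch) · 1000  [ms]    (negative: anchor leads pitch)

On top of the event-level D table:

* **Coupling strength** — does DAF *tighten* synchrony? Tested on
  |D_peak_vel| of beat gestures and, more directly, on *SDD* — the SD of
  D per participant × condition × gesture type × anchor — with
  random-intercept mixed models (ML) and likelihood-ratio ladders.
* **Entrainment** — does gesture timing shift *toward* the delayed
  signal? The condition coefficient of a mixed model for D stacked over
  the four anchors.
* **SD–mean correlation** — Pearson r between per-participant coupling
  (SD of D) and mean shift.
* **Leave-two-out robustness** — every analysis refitted on all C(n, 2)
  participant-pair exclusions.
* **Cross-wavelet coherence** — Morlet wavelet coherence between hand
  speed and the speech amplitude envelope (Hilbert, scaled to [0, 1]),
  with 250 white-noise surrogate simulations per series pair, averaged
  over syllable- (0.2–0.5 s), gesture- (0.5–2 s) and sentence-scale
  (2–6 s) period bands.

See `docs/methods.md` for the model details and numerical conventions.

## Worked example

Generate a synthetic study at the original study's scale (10
participants, ~160-s sessions, ~21 gestures/min) and run the full
analysis:

```python
from gesturesync import SyntheticConfig, generate_dataset
from gesturesync.pipeline import PipelineConfig, run_pipeline

dataset = generate_dataset(SyntheticConfig.study_scale(), seed=1)
result = run_pipeline(dataset, PipelineConfig(seed=1))

eh = result.analyses["eh_beat"]
print("entrainment shift (beat):", round(eh["condition_coef"], 1), "ms")
print("condition LRT p:", round(eh["lrts"][1]["p"], 4))
print("SDD condition effect:",
      round(result.analyses["csh_sdd"]["condition_coef"], 1), "ms")
rob = result.robustness["entrainment"]
print("leave-two-out:", rob["n_significant"], "of", rob["n_datasets"],
      "exclusion datasets significant")
```

Output for this seed:

```
entrainment shift (beat): 55.8 ms
condition LRT p: 0.0
SDD condition effect: -52.6 ms
leave-two-out: 45 of 45 exclusion datasets significant
```

The generator injects a +27 ms DAF shift for beat gestures (offset means
7 → 34 ms) and a tighter DAF offset distribution (SD 230 → 193 ms for
beats, 379 → 295 ms for iconic gestures); the fitted shift of +56 ms is
within two (event-clustered) standard errors of the injected value, and
the negative SDD coefficient recovers the tighter coupling under DAF.

The same pipeline runs from the shell on a dataset directory:

```bash
gesturesync simulate --seed 1 --out data/ --study-scale
gesturesync report --in data/ --out results/ --seed 1
```

`results/` then holds the event table (`records.csv`), the descriptive
tables, model reports (`models.json`), the robustness report, the band
coherence table and a manifest tying every number to config + seed.

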