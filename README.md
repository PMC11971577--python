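# contactstim

A testable re-implementation of a webcam-based contingent-stimulation system
for people with severe-to-profound intellectual and sensory-motor
disabilities, together with the single-case analysis used to evaluate it.

The clinical idea: a participant sits at a desk with two objects fixed on it.
A camera watches their hands; each *response* — a new hand contact with
(touching or exploring) one of the objects — is detected from hand landmarks
and, during intervention sessions, immediately triggers a 10-second period of
preferred stimulation (music, songs, lights, mild airflow). Contact with the
environment is thereby reinforced without attaching any sensor to the person
or the objects. Sessions last 5 minutes; after periods of 30–40 s without
responding a brief alerting event (encouragement, sound) sustains vigilance.

This package contains everything *around* the camera, testable without one:

- **`contactstim.detection`** — object regions as polygons in normalized
  image coordinates, closed-boundary point containment (shapely), per-frame
  contact verdicts from a configurable landmark subset (default: the five
  fingertips), and debounced rising-edge response extraction: a sustained
  touch counts once, a new response requires release and re-contact.
- **`contactstim.engine`** — a deterministic session state machine. Phases:
  *baseline* (record + alert only), *intervention* (10 s contingent
  stimulation per response), *control* (continuous response-independent
  stimulation, changed periodically). After every response, monitoring halts
  for 10 s in **all** phases, capping responses at 30 per session. The only
  randomness is the seeded alert-interval draw, so (config, seed, frames)
  determine the log byte-for-byte and any session can be replayed.
- **`contactstim.actuation`** — the speaker / smart-plug contract with
  inspectable, fail-open mock implementations.
- **`contactstim.analysis`** — ABACB phase series, PEM (percentage of
  intervention sessions whose count strictly exceeds the comparison-phase
  median), inter-rater agreement percentage, blocked plotting, and the
  stimulus preference screening rule (≥ 50 % positive of ≥ 10 presentations).
- **`contactstim.simulate`** — a seeded synthetic participant: Poisson
  attempt processes per phase (baseline 1.0/min, intervention 3.5/min,
  control 0.8/min), a transient post-alert hazard boost, and a renderer that
  turns attempts into fingertip landmark streams, so the entire pipeline runs
  end to end without hardware.
- **`contactstim.io` / `contactstim.cli`** — schema-versioned JSON configs,
  JSONL event and frame files, CSV export, study bundles, and the
  `contactstim` command (`run`, `simulate`, `analyze`, `screen`, `validate`).

## Worked example

```sh
contactstim simulate --seed 7 --out study7
contactstim analyze --bundle study7 --out study7/analysis
```

or equivalently in Python:

```python
from contactstim.simulate import simulate_study
from contactstim.analysis import study_summary

result = simulate_study(seed=1)
table, pems = study_summary(result.series)
print(table.to_string(index=False)); print(pems)
```

which prints

```
phase  n_sessions      mean  median  min  max
   A1           5  4.400000     4.0  2.0  8.0
   B1          15 12.733333    12.0 11.0 17.0
   A2           5  3.800000     4.0  1.0  6.0
    C           5  5.200000     5.0  3.0  8.0
   B2          15 12.000000    13.0  8.0 16.0
{"B1_vs_A1": 1.0, "B2_vs_A2": 1.0, "B2_vs_C": 1.0}
```

Read it as a miniature single-case study: responding sits around 4 per
session under baseline (A1, A2), roughly triples when stimulation is made
contingent on responses (B1, B2), and does **not** rise when the same
stimulation is given for free (C ≈ baseline). All three PEM comparisons are
1.0 — every intervention session exceeded the comparison-phase median — which
is the signature of a contingency effect rather than mere activation by
stimulation.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch — simulates a complete ABACB study at
the given seed, passes every session through the detector and session engine,
and recomputes the phase summary and PEM report — then writes the report JSON
to `--out`.

See `docs/methods.md` for the model, its assumptions, numerical choices, and
what the synthetic generator does and does not emulate.
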