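# Methods

## The system under test

The package models a contactless "microswitch": a camera watches a desk, a
pose-landmark backend reports hand landmark positions in normalized image
coordinates, and software decides when a *response* — a new hand contact with
one of the objects fixed on the desk — has occurred. Responses drive an
operant contingency: during intervention sessions each response is followed
immediately by a 10-s period of preferred stimulation; baseline sessions
record and alert only; control sessions play the same stimulation
continuously and response-independently, to separate the effect of the
*contingency* from the effect of stimulation per se. The phase sequence is
the single-case ABACB reversal design (baseline, intervention, baseline,
control, intervention).

## Contact and response semantics

**Geometry.** Each object is a fixed polygon in image coordinates
([0,1]², origin top-left). Containment is closed (boundary counts as
inside); edge flicker is handled temporally, not geometrically. Contact is
evaluated in the 2D image plane even when a z coordinate is present: the
objects are fixed on the desktop, so their image-plane footprint is what the
camera can certify. Polygon predicates are delegated to shapely (prepared
geometries, vectorized over whole streams).

**Per-frame verdict.** A frame is in contact when at least `min_landmarks_in`
(default 1) of the configured landmark subset (default: the five fingertip
landmarks — touching is fingertip-led) lie inside a single region; the
winning region is the one containing the most qualifying landmarks, ties
broken by lowest region id. An empty landmark list (hand not visible) is
simply no contact.

**Response = debounced rising edge.** A contact must persist
`debounce_frames` consecutive frames (default 3, i.e. 0.2 s at the assumed
≥ 15 fps) to be trusted; its *onset* — the first frame of the run — is the
response timestamp. Once confirmed, gaps shorter than `release_frames`
do not end it, and no further response is possible until the contact is lost
for `release_frames` and re-established. This operationalizes "a *new* hand
contact": resting a hand on the object counts once.

## The session state machine

States are MONITORING and LOCKOUT. On a response in MONITORING the engine
logs it, delivers stimulation if (and only if) the phase is intervention,
and enters LOCKOUT for `lockout_s` — a single coupled parameter equal to
`stim_duration_s` (10 s), because the monitoring halt applies after every
response in every phase, for cross-phase consistency. During LOCKOUT
detection is disabled; raw contact runs that *begin* inside it are audited
as non-counted `contact_ignored` events. At LOCKOUT exit the debouncer is
reset, so a touch still held reads as a fresh onset — a hand never lifted
yields responses at 0, 10, 20, …, 290 s, the structural ceiling of
`ceil(300/10) = 30` per session.

**Alerts.** In MONITORING, an alerting event fires when the time since the
latest of (last response, last alert, session start) reaches a value drawn
uniformly from `alert_window_s` (default 30–40 s), one seeded draw per
waiting period; firing or responding resets the clock and redraws. The draw
is the *only* randomness in the engine, so a replay with the same seed is
byte-identical and a replay with a different seed can move alerts but never
responses. Draws are rounded to 3 decimals so logged gaps are exact under
the serialization contract.

Two timing subtleties follow from back-dating responses to their onset
frame. (1) An alert due while a debounce streak is still unconfirmed is held
back until the streak resolves: if the streak confirms, the response
(time-stamped before the due alert) resets the clock and the alert is
discarded; if it breaks, the alert fires stamped at its original due time.
This keeps the invariant that no alert ever occurs within the window minimum
of a *preceding* response or alert — an alert may immediately precede a
response (that is its purpose), never trail one. (2) An alert due inside a
lockout (impossible under the default window, which exceeds the lockout) is
deferred to the lockout end.

**Control phase.** Stimulation is on from 0 to session end with `stim_change`
events every `control_change_s` (default 60 s → 4 changes per 5-min session;
the cadence is not prescribed anywhere, "several times per session" was the
constraint). Whether it should pause during post-response lockouts is
unspecified; it is kept continuous, which matches its purpose of providing
response-independent stimulation.

**Actuation.** Speaker and smart-plug adapters sit behind one contract with
inert mocks that record (descriptor, start, stop) for inspection. Actuator
failures are fail-open: they annotate the log and never abort a session —
in this population an aborted session costs far more than a missed jingle.

## Single-case analysis

PEM — here reported as a proportion in [0,1] — is the fraction of
intervention sessions whose response count **strictly** exceeds the median
of the comparison phase. Ties count as not exceeding; PEM variants differ on
this, so it is pinned by test. Even-length medians use the midpoint of the
two central order statistics. The three comparisons reported are B1 vs A1,
B2 vs A2 and B2 vs C. Under exchangeability, E[PEM] equals the expected
exceedance probability of the comparison median (≈ 0.5 for continuous data,
below 0.5 for ties-prone counts) — this is verified by simulation in the
tests. Agreement is 100·agreements/(agreements+disagreements), undefined
(an error, not 0 or 100) at 0/0. Block means follow the blocked plotting
convention: 2-session blocks in baseline/control, 4-session in intervention,
a trailing partial block annotated with its size. Phase lengths outside the
study's printed ranges (5–10 / 15–31 / 5–9 / 5–8 / 43–74) warn rather than
error, so mini-studies remain legal. The screening rule consumes
already-agreed positive-reaction flags: the upstream two-rater agreement is
a human judgment, not software.

## The synthetic participant

The generator emulates *the statistics the system assumes*, not operant
learning. Attempts to touch are a homogeneous Poisson process per phase —
baseline 1.0/min, intervention 3.5/min, control 0.8/min. The intervention
rate is simply higher; a linear within-phase ramp hook exists
(`intervention_ramp`) but is off by default, because the artifact tests the
system, not acquisition curves. The baseline and intervention rates were
fixed first (they imply, after 10-s lockout filtering, per-session counts of
≈ 4–5 and ≈ 12, inside the study's printed per-phase mean ranges of ~3–6.5
and ~10–19.5; a Monte-Carlo calibration check confirmed phase means land in
those ranges in well over 90 % of replicate studies). The control rate has
no printed value; 0.8/min encodes the reported tendency of responding to
decline under free stimulation.

Alerting events multiply the attempt hazard by `alert_boost` (2.0) decaying
exponentially (`alert_decay_s` = 10 s) — an invented, unvalidated transient
standing in for the vigilance function of alerts. Because alerts depend on
responses and responses on attempts, each session is generated by an
event-level closed-loop co-simulation that mirrors the engine's alert clock
(same seed, same draw order: session start, each response, each alert),
including lockout filtering and the boundary case of a touch begun during
lockout and still held (at least one debounce time) past its end. The
rendered stream is then run through the *real* detector and engine; all
recorded counts come from the engine, and the co-simulation's alert schedule
agrees with the engine's to within frame quantization (divergence is
possible in rare sub-frame boundary cases and affects only the boost's
timing, never the log's internal consistency).

Rendering places the five fingertips at a rest point outside all regions,
ramps them over 0.3 s to just outside the target region, holds them at the
region center for a dwell drawn uniformly from 0.5–2 s, and returns;
overlapping dwells merge into one contact run. Gaussian jitter (σ = 0.003,
clipped at ±0.012) is small against the geometric margins, so containment
during a dwell is exact. Simulated streams default to 10 fps with
debounce/release of 2 frames (the same 0.2 s tolerance the 15-fps default
assumes), trading frame-rate realism for run time.

What the generator does **not** emulate — so a green test does not establish
robustness to it: landmark dropout and misdetection, multi-person scenes,
camera motion, continuous reach kinematics (the approach ramp is schematic),
habituation in the control phase, or any learning dynamics. It certifies the
contingency logic, timing, bookkeeping and statistics, not the vision model.

## Numerical and design choices

- Event timestamps are seconds from session start, rounded to 3 decimals at
  creation so the in-memory log equals its JSONL serialization; files use
  sorted keys, making identical runs byte-identical and diff-able.
- Simultaneous events order deterministically (stim_off before the response
  that becomes possible at the same instant; session_end last).
- A frame source must cover the session to within `coverage_tolerance_s`
  (1 s); otherwise the error names the last covered timestamp.
- Per-session seeds in `simulate_study` (alert, attempts, rendering) are
  drawn from one master generator, giving end-to-end reproducibility from a
  single integer.
- Degenerate inputs fail loudly and specifically: degenerate polygons,
  decreasing timestamps, 0/0 agreement, < 10 screening presentations,
  unknown config schema versions, config-hash mismatches on replay.

## Known limitations

Monitoring assumes one relevant hand pose stream; any hand in frame is
response-capable (whether the original monitored one or both hands is
unstated). Whether the original contact test used 2D or 3D proximity is
unstated; 2D is the default here. The alert-hazard transient and the control
rate are modeling choices without empirical anchors. Session means and PEM
values from the simulator characterize the simulator, not human behavior.
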