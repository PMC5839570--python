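# Methods

This note records the models behind `phstat`, the defaults and why they
were chosen, and what the simulation does and does not establish about
real hardware.

## Display OCR

A frame is an (H, W, 3) uint8 RGB array. Red seven-segment displays put
essentially all signal in the red channel, so decoding uses only that
plane, binarised with a strict `intensity > threshold` test (one
convention had to be fixed; strictness makes an all-zero frame decode to
all-off at every threshold). Each digit occupies a box of
`digit_width x digit_height` pixels repeating every `digit_pitch`
columns; within the box, seven thin probe rectangles (thickness
`max(1, digit_height // 10)`) sit at the standard segment positions —
top/middle/bottom centre bands for a/g/d, quarter-height edge strips for
b/c/e/f. A segment counts as lit when at least `on_fraction` (default
0.5, the robust midpoint) of its probe pixels are on.

The decoded pattern is looked up exactly in the canonical map; 12 of the
128 patterns are meaningful (digits 0–9, blank, minus). Display
semantics: the decimal point is fixed by configuration (`decimal_index`
integer digits), leading blanks are blanked leading zeros and read as
zero, and any invalid pattern, minus sign, or blank after a lit digit
invalidates the whole reading. Rejecting rather than guessing matters
because frames captured mid-transition show partial segments; the
single-segment-flip tests verify a corrupted digit either still reads as
a valid glyph from the canonical map or is rejected — never silently
misread as an unrelated number.

`auto_threshold` scans all 256 thresholds against a frame of known value
and returns the midpoint of the widest working interval, the choice with
the most margin against lighting drift (re-calibration under changed
lighting remains an operator task, as on the physical instrument).

The renderer draws classic block digits (bar thickness chosen to cover
the probe rectangles; digits of roughly 2:1 height:width aspect are
assumed — extreme aspect ratios would let bars and probes of different
segments collide), red-dominant, with optional Gaussian pixel noise and
optional deliberately-invalid "transition" digits. It exists so every
OCR path, including failure paths, is exercisable without a camera; it
does not model glare, perspective, rolling shutter or uneven
illumination.

## Pump models

Syringe: plunger advance is `lead / steps_per_rev` mm/step (0.004 mm for
the 200-step NEMA 17 on a 0.8 mm leadscrew); volume per step is bore
cross-section × advance (0.0013 ml/step at a nominal 20.0 mm bore,
0.0026 ml/step at 28.8 mm — bore diameters are configuration, since only
the resulting resolutions are standard figures). Doses are rounded to
the nearest step with the sub-step residual carried forward, so long
dosing sequences stay within one step's volume of the requested total
instead of drifting. Capacity is enforced at the plunger.

Peristaltic: volume = (run time − dead time) × coefficient. The
coefficient (ml/ms) is fitted from repeated fixed-length doses by the
pooled ratio of sums Σvolume/Σtime — matching the physical calibration
procedure of dosing N times and weighing the total, and converging as
1/√n under multiplicative dose noise. Supply-voltage profiles model the
permanent-magnet motor's unstable start qualitatively: 12 V → dead time
0 ms, reliable minimum 0.5 ml; 9 V → 40 ms and 1.5 ml. These two
numbers are free parameters, not measured constants. Sub-minimum doses
warn but execute.

Protocol: one ASCII line per message, `VERB {json}`, with
IDENTIFY/IDENTITY/DOSE/STOP/GET_CAL/SET_CAL/ACK/ERROR. Module-resident
calibration (the EEPROM of a real module) is modelled as the
IDENTITY/GET_CAL/SET_CAL exchange; the transport contract is
`write_line`/`read_line`, implemented in-memory against the virtual
pumps. No serial implementation is included.

## Controller

The decision rule is deliberately minimal: dose one unit volume iff the
latest reading is valid AND strictly below the setpoint AND at least
`min_interval` has passed since the last dose. Equality does not dose
(one convention had to be chosen, and the strict rule is the
conservative one). Invalid readings never dose; `stale_timeout` (10 s,
a safety addition — roughly 100× the expected gap between clean frames)
with no valid reading raises an alarm that terminates the run with the
log flagged. Decisions tick at 1 s, aligned with the 1 s logging period.

Adaptation concretises "shrink the dose as the process stabilises": when
four consecutive dose-eligible windows (4 × current `min_interval`) pass
without a dose, the unit volume halves (down to `unit_volume_floor`,
default 0.5 ml) and the interval doubles (up to `interval_cap`, 60 s); a
dose fired while the pH sits more than 0.05 below setpoint reverses one
step. All five constants are configuration. Under the default kinetics
this walks the 2 ml / 5 s start regime down to the 0.5 ml floor regime
over the first hour.

PID mode (`pid_step`) is a standard positional PID with the output
clamped to [0, max_rate] and the integral frozen while clamped. It is
secondary and off by default: with a 20 s electrode lag and a fast
initial acid burst, threshold dosing is far easier to keep stable.

## Simulated plant

Chemistry is strong-electrolyte only: true pH solves
[H⁺]² + (C_b − C_a)[H⁺] − Kw = 0 in closed form (numerically stable on
both sides of equivalence; Kw = 1e-14, temperature-independent). The
real oxidation mixture's buffering and its acid release are folded
together into an *effective* generation rate
r(t) = r_fast·e^(−t/τ_fast) + r_slow, integrated exactly per step.
Defaults — r_fast = 1.2e-4 mol/s, τ_fast = 600 s, r_slow = 1e-6 mol/s in
2.5 L — were sized from the target operating description: early demand
≈1.2 ml of 0.5 M NaOH per 5 s (safely under the 2 ml / 5 s dosing
capacity), a tail demanding ≈0.5 ml per 250 s, and ≈165 ml total over
3 h.

The electrode is a first-order lag (τ = 20 s — slow pH meters are why
the pH-stat doses in discrete units rather than under PID) plus Gaussian
reading noise of 0.001 pH, one display quantum. Frames of the measured
value are emitted through the renderer, with a configurable probability
of a corrupted transition digit.

Virtual pumps apply multiplicative dose noise
σ(v) = σ0·(1 + v_ref/v): syringe σ = 1% flat; peristaltic 12 V
σ0 = 1%, v_ref = 0.2 ml; 9 V σ0 = 2%, v_ref = 1.0 ml. These reproduce
the qualitative orderings (small doses relatively noisier; 9 V worse
than 12 V), not any measured dissipation magnitude — absolute hardware
precision figures are not reproducible in software and are not claimed.

One seeded generator per simulation feeds every stochastic draw
(reading noise, frame corruption, actuation noise), so runs are
bit-reproducible per seed, and fully deterministic with noise disabled.

## Titration

Each cycle waits until the pH is stable — the readings now and one
`stability_window` (5 s) ago agree within `stability_epsilon` (0.005
pH, five display quanta; an endpoint comparison, not a variance test) —
records (cumulative delivered volume, pH), then doses the next scheduled
increment. Never-settling pH raises a timeout carrying the partial
curve. The equivalence point is the maximum of dpH/dV by central
differences on the (possibly uneven) volume grid, refined by the vertex
of a parabola through the peak and its neighbours; the method is tagged
in the result. Parabolic refinement was preferred over a
second-derivative zero-crossing as the more noise-tolerant of the two
classical constructions. A curve spanning less than 1 pH unit reports
no equivalence rather than amplifying noise.

## Problem sizes and numerical choices

The reference closed-loop experiment is 10 800 ticks of 1 s (3 h) with a
frame rendered and OCR-decoded every tick; the exhaustive OCR check
covers all 14 001 values 0.000–14.000. Titrations use 0.05–0.5 ml
increments to 20 ml. Time integration is explicit 1 s stepping with the
generation integral exact, so no step-size error accumulates in the
chemistry; dose quantisation (one step / one ms) bounds volume
bookkeeping error at one quantum per dose sequence.

## Limitations

* Strong-electrolyte chemistry only: no buffering, CO₂ uptake, activity
  corrections, or temperature dependence — weak-acid titration curves
  are out of scope.
* The effective generation rate stands in for real oxidation kinetics;
  passing closed-loop tests shows the controller holds the band against
  a *plausible* demand profile, not against any particular batch.
* The renderer does not model real camera optics, so OCR robustness
  results transfer to hardware only after on-site threshold calibration.
* Hardware transports (serial) and multi-reagent (acid+base) control are
  not implemented; single-reagent dosing only.
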