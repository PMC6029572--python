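# Methods

## Measurement model

A scalp MFEIT acquisition injects a sinusoidal current `I(f)` between one
electrode pair while single-ended voltages are recorded on all 32 measurement
electrodes against a common forehead reference (index 33). The acquisition
cycles carriers within each injection and injections within each frame, with
one digital trigger at every (injection, carrier) sub-segment start, so the
trigger stream orders segments frame-major, injection-next, carrier-minor.
Each carrier runs for a fixed number of sinusoid periods (32 at 5–100 Hz, 64
at 200–1000 Hz, 128 above), so low carriers dominate the session length: one
full 17-carrier sweep lasts 13.1 s per injection, and three frames over 31
injections take ≈ 1218 s.

One row of the built-in schedule prints an injection time inconsistent with
its periods column (800 Hz: 76 ms printed vs 64 periods / 800 Hz = 80 ms);
the package derives every duration from the periods column, which is the
quantity synthesis and segmentation actually depend on.

The measurement list expands injections into `(CS+, CS−, V+, V−)` rows,
injection-major and electrode-minor, with the common electrode always in the
V− column; current-carrying electrodes are excluded from the retained set
(930 = 31 × 30 rows for the standard arrangement). Two column orders
circulate for the 4-column protocol files: the header description
`[CS+ CS− V+ V−]` and the worked-example order `[V+ CS+ CS− V−]` (a published
example row `[1, 5, 32, 33]` injects between 5 and 32 and measures 1 against
33, contradicting the header). Both are supported via a `column_order` flag;
the default follows the worked example, since that matches the published
numeric rows.

The shipped 31-pair injection protocol and the default electrode coordinates
are synthetic placeholders (labelled as such in their file and docstrings):
the published protocol pairs and TSV coordinates are not reproduced, and
users processing real recordings must supply the published files. The
placeholder pairs mix ring separations of 16, 10, 6 and 3 positions to give
diverse current paths.

## Demodulation

Per segment and channel:

1. **Zero-phase filtering.** Forward–backward (`filtfilt`) application of the
   per-carrier filter, so the pass band is applied twice in magnitude and the
   phase response is identically zero. Default design: Butterworth band-pass
   ±50 Hz around the carrier (order 5); when its impulse response exceeds
   25 % of the segment, a Blackman-Harris-windowed FIR of order
   `0.25 × segment_len`; below 100 Hz, where a −50 Hz band edge would reach
   0 Hz, a split pair of Butterworth low-pass (order 7, corner carrier+50 Hz)
   and high-pass (order 2, corner `max(2, carrier−50)` Hz) stages. The
   built-in schedule carries the published per-carrier filter column as an
   override; one printed FIR order (910 at 1000 Hz) cannot be trimmed from
   its own 1048-sample segment and is treated as a misprint — the design
   falls back to the 25 % rule (order 262) with a warning. The printed FIR
   orders at other carriers (≈ 44 % of the segment) also exceed the stated
   25 % rule; the overrides win by default so published behaviour is
   reproduced, with the rule as fallback.
2. **Hilbert demodulation.** The analytic signal supplies the instantaneous
   amplitude (envelope) and phase.
3. **Trimming.** The filter's impulse-response length is cut from both
   segment ends, removing filter start-up and electrode-switching artefacts.
   For FIR filters the trim equals the filter order; for IIR filters it is
   the sample at which the impulse-response magnitude decays below 1 % of its
   peak (the published pipeline does not define this quantity; 1 % is the
   package's choice and is uncritical given the transient suppression below).
4. **Averaging.** Arithmetic mean of the envelope, divided by the filter's
   squared magnitude response at the carrier (the exact steady-state gain of
   two passes), and circular mean — mean of unit phasors — of the
   carrier-referenced instantaneous phase, avoiding wrap-around bias. Phases
   are reported in (−π, π]. A segment leaving less than one carrier period
   after trimming is flagged with a reason, never silently averaged.

**Carrier-locked transient suppression.** `filtfilt` and the FFT-based
analytic signal are exact only for infinite steady-state sinusoids; on the
short published segment lengths their edge transients and circular-FFT
leakage are the dominant error terms (10⁻⁴–10⁻² % in amplitude, orders above
the demodulator's intrinsic accuracy). Because the carrier is known, each
segment is decomposed — exactly — into a least-squares `a·cos + b·sin + c`
component and a residual. The carrier + DC component is propagated through
the filter analytically (multiplication by the squared magnitude response at
the carrier and at DC; zero phase) and through the analytic-signal step in
closed form (`a·cos + b·sin → (a − ib)e^{iωt}`; the Hilbert transform of a
constant is zero). Only the residual — noise, drift, switching artefacts —
passes through the numerical `filtfilt` and FFT Hilbert transform, so edge
errors scale with the residual rather than the signal. The estimator itself
(envelope mean, circular phase mean after trimming) is unchanged, and on
time-varying real data the residual path carries the difference. With this
in place the noiseless validation sweep is exact to ≈ 10⁻¹²  % at every
carrier, comfortably inside the published bounds (0.001 % amplitude and
0.0017 % phase at 10 Hz; 10⁻⁵ % at and above 100 Hz). The residual's FFT is
zero-padded to the next fast length; the pad touches only the residual.

The validation harness (`qc.validate_demodulation`) uses 16 generating
phases evenly spaced in (0, π) — kept away from zero so the *relative* phase
error is well defined — with a 10 mV DC offset and 1 mV amplitude, and is
fully deterministic.

## Post-processing

* **Gain correction.** The recording amplifier's anti-aliasing response is
  modelled as a single-pole low-pass with the −3 dB point at 3 kHz (the one
  documented parameter); each frequency column is multiplied by the inverse
  gain (√2 at 3 kHz, ≈ 1.2019 at 2 kHz). A calibration-table mode with
  log-frequency interpolation allows exact replication of a bench
  calibration when one is available.
* **Current normalisation** scales each column by `I_max / I(f)` (280 µA at
  2 kHz in the built-in schedule, so ×6.22 at 5 Hz). Both scalings are
  per-frequency scalars and therefore commute; the test suite asserts this.
* **Real component** `BV·cos(PA)` keeps only resistive changes.
* **Frame averaging** is the arithmetic mean over frames, skipping flagged
  entries; a cell flagged in every frame stays NaN.
* **Cleaning** rejects entries deviating from a reference by strictly more
  than 20 mV (a deviation of exactly 20 mV is kept, reading the published
  "more than ±20 mV" literally). The reference is the elementwise NaN-aware
  mean of healthy-volunteer matrices (median by flag); whether the published
  reference was per-cell or pooled is not stated, per-cell is assumed.
  Removed cells become NaN — the `"_NaN_"` string in JSON — and are listed in
  a report whose length equals the number of NaNs introduced. No imputation
  is performed.

## Synthetic recordings

The phantom is a lumped resistor network, not a finite-element head: a
symmetric conductance matrix over mesh nodes, each electrode attached through
its series contact impedance, solved by nodal analysis with the common
electrode as ground. This gives exact, reciprocity-obeying,
frequency-invariant transfer impedances — the right oracle for a pipeline
test, at desk scale. The default random mesh places one boundary node per
electrode on a ring with random chords to a small internal clique, branch
conductances log-uniform between 5 mS and 50 mS (20–200 Ω branches) and
contact impedances uniform in 0.5–3 kΩ; at the schedule's 45–280 µA this
yields boundary voltages of roughly 1–50 mV, matching the published dynamic
range (±262 mV with measured values of a few mV to tens of mV). Zero contact
impedances are floored at 1 µΩ to keep the system well conditioned.

Waveform synthesis emits, per (frame, injection, carrier), a cosine at the
phantom-predicted amplitude for the plan's current, with a trigger at each
sub-segment start, optional inter-segment dead time (default 0 ms; the real
gap duration is not published), and noise terms: white Gaussian noise
(default 5 µV SD, typical of EEG instrumentation), per-channel DC electrode
offsets (default within ±20 mV, below the 50 mV acceptance cap), 50 Hz mains
pickup (5 µV) and a decaying exponential switching transient (1 mV, 2 ms) at
every segment start. All draws come from one seeded generator, so identical
seeds give bit-identical recordings. The ground truth records the signed
noiseless real voltages at the plan currents (gain-free) plus the exact
segment map. Contact-check recordings are synthesized as 1 kHz injections
cycling through every electrode paired with its ring neighbour.

In the noisy end-to-end acceptance run, the white-noise SD is set to 270 µV,
calibrated so the repeated-frame SNR of the demodulated magnitudes is ≈ 40 dB
for the default phantom's 1–8 mV boundary voltages — the regime in which
frequency-difference imaging is known to work — before asserting that the
±20 mV cleaning stage removes nothing against a same-phantom reference and
exactly the faults injected above threshold.

## QC definitions

* **Contact impedance**: demodulated voltage on an electrode while it
  injects, divided by the injected current (mV/µA = kΩ), checked against the
  1–3 kΩ application criterion. The estimate includes the series path through
  the medium, which for kΩ contacts and an Ω-scale medium is a small positive
  bias.
* **DC offsets**: per-channel mean over the pre-injection window (0.5 s guard
  before the first trigger); a channel passes while strictly below 50 mV.
* **SNR**: `20·log10(|mean over frames| / std over frames)` per cell (sample
  standard deviation), +∞ where frames are identical, summarised per
  frequency as the mean over measurements; the published pipeline does not
  define its SNR, this is the standard repeated-measures definition. Whether
  published SNR used magnitude or real-component voltages is unstated;
  magnitude is the default. A one-way ANOVA p-value across frequency is
  available (`qc.snr_anova_p`).

## EEG extraction

Up to a minute of injection-free recording before the first trigger and
after the last segment is band-passed with a zero-phase second-order
Butterworth filter (2–200 Hz) and a second-order IIR notch at 50 Hz
(quality factor 35, ≈ 1.4 Hz width; no notch parameters are published). A
0.5 s guard band keeps switching transients out; window lengths and guards
are configurable since the published values are unstated. Average-montage
re-referencing is optional, as a non-clinical montage is assumed.

## Scale of the test problems

The acceptance suite runs the full 17-carrier schedule on an 8-electrode,
5-injection phantom (one noiseless frame, then three noisy frames), which
exercises every code path — all three filter families, both trigger modes,
gain and current scalings, cleaning — in well under a minute of synthesized
signal per run. The protocol arithmetic (992/930/15 810/930 × 17) and the
session-length check are exact and run on the full-size measurement list.
What the synthetic phantom does *not* emulate: tissue impedance spectra
(its transfer impedances are frequency-flat by construction), physiological
drift, movement artefacts and electrode-position error. Passing tests
therefore establish the correctness of the processing chain, not the
clinical performance of MFEIT measurements.

## Known limitations

* No BDF reader is bundled; recordings enter as arrays (`RawRecording`) or
  via the `.npy` + JSON sidecar fixture format. An adapter through an EEG
  I/O library can produce `RawRecording` objects without touching the core.
* The exact pass/stop specifications behind the published IIR orders, and
  the segment length the published 25 % FIR rule was applied to, are not
  recoverable; the filter column is reproduced verbatim and everything else
  is configurable.
* `.mat` export is not implemented; JSON is treated as the normative record
  format.
* Image reconstruction, frequency-difference algorithms, head meshing and
  EEG recovery during injection are out of scope.
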