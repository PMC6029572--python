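"""Quality control: contact impedance, DC offsets, SNR and demodulator
validation.

Three run-time checks guard a recording session — electrode contact
impedance estimated from single-electrode injections at 1 kHz (acceptance
band 1-3 kOhm), per-channel DC offsets (kept below 50 mV to avoid clipping),
and the signal-to-noise ratio of repeated frames — plus an offline validation
harness that sweeps noiseless simulated carriers through the full
demodulation path and reports the worst-case amplitude and phase errors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .demod import demodulate_segment
from .errors import DemodulationError
from .filters import design_filter
from .protocol import FrequencyPlan, InjectionProtocol
from .rawseg import RawRecording, extract_segment, parse_triggers

#: Contact-impedance acceptance band (kOhm): re-abrade above the upper bound.
CONTACT_BAND_KOHM = (1.0, 3.0)
#: Electrode DC-offset cap (mV); offsets must stay strictly below.
OFFSET_CAP_MV = 50.0


# ---------------------------------------------------------------------------
# Contact impedance
# ---------------------------------------------------------------------------

def estimate_contact_impedance(z_rec: RawRecording, plan: FrequencyPlan,
                               protocol: InjectionProtocol, current_ua: float,
                               criterion_kohm: float = CONTACT_BAND_KOHM[1],
                               ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-electrode contact impedance (kOhm) from a contact-check recording.

    For each electrode, the demodulated voltage on that electrode while it
    injects current is divided by the injected current; with kOhm-scale
    contacts and an Ohm-scale medium this is dominated by the electrode's own
    series contact impedance.

    Returns ``(z_kohm, passes, unmeasured)``: impedances (NaN when the
    electrode never injects), the ``z <= criterion`` flags, and the 1-based
    indices of unmeasured electrodes.
    """
    n_el = z_rec.n_electrodes
    index = parse_triggers(z_rec, plan, protocol.n_injections, n_frames=1)
    carrier = plan.entries[0].carrier_hz
    z = np.full(n_el, np.nan)
    segments = {e.injection: e for e in index if e.frequency_slot == 1}
    for inj, (src, _snk) in enumerate(protocol.pairs, start=1):
        if not 1 <= src <= n_el or not np.isnan(z[src - 1]):
            continue
        seg = extract_segment(z_rec, segments[inj])
        spec = design_filter(carrier, seg.shape[-1], z_rec.fs,
                             plan.filter_overrides())
        amp, _ = demodulate_segment(seg[src - 1:src], spec, carrier, z_rec.fs)
        z[src - 1] = amp[0] / current_ua  # mV / uA == kOhm
    unmeasured = [int(i) + 1 for i in np.nonzero(np.isnan(z))[0]]
    with np.errstate(invalid="ignore"):
        passes = z <= criterion_kohm
    return z, passes, unmeasured


# ---------------------------------------------------------------------------
# DC offsets
# ---------------------------------------------------------------------------

def check_offsets(rec: RawRecording, cap_mv: float = OFFSET_CAP_MV,
                  guard_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean DC level (mV) over the pre-injection window.

    The window runs from the recording start to ``guard_s`` before the first
    trigger; when no such window exists the whole recording is used (with a
    warning).  A channel passes while its |mean| stays strictly below the cap.
    """
    if len(rec.triggers):
        end = int(rec.triggers[0] - guard_s * rec.fs)
    else:
        end = rec.n_samples
    if end <= 0:
        warnings.warn("no pre-injection window before the first trigger; "
                      "using the whole recording", stacklevel=2)
        window = rec.samples
    else:
        window = rec.samples[:, :end]
    offsets = window.mean(axis=-1)
    return offsets, np.abs(offsets) < cap_mv


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def compute_snr(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Repeated-frame SNR in dB.

    ``values`` is ``(n_rows, n_freq, n_frames)``; per cell,
    ``SNR = 20 log10(|mean over frames| / std over frames)`` (sample std),
    with +inf where the frames are identical.  Returns the per-(row, freq)
    matrix and the per-frequency mean over rows (finite cells only).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[-1] < 2:
        raise ValueError("SNR needs (rows, freqs, frames) with >= 2 frames")
    mean = np.nanmean(values, axis=-1)
    std = np.nanstd(values, axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = 20.0 * np.log10(np.abs(mean) / std)
    snr[std == 0] = np.inf
    finite = np.where(np.isfinite(snr), snr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_freq = np.nanmean(finite, axis=0)
    return snr, per_freq


def snr_anova_p(snr_rows: np.ndarray) -> float:
    """One-way ANOVA p-value for SNR differences across frequency."""
    groups = [col[np.isfinite(col)] for col in np.asarray(snr_rows).T]
    groups = [g for g in groups if len(g) > 1]
    if len(groups) < 2:
        return float("nan")
    return float(stats.f_oneway(*groups).pvalue)


# ---------------------------------------------------------------------------
# Demodulator validation harness
# ---------------------------------------------------------------------------

def default_phase_grid(n_phases: int = 16) -> np.ndarray:
    """Evenly spaced non-zero generating phases in (0, pi).

    Phases are kept strictly positive (and below pi) so the relative phase
    error is well defined; amplitude invariance over the full circle is a
    separate property.
    """
    return (np.arange(n_phases) + 0.5) * np.pi / n_phases


def validate_demodulation(plan: FrequencyPlan | None = None,
                          fs: float = 16384.0, amplitude_mv: float = 1.0,
                          dc_offset_mv: float = 10.0,
                          phase_grid: np.ndarray | None = None,
                          use_plan_filters: bool = True,
                          ) -> dict[float, dict[str, float]]:
    """Worst-case demodulation errors on noiseless simulated carriers.

    For every carrier of the plan, sinusoids of the plan's duration are
    generated over a grid of signal phases (with a DC offset), demodulated
    through the full filter + Hilbert + trim + average path, and compared
    with the generating values.  Returns, per carrier, the maxima of
    ``|est - true| / true * 100`` for amplitude and phase (%).

    Deterministic: no randomness enters; repeated runs are bit-identical.
    """
    plan = plan or FrequencyPlan.table1()
    phases = default_phase_grid() if phase_grid is None else np.asarray(phase_grid)
    overrides = plan.filter_overrides() if use_plan_filters else None
    results: dict[float, dict[str, float]] = {}
    for entry in plan.entries:
        carrier = entry.carrier_hz
        n = entry.segment_samples(fs)
        t = np.arange(n) / fs
        sig = dc_offset_mv + amplitude_mv * np.cos(
            2 * np.pi * carrier * t[None, :] + phases[:, None])
        spec = design_filter(carrier, n, fs, overrides)
        amp, ph = demodulate_segment(sig, spec, carrier, fs)
        amp_err = np.abs(amp - amplitude_mv) / amplitude_mv * 100.0
        wrapped = np.angle(np.exp(1j * (ph - phases)))
        ph_err = np.abs(wrapped) / np.abs(phases) * 100.0
        results[carrier] = {
            "amplitude_error_pct": float(amp_err.max()),
            "phase_error_pct": float(ph_err.max()),
        }
    return results


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Aggregated QC outcome; every section is optional."""

    contact_impedance_kohm: np.ndarray | None = None
    contact_passes: np.ndarray | None = None
    contact_unmeasured: list[int] = field(default_factory=list)
    dc_offsets_mv: np.ndarray | None = None
    offset_passes: np.ndarray | None = None
    snr_db: np.ndarray | None = None
    snr_per_freq_db: np.ndarray | None = None
    validation_errors: dict[float, dict[str, float]] | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return [None if not np.isfinite(x) else float(x)
                        for x in np.ravel(v)]
            return v
        return {k: conv(v) for k, v in self.__dict__.items() if v is not None}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_text(self) -> str:
        lines = []
        if self.contact_impedance_kohm is not None:
            worst = np.nanmax(self.contact_impedance_kohm)
            nfail = int((~self.contact_passes[
                np.isfinite(self.contact_impedance_kohm)]).sum())
            lines.append(f"contact impedance: worst {worst:.2f} kOhm, "
                         f"{nfail} electrode(s) above criterion, "
                         f"{len(self.contact_unmeasured)} unmeasured")
        if self.dc_offsets_mv is not None:
            lines.append(f"dc offsets: worst {np.abs(self.dc_offsets_mv).max():.1f} mV, "
                         f"{int((~self.offset_passes).sum())} channel(s) failing")
        if self.snr_per_freq_db is not None:
            finite = self.snr_per_freq_db[np.isfinite(self.snr_per_freq_db)]
            if len(finite):
                lines.append(f"snr: {finite.mean():.1f} dB mean across frequency")
        if self.validation_errors is not None:
            worst_amp = max(v["amplitude_error_pct"]
                            for v in self.validation_errors.values())
            worst_ph = max(v["phase_error_pct"]
                           for v in self.validation_errors.values())
            lines.append(f"demodulator validation: worst amplitude error "
                         f"{worst_amp:.2e}%, worst phase error {worst_ph:.2e}%")
        return "\n".join(lines) if lines else "empty QC report"
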