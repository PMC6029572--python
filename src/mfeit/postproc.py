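"""From BV/PA matrices to the final cleaned voltage matrices.

The demodulated magnitudes are corrected for the amplifier's frequency
response, normalised to the maximum injected current, reduced to their real
(resistive) component, averaged across frames and finally cleaned against a
reference by the +-20 mV rejection rule.  Removed entries become NaN so the
matrix dimensions stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .protocol import FrequencyPlan

logger = logging.getLogger(__name__)

#: Published rejection threshold (mV) against the healthy-volunteer reference.
DEFAULT_CLEAN_THRESHOLD_MV = 20.0
#: Anti-aliasing -3 dB point of the recording amplifier (Hz).
DEFAULT_F3DB_HZ = 3000.0


@dataclass
class GainModel:
    """Frequency response of the recording amplifier.

    ``single-pole-lp`` models the anti-aliasing filter as a first-order
    low-pass with its -3 dB point at ``f3db`` (default 3 kHz), the one
    parameter the hardware documentation states.  ``calibration-table`` uses
    measured (frequency, gain) pairs and interpolates linearly in
    log-frequency, for exact replication of a bench calibration.
    """

    kind: str = "single-pole-lp"
    f3db: float = DEFAULT_F3DB_HZ
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.kind not in ("single-pole-lp", "calibration-table"):
            raise ValueError(f"unknown gain model kind {self.kind!r}")
        if self.kind == "calibration-table":
            if not self.table:
                raise ValueError("calibration-table model needs (freq, gain) pairs")
            freqs = [f for f, _ in self.table]
            gains = [g for _, g in self.table]
            if any(a >= b for a, b in zip(freqs, freqs[1:])):
                raise ValueError("table frequencies must increase")
            if any(a < b for a, b in zip(gains, gains[1:])) or gains[0] > 1.0:
                raise ValueError("gain must be <= 1 and non-increasing with frequency")

    def gain(self, freq: float) -> float:
        """|gain| at ``freq`` Hz; 1 at DC, non-increasing with frequency."""
        if self.kind == "single-pole-lp":
            return 1.0 / np.sqrt(1.0 + (freq / self.f3db) ** 2)
        freqs = np.array([f for f, _ in self.table])
        gains = np.array([g for _, g in self.table])
        if not freqs[0] <= freq <= freqs[-1]:
            logger.warning("gain table does not cover %g Hz; extrapolating "
                           "in log-frequency", freq)
        return float(np.interp(np.log(max(freq, 1e-9)), np.log(freqs), gains))


def gain_correct(bv: np.ndarray, plan: FrequencyPlan,
                 model: GainModel | None = None) -> np.ndarray:
    """Undo the amplifier's frequency-dependent gain, per frequency column.

    Axis 1 of ``bv`` must be the frequency axis (``n_protocol x n_freq`` or
    ``n_protocol x n_freq x n_frames``).
    """
    model = model or GainModel()
    factors = np.array([1.0 / model.gain(c) for c in plan.carriers])
    return bv * _per_freq(factors, bv.ndim)


def normalize_current(values: np.ndarray, plan: FrequencyPlan) -> np.ndarray:
    """Scale each frequency column to the plan's maximum current amplitude."""
    amps = plan.amplitudes_ua
    if np.any(amps <= 0):
        raise ValueError("plan contains a non-positive current amplitude")
    factors = plan.max_amplitude_ua / amps
    return values * _per_freq(factors, values.ndim)


def _per_freq(factors: np.ndarray, ndim: int) -> np.ndarray:
    shape = [1] * ndim
    shape[1] = len(factors)
    return factors.reshape(shape)


def extract_real(bv: np.ndarray, pa: np.ndarray) -> np.ndarray:
    """Real (resistive) voltage component, elementwise ``BV * cos(PA)``."""
    bv, pa = np.asarray(bv), np.asarray(pa)
    if bv.shape != pa.shape:
        raise ValueError(f"shape mismatch: BV {bv.shape} vs PA {pa.shape}")
    return bv * np.cos(pa)


def average_frames(values: np.ndarray, flags: np.ndarray | None = None) -> np.ndarray:
    """Mean over the trailing frame axis, skipping flagged/NaN entries.

    Cells flagged in every frame remain NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 2:
        raise ValueError("expected at least (rows, frames)")
    if flags is not None:
        values = np.where(flags, np.nan, values)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        return np.nanmean(values, axis=-1)


@dataclass
class CleanReport:
    """Record of the reference-based rejection stage.

    ``removed`` lists ``(row, frequency_slot, deviation_mv)`` triples
    (0-based indices) for every entry replaced by NaN; its length equals the
    number of NaN entries the cleaning introduced.
    """

    removed: list[tuple[int, int, float]]
    reference: np.ndarray
    threshold_mv: float

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def removed_fraction(self, total: int) -> float:
        return self.n_removed / total


def clean(voltages: np.ndarray, reference: np.ndarray,
          threshold_mv: float = DEFAULT_CLEAN_THRESHOLD_MV,
          ) -> tuple[np.ndarray, CleanReport]:
    """Reject entries deviating from the reference by more than the threshold.

    The rule is strict: a deviation of exactly ``threshold_mv`` is kept.
    Surviving entries are returned bit-identical; removed entries become NaN
    and are listed in the report.
    """
    voltages = np.asarray(voltages, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if voltages.shape != reference.shape:
        raise ValueError(
            f"voltages {voltages.shape} vs reference {reference.shape}")
    dev = voltages - reference
    with np.errstate(invalid="ignore"):
        mask = np.abs(dev) > threshold_mv
    cleaned = np.where(mask, np.nan, voltages)
    removed = [(int(r), int(c), float(dev[r, c]))
               for r, c in zip(*np.nonzero(mask))]
    for r, c, d in removed:
        logger.info("rejected measurement row %d, frequency slot %d "
                    "(deviation %+.2f mV)", r, c, d)
    return cleaned, CleanReport(removed, reference, threshold_mv)


def build_reference(datasets: list[np.ndarray], method: str = "mean") -> np.ndarray:
    """Elementwise reference across healthy-volunteer matrices, ignoring NaN."""
    if not datasets:
        raise ValueError("at least one dataset required to build a reference")
    stack = np.stack([np.asarray(d, dtype=float) for d in datasets])
    if method == "mean":
        return np.nanmean(stack, axis=0)
    if method == "median":
        return np.nanmedian(stack, axis=0)
    raise ValueError(f"unknown reference method {method!r}")


def process_frames(bv: np.ndarray, pa: np.ndarray, plan: FrequencyPlan,
                   flags: np.ndarray | None = None,
                   gain_model: GainModel | None = None,
                   normalize: bool = True) -> np.ndarray:
    """Convenience chain: gain correction, current normalisation, real
    component, frame average -> ``VoltagesFull`` (n_protocol x n_freq, mV)."""
    corrected = gain_correct(bv, plan, gain_model) if gain_model is not None else bv
    if normalize:
        corrected = normalize_current(corrected, plan)
    real = extract_real(corrected, pa)
    return average_frames(real, flags)
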