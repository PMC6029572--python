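"""Per-carrier filter specification and design.

Each carrier is isolated with a zero-phase (forward-backward) filter before
Hilbert demodulation.  Three filter families are used, following the
published processing chain:

* ``bandpass-iir`` — Butterworth band-pass, 50 Hz either side of the carrier;
* ``bandpass-fir-blackmanharris`` — linear-phase FIR with a Blackman-Harris
  window, used when the IIR impulse response would exceed 25% of the data
  segment;
* ``split-lp-hp-iir`` — separate Butterworth low-pass and high-pass stages,
  used below 100 Hz where a band edge at ``carrier - 50 Hz`` would be at or
  below 0 Hz and attenuate the carrier itself.

A ``FilterSpec`` is serialisable to and from the compact string dialect used
in published frequency tables, e.g. ``"BP FIR 490"`` or ``"LP IIR 7, HP IIR 2"``.
"""

from __future__ import annotations

import functools
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import FilterDesignError

KIND_BANDPASS_IIR = "bandpass-iir"
KIND_BANDPASS_FIR = "bandpass-fir-blackmanharris"
KIND_SPLIT_IIR = "split-lp-hp-iir"

#: Default half-bandwidth (Hz) either side of the carrier.
HALF_BANDWIDTH_HZ = 50.0
#: Floor for the high-pass corner of the split path (Hz); keeps the corner
#: strictly positive for 5-20 Hz carriers while still rejecting DC and drift.
MIN_HP_CORNER_HZ = 2.0
#: Default Butterworth orders: band-pass, and (low-pass, high-pass) split.
DEFAULT_BP_ORDER = 5
DEFAULT_SPLIT_ORDERS = (7, 2)
#: Fraction of the impulse-response peak below which the response is treated
#: as decayed when measuring the trim length of an IIR filter.
IIR_DECAY_FRACTION = 0.01
#: FIR order is this fraction of the segment length when the IIR impulse
#: response is too long for the segment.
FIR_SEGMENT_FRACTION = 0.25

_FILTER_TOKEN = re.compile(r"(BP|LP|HP)\s+(IIR|FIR)\s+(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class FilterSpec:
    """Specification of the per-segment carrier-isolation filter.

    Parameters
    ----------
    kind:
        One of ``bandpass-iir``, ``bandpass-fir-blackmanharris`` or
        ``split-lp-hp-iir``.
    orders:
        Filter order(s): ``(order,)`` for the band-pass kinds, or
        ``(lp_order, hp_order)`` for the split kind.
    band:
        ``(low, high)`` corner frequencies in Hz.  For the split kind these
        are the high-pass and low-pass corners respectively.
    """

    kind: str
    orders: tuple[int, ...]
    band: tuple[float, float]

    def __post_init__(self):
        if self.kind not in (KIND_BANDPASS_IIR, KIND_BANDPASS_FIR, KIND_SPLIT_IIR):
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        if self.band[0] >= self.band[1]:
            raise FilterDesignError(f"band corners must increase: {self.band}")
        if self.kind != KIND_SPLIT_IIR and self.band[0] <= 0:
            raise FilterDesignError(
                f"band-pass low edge {self.band[0]} Hz is not positive; "
                "carriers at or below the half-bandwidth must use the split "
                "low-pass/high-pass path"
            )
        if any(o < 1 for o in self.orders):
            raise FilterDesignError(f"orders must be positive: {self.orders}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_string(cls, text: str, carrier: float) -> "FilterSpec":
        """Parse the table dialect, e.g. ``"BP FIR 490"`` or ``"LP IIR 7, HP IIR 2"``.

        Trailing fragments without an order (occasionally present in printed
        tables) are ignored.
        """
        tokens = _FILTER_TOKEN.findall(text)
        if not tokens:
            raise FilterDesignError(f"cannot parse filter string {text!r}")
        kinds = {t[0].upper() for t in tokens}
        if kinds == {"BP"}:
            band_kind, order = tokens[0][1].upper(), int(tokens[0][2])
            kind = KIND_BANDPASS_IIR if band_kind == "IIR" else KIND_BANDPASS_FIR
            return cls(kind, (order,),
                       (carrier - HALF_BANDWIDTH_HZ, carrier + HALF_BANDWIDTH_HZ))
        if kinds == {"LP", "HP"}:
            lp = next(int(t[2]) for t in tokens if t[0].upper() == "LP")
            hp = next(int(t[2]) for t in tokens if t[0].upper() == "HP")
            return cls.split_for_carrier(carrier, (lp, hp))
        raise FilterDesignError(f"unsupported filter combination in {text!r}")

    @classmethod
    def split_for_carrier(cls, carrier: float,
                          orders: tuple[int, int] = DEFAULT_SPLIT_ORDERS) -> "FilterSpec":
        hp_corner = max(MIN_HP_CORNER_HZ, carrier - HALF_BANDWIDTH_HZ)
        return cls(KIND_SPLIT_IIR, tuple(orders),
                   (hp_corner, carrier + HALF_BANDWIDTH_HZ))

    def to_string(self) -> str:
        if self.kind == KIND_BANDPASS_IIR:
            return f"BP IIR {self.orders[0]}"
        if self.kind == KIND_BANDPASS_FIR:
            return f"BP FIR {self.orders[0]}"
        return f"LP IIR {self.orders[0]}, HP IIR {self.orders[1]}"

    # -- realisation ---------------------------------------------------

    def build(self, fs: float):
        """Return the realised filter as ``("sos", array)`` or ``("fir", taps)``."""
        return _build_cached(self, fs)

    def impulse_response_len(self, fs: float) -> int:
        """Trim length in samples.

        For FIR filters this is the filter order.  For IIR filters it is the
        index at which the impulse-response magnitude has decayed below
        ``IIR_DECAY_FRACTION`` of its peak.
        """
        return _ir_len_cached(self, fs)

    def gain_at(self, freq: float, fs: float, passes: int = 2) -> float:
        """Magnitude response at ``freq`` for ``passes`` filter passes.

        Forward-backward (zero-phase) filtering applies the magnitude
        response twice, hence the default ``passes=2``.
        """
        kind, f = self.build(fs)
        if kind == "sos":
            _, h = signal.sosfreqz(f, worN=[freq], fs=fs)
        else:
            _, h = signal.freqz(f, worN=[freq], fs=fs)
        return float(np.abs(h[0]) ** passes)

    def contains(self, carrier: float) -> bool:
        """Whether the carrier lies inside the pass band."""
        if self.kind == KIND_SPLIT_IIR:
            return self.band[0] < carrier < self.band[1]
        return self.band[0] < carrier < self.band[1]


@functools.lru_cache(maxsize=128)
def _build_cached(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if spec.band[1] >= nyq:
        raise FilterDesignError(
            f"upper corner {spec.band[1]} Hz at or above Nyquist ({nyq} Hz)")
    if spec.kind == KIND_BANDPASS_IIR:
        sos = signal.butter(spec.orders[0], list(spec.band), "bandpass",
                            fs=fs, output="sos")
        return ("sos", sos)
    if spec.kind == KIND_SPLIT_IIR:
        hp_corner, lp_corner = spec.band
        lp = signal.butter(spec.orders[0], lp_corner, "low", fs=fs, output="sos")
        hp = signal.butter(spec.orders[1], hp_corner, "high", fs=fs, output="sos")
        return ("sos", np.vstack([lp, hp]))
    taps = signal.firwin(spec.orders[0] + 1, list(spec.band),
                         window="blackmanharris", pass_zero=False, fs=fs)
    return ("fir", taps)


@functools.lru_cache(maxsize=128)
def _ir_len_cached(spec: FilterSpec, fs: float) -> int:
    kind, f = spec.build(fs)
    if kind == "fir":
        return int(spec.orders[0])
    n = 1 << 17
    x = np.zeros(n)
    x[0] = 1.0
    h = np.abs(signal.sosfilt(f, x))
    idx = np.nonzero(h >= IIR_DECAY_FRACTION * h.max())[0][-1]
    return int(idx) + 1


def design_filter(carrier: float, segment_len: int, fs: float,
                  overrides: dict[float, "FilterSpec | str"] | None = None) -> FilterSpec:
    """Choose the carrier-isolation filter for one segment.

    The selection rule mirrors the published processing chain: a Butterworth
    band-pass 50 Hz either side of the carrier by default; an FIR
    Blackman-Harris filter of order ``0.25 * segment_len`` when the IIR
    impulse response exceeds 25% of the segment; and a split low-pass /
    high-pass pair below 100 Hz, where a band-pass edge would reach 0 Hz.

    When ``overrides`` supplies a spec for this carrier (e.g. the published
    per-frequency filter column), it wins — unless its trim length cannot
    fit in the segment, in which case the rule-based design is used and a
    warning is emitted.

    Parameters
    ----------
    carrier:
        Carrier frequency in Hz; must be below ``fs / 2``.
    segment_len:
        Length of the data segment in samples.
    fs:
        Sampling rate in Hz.
    overrides:
        Optional map ``carrier -> FilterSpec`` (or table-dialect string).
    """
    if carrier >= fs / 2:
        raise FilterDesignError(f"carrier {carrier} Hz at or above Nyquist")
    if segment_len < 2 * fs / carrier:
        raise FilterDesignError(
            f"segment of {segment_len} samples is shorter than 2 carrier "
            f"periods at {carrier} Hz")

    if overrides is not None and carrier in overrides:
        ov = overrides[carrier]
        spec = ov if isinstance(ov, FilterSpec) else FilterSpec.from_string(ov, carrier)
        if 2 * spec.impulse_response_len(fs) < segment_len:
            return spec
        warnings.warn(
            f"override filter {spec.to_string()!r} for {carrier} Hz needs a "
            f"trim of {spec.impulse_response_len(fs)} samples per edge, which "
            f"does not fit a {segment_len}-sample segment; falling back to "
            "the rule-based design", stacklevel=2)

    if carrier < 100.0:
        spec = FilterSpec.split_for_carrier(carrier)
        if 2 * spec.impulse_response_len(fs) >= segment_len:
            raise FilterDesignError(
                f"split-path impulse response does not fit the "
                f"{segment_len}-sample segment at {carrier} Hz")
        return spec

    bp = FilterSpec(KIND_BANDPASS_IIR, (DEFAULT_BP_ORDER,),
                    (carrier - HALF_BANDWIDTH_HZ, carrier + HALF_BANDWIDTH_HZ))
    if bp.impulse_response_len(fs) <= FIR_SEGMENT_FRACTION * segment_len:
        return bp
    order = int(FIR_SEGMENT_FRACTION * segment_len)
    return FilterSpec(KIND_BANDPASS_FIR, (order,),
                      (carrier - HALF_BANDWIDTH_HZ, carrier + HALF_BANDWIDTH_HZ))
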