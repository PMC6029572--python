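"""EEG extraction from the injection-free portions of a recording.

Before the first current injection and after the last there is up to a minute
of recording in which EEG is the only signal present.  That window is
selected, band-passed with a zero-phase second-order Butterworth filter
(2-200 Hz) and notch-filtered at the mains frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .rawseg import RawRecording, SegmentIndex

#: Published EEG band corners (Hz) and notch frequency.
EEG_BAND_HZ = (2.0, 200.0)
NOTCH_HZ = 50.0
#: Notch quality factor; gives roughly a 1.4 Hz -3 dB width at 50 Hz.
NOTCH_Q = 35.0


@dataclass
class EEGSegment:
    """Filtered injection-free EEG block.

    ``samples`` are mV (multiply by 1e3 for uV); ``window`` is the
    (start, end) sample range within the source recording.
    """

    samples: np.ndarray
    fs: float
    window: tuple[int, int]
    montage_note: str = ("single-ended against the common forehead electrode; "
                         "re-referencing before analysis is recommended")


def _eeg_filters(fs: float, band: tuple[float, float], notch_hz: float,
                 notch_q: float):
    sos = signal.butter(2, list(band), "bandpass", fs=fs, output="sos")
    b, a = signal.iirnotch(notch_hz, notch_q, fs=fs)
    return sos, (b, a)


def extract_eeg(rec: RawRecording, index: SegmentIndex, which: str = "pre",
                *, guard_s: float = 0.5, max_duration_s: float = 60.0,
                band: tuple[float, float] = EEG_BAND_HZ,
                notch_hz: float = NOTCH_HZ, notch_q: float = NOTCH_Q,
                rereference: bool = False) -> EEGSegment:
    """Extract and filter the pre- or post-injection EEG window.

    ``which`` selects the window before the first injection segment or after
    the last one; a ``guard_s`` margin keeps switching transients out, and at
    most ``max_duration_s`` of data is taken.  Filtering is zero-phase
    (forward-backward) so in-band components are not delayed.  With
    ``rereference`` the channel-average montage is subtracted.
    """
    guard = int(round(guard_s * rec.fs))
    max_n = int(round(max_duration_s * rec.fs))
    first = min(e.start for e in index)
    last = max(e.end for e in index)
    if which == "pre":
        end = first - guard
        start = max(0, end - max_n)
    elif which == "post":
        start = last + guard
        end = min(rec.n_samples, start + max_n)
    else:
        raise ValueError(f"which must be 'pre' or 'post', got {which!r}")
    if end - start <= 0:
        raise ValueError(
            f"empty {which}-injection window: injection segments span "
            f"[{first}, {last}) of {rec.n_samples} samples "
            f"(guard {guard} samples)")

    block = np.asarray(rec.samples[:, start:end], dtype=float)
    sos, (b, a) = _eeg_filters(rec.fs, band, notch_hz, notch_q)
    n = block.shape[-1]
    out = signal.sosfiltfilt(sos, block, axis=-1,
                             padlen=min(n - 1, int(3 * rec.fs / band[0])))
    out = signal.filtfilt(b, a, out, axis=-1, padlen=min(n - 1, 3 * len(b)))
    if rereference:
        out = out - out.mean(axis=0, keepdims=True)
    return EEGSegment(out, rec.fs, (start, end))
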