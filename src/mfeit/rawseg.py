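"""Raw multichannel recordings and trigger-based segmentation.

A recording is a dense ``n_electrodes x n_samples`` voltage array (mV) with a
list of trigger sample indices.  Hardware emits one trigger at the start of
every (injection, carrier) sub-segment; a full acquisition cycles carriers
within each injection, injections within each frame, so the trigger stream
orders segments frame-major, injection-next, carrier-minor.

The on-disk fixture format is deliberately simple: a ``.npy`` array plus a
JSON sidecar carrying the sampling rate, triggers and provenance.  Adapters
for vendor formats (e.g. BioSemi BDF via ``mne``) can produce
:class:`RawRecording` objects without the core depending on any file format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SegmentationError
from .protocol import FrequencyPlan

#: Sampling rate of the deposited recordings (Hz).
DATASET_FS = 16384.0


@dataclass
class RawRecording:
    """Sampled voltages (mV), sampling rate, trigger events and provenance."""

    samples: np.ndarray
    fs: float
    triggers: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples))
        self.triggers = np.asarray(self.triggers, dtype=int)
        if np.any(np.diff(self.triggers) <= 0):
            raise SegmentationError("triggers must be strictly increasing")
        if len(self.triggers) and self.triggers[-1] >= self.n_samples:
            raise SegmentationError("trigger beyond end of recording")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.npy`` and a ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.samples)
        sidecar = {
            "fs": self.fs,
            "triggers": self.triggers.tolist(),
            "meta": self.meta,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "RawRecording":
        prefix = Path(prefix)
        samples = np.load(prefix.with_suffix(".npy"))
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(samples, float(sidecar["fs"]),
                   np.asarray(sidecar["triggers"], dtype=int),
                   sidecar.get("meta", {}))


@dataclass(frozen=True)
class SegmentEntry:
    """One (frame, injection, carrier) span, all 1-based indices."""

    frame: int
    injection: int
    frequency_slot: int
    start: int
    end: int

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class SegmentIndex:
    """Ordered, non-overlapping (frame, injection, carrier) sample spans."""

    entries: list[SegmentEntry]
    n_frames: int
    n_injections: int
    n_frequencies: int

    def __post_init__(self):
        expected = self.n_frames * self.n_injections * self.n_frequencies
        if len(self.entries) != expected:
            raise SegmentationError(
                f"{len(self.entries)} segments for a "
                f"{self.n_frames} x {self.n_injections} x "
                f"{self.n_frequencies} layout (expected {expected})")
        prev_end = -1
        for e in self.entries:
            if e.start < prev_end:
                raise SegmentationError(f"segments overlap at {e}")
            prev_end = e.end

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def parse_triggers(rec: RawRecording, plan: FrequencyPlan, n_injections: int,
                   n_frames: int, mode: str = "per-segment",
                   duration_tol: float = 0.10) -> SegmentIndex:
    """Partition a recording into (frame, injection, carrier) segments.

    Parameters
    ----------
    mode:
        ``"per-segment"`` — one trigger per carrier sub-segment (the
        default); ``"per-injection"`` — one trigger per injection, with
        carrier sub-segments laid out back-to-back from the plan durations.
    duration_tol:
        Warn when an inter-trigger interval deviates from the plan's
        injection time by more than this fraction.

    Each segment spans its trigger up to the next trigger, capped at the
    plan's expected duration so inter-segment dead time is excluded; the last
    segment ends at the expected duration (capped at the recording end).
    """
    nf = plan.n_frequencies
    if mode == "per-segment":
        expected = n_frames * n_injections * nf
    elif mode == "per-injection":
        expected = n_frames * n_injections
    else:
        raise ValueError(f"unknown trigger mode {mode!r}")
    if len(rec.triggers) < expected:
        raise SegmentationError(
            f"trigger count mismatch: expected at least {expected} "
            f"({mode}), found {len(rec.triggers)}")
    trig = rec.triggers[:expected]

    seg_samples = [e.segment_samples(rec.fs) for e in plan.entries]
    entries: list[SegmentEntry] = []
    if mode == "per-segment":
        k = 0
        for frame in range(1, n_frames + 1):
            for inj in range(1, n_injections + 1):
                for slot in range(1, nf + 1):
                    start = int(trig[k])
                    nominal = seg_samples[slot - 1]
                    nxt = int(trig[k + 1]) if k + 1 < expected else rec.n_samples
                    gap = nxt - start
                    if abs(gap - nominal) > duration_tol * nominal and k + 1 < expected:
                        warnings.warn(
                            f"segment (frame {frame}, injection {inj}, slot "
                            f"{slot}) inter-trigger interval {gap} samples "
                            f"deviates >{duration_tol:.0%} from the plan's "
                            f"{nominal}", stacklevel=2)
                    end = min(start + nominal, nxt, rec.n_samples)
                    entries.append(SegmentEntry(frame, inj, slot, start, end))
                    k += 1
    else:
        k = 0
        for frame in range(1, n_frames + 1):
            for inj in range(1, n_injections + 1):
                start = int(trig[k])
                for slot in range(1, nf + 1):
                    nominal = seg_samples[slot - 1]
                    end = min(start + nominal, rec.n_samples)
                    entries.append(SegmentEntry(frame, inj, slot, start, end))
                    start = end
                k += 1
    return SegmentIndex(entries, n_frames, n_injections, nf)


def extract_segment(rec: RawRecording, entry: SegmentEntry) -> np.ndarray:
    """All-channel sample block for one segment (view into the recording)."""
    if entry.start < 0 or entry.end > rec.n_samples:
        raise IndexError(f"segment {entry} out of recording bounds")
    if entry.n_samples <= 0:
        raise IndexError(f"segment {entry} is empty")
    return rec.samples[:, entry.start:entry.end]
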