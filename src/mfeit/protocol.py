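"""Electrodes, injection pairs, measurement protocol and the frequency plan.

The measurement geometry follows the scalp MFEIT convention: 32 measurement
electrodes (EEG 10-10/10-5 positions), a single common reference electrode on
the forehead, and a protocol of two-electrode current injections.  During one
injection, single-ended voltages are recorded on every electrode against the
common electrode; the electrodes carrying current are normally excluded from
the retained measurement set.

All user-facing electrode indices are 1-based; the common electrode is
index ``n_electrodes + 1`` (33 in the standard 32-electrode arrangement) and
appears only in the voltage-reference column of the measurement list.
"""

from __future__ import annotations

import configparser
import importlib.resources
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PlanError, ProtocolError
from .filters import FilterSpec

#: Built-in full-spectrum frequency schedule: carrier (Hz), injected current
#: amplitude (uA), sinusoid periods per injection, and the per-carrier filter
#: in the compact table dialect.  Injection durations are derived from the
#: periods column (``periods / carrier``).
TABLE1_ROWS: tuple[tuple[float, float, int, str], ...] = (
    (5.0, 45.0, 32, "LP IIR 7, HP IIR 2"),
    (10.0, 45.0, 32, "LP IIR 7, HP IIR 2"),
    (20.0, 45.0, 32, "LP IIR 7, HP IIR 2"),
    (100.0, 45.0, 32, "BP FIR 2160"),
    (200.0, 90.0, 64, "BP IIR 5"),
    (300.0, 90.0, 64, "BP FIR 1470"),
    (400.0, 90.0, 64, "BP FIR 1120"),
    (500.0, 90.0, 64, "BP FIR 910"),
    (600.0, 90.0, 64, "BP FIR 770"),
    (700.0, 140.0, 64, "BP FIR 670"),
    (800.0, 140.0, 64, "BP FIR 590"),
    (900.0, 140.0, 64, "BP FIR 540"),
    (1000.0, 140.0, 64, "BP FIR 910"),
    (1200.0, 160.0, 128, "BP FIR 770"),
    (1350.0, 190.0, 128, "BP FIR 690"),
    (1700.0, 235.0, 128, "BP FIR 560"),
    (2000.0, 280.0, 128, "BP FIR 490"),
)

#: Carriers of the reduced-spectrum (time-difference) schedule.
TD_CARRIERS = (200.0, 1200.0, 2000.0)

#: Standard 32-electrode scalp arrangement (10-10 extension names).
DEFAULT_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "O1", "Oz", "O2", "PO8",
)

COMMON_LABEL = "NFpz"


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeLayout:
    """Measurement electrodes plus the single-ended reference.

    Parameters
    ----------
    n_electrodes:
        Number of measurement electrodes (32 in the standard arrangement).
    labels:
        Position name per measurement electrode.
    coords:
        Nominal Cartesian ``(x, y, z)`` per measurement electrode, arbitrary
        length units.
    common_electrode:
        1-based index of the voltage reference; always ``n_electrodes + 1``
        and never part of the measurement electrode set.
    """

    n_electrodes: int
    labels: tuple[str, ...]
    coords: np.ndarray
    common_electrode: int = 0  # filled in __post_init__ if left at 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.common_electrode == 0:
            self.common_electrode = self.n_electrodes + 1
        if len(self.labels) != self.n_electrodes:
            raise ProtocolError(
                f"{len(self.labels)} labels for {self.n_electrodes} electrodes")
        if self.coords.shape != (self.n_electrodes, 3):
            raise ProtocolError(
                f"coords shape {self.coords.shape}, expected "
                f"({self.n_electrodes}, 3)")
        if 1 <= self.common_electrode <= self.n_electrodes:
            raise ProtocolError(
                "common electrode must lie outside the measurement set")

    @classmethod
    def default(cls, n_electrodes: int = 32) -> "ElectrodeLayout":
        """Standard layout with synthetic nominal coordinates.

        Labels follow the 10-10 extension names; coordinates are a synthetic
        stand-in (points on a 92 mm hemisphere via a golden-spiral rule) for
        the nominal positions shipped with real recordings.  Users processing
        deposited data should load the accompanying electrode TSV instead.
        """
        if n_electrodes == 32:
            labels = DEFAULT_LABELS
        else:
            labels = tuple(f"E{i}" for i in range(1, n_electrodes + 1))
        golden = np.pi * (3.0 - np.sqrt(5.0))
        k = np.arange(n_electrodes)
        z = 0.05 + 0.95 * (k + 0.5) / n_electrodes  # upper hemisphere only
        r = np.sqrt(1.0 - z**2)
        theta = golden * k
        coords = 92.0 * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        return cls(n_electrodes, labels, coords)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElectrodeLayout":
        """Load a ``label, x, y, z`` tab-separated electrode file."""
        df = pd.read_csv(path, sep="\t")
        missing = {"label", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ProtocolError(f"electrode TSV missing columns: {sorted(missing)}")
        return cls(len(df), tuple(df["label"].astype(str)),
                   df[["x", "y", "z"]].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Injection protocol and measurement list
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionProtocol:
    """Ordered list of (source, sink) current-injection electrode pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        for src, snk in self.pairs:
            if src == snk:
                raise ProtocolError(f"injection pair ({src}, {snk}) has source == sink")
        seen: set[frozenset[int]] = set()
        for p in self.pairs:
            key = frozenset(p)
            if key in seen:
                warnings.warn(f"duplicate injection pair {p}; retained (order "
                              "matters for segmentation)", stacklevel=2)
            seen.add(key)

    @property
    def n_injections(self) -> int:
        return len(self.pairs)

    def validate(self, layout: ElectrodeLayout) -> None:
        for src, snk in self.pairs:
            for e in (src, snk):
                if not 1 <= e <= layout.n_electrodes:
                    raise ProtocolError(
                        f"electrode index {e} out of range "
                        f"[1, {layout.n_electrodes}]")

    @classmethod
    def default_31(cls) -> "InjectionProtocol":
        """The shipped 31-pair protocol (synthetic placeholder).

        The published protocol file is not reproduced here; this default is a
        documented placeholder chosen for pair diversity (electrode
        separations 16, 10, 6 and 3 around the ring).  Users processing real
        recordings must supply the published protocol file.
        """
        text = (importlib.resources.files("mfeit.data")
                / "synthetic_default_injection_pairs.txt").read_text()
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "InjectionProtocol":
        pairs = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ProtocolError(f"expected 2 columns per pair line, got {line!r}")
            pairs.append((int(parts[0]), int(parts[1])))
        return cls(tuple(pairs))

    @classmethod
    def from_file(cls, path: str | Path) -> "InjectionProtocol":
        return cls.from_text(Path(path).read_text())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s} {k}\n" for s, k in self.pairs))


#: Supported measurement-list column orders.  ``example`` follows the worked
#: single-row convention ``[V+ CS+ CS- V-]`` used in published protocol
#: tables; ``header`` follows the column-header description
#: ``[CS+ CS- V+ V-]``.  The two disagree in the published record format;
#: see the methods note.
COLUMN_ORDERS = {
    "example": (2, 0, 1, 3),  # file col -> canonical (cs+, cs-, v+, v-) slot
    "header": (0, 1, 2, 3),
}


@dataclass(frozen=True)
class MeasurementList:
    """Expanded per-measurement electrode table.

    ``rows`` has canonical columns ``(CS+, CS-, V+, V-)`` — the two
    current-carrying electrodes, the sensed electrode and the voltage
    reference (always the common electrode).  Column order only matters for
    file I/O; see :data:`COLUMN_ORDERS`.
    """

    rows: np.ndarray
    common_electrode: int
    includes_injection: bool = False

    def __post_init__(self):
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=int))
        if self.rows.ndim != 2 or self.rows.shape[1] != 4:
            raise ProtocolError(f"measurement list must be n x 4, got {self.rows.shape}")
        if np.any(self.rows[:, 3] != self.common_electrode):
            raise ProtocolError("every V- entry must be the common electrode")
        if not self.includes_injection:
            bad = ((self.rows[:, 2] == self.rows[:, 0])
                   | (self.rows[:, 2] == self.rows[:, 1]))
            if np.any(bad):
                raise ProtocolError(
                    f"rows {np.nonzero(bad)[0].tolist()} measure on an "
                    "injecting electrode")

    @property
    def n_protocol(self) -> int:
        return len(self.rows)

    def to_array(self, column_order: str = "example") -> np.ndarray:
        perm = COLUMN_ORDERS[column_order]
        out = np.empty_like(self.rows)
        for file_col, canon_col in enumerate(perm):
            out[:, file_col] = self.rows[:, canon_col]
        return out

    @classmethod
    def from_array(cls, arr: np.ndarray, common_electrode: int,
                   column_order: str = "example") -> "MeasurementList":
        arr = np.asarray(arr, dtype=int)
        perm = COLUMN_ORDERS[column_order]
        rows = np.empty_like(arr)
        for file_col, canon_col in enumerate(perm):
            rows[:, canon_col] = arr[:, file_col]
        return cls(rows, common_electrode)

    def to_file(self, path: str | Path, column_order: str = "example") -> None:
        np.savetxt(path, self.to_array(column_order), fmt="%d")

    @classmethod
    def from_file(cls, path: str | Path, common_electrode: int,
                  column_order: str = "example") -> "MeasurementList":
        arr = np.loadtxt(path, dtype=int, ndmin=2)
        return cls.from_array(arr, common_electrode, column_order)


def build_measurement_list(protocol: InjectionProtocol, layout: ElectrodeLayout,
                           exclude_injection: bool = True) -> MeasurementList:
    """Expand injection pairs into the single-ended measurement table.

    Row order is injection-major, electrode-minor.  With
    ``exclude_injection`` the two current-carrying electrodes are dropped
    from each injection, giving ``n_injections * (n_electrodes - 2)`` rows
    (930 for the standard 31-injection, 32-electrode arrangement); without
    it every electrode is listed (992 rows).
    """
    protocol.validate(layout)
    common = layout.common_electrode
    rows = []
    for src, snk in protocol.pairs:
        for e in range(1, layout.n_electrodes + 1):
            if exclude_injection and e in (src, snk):
                continue
            rows.append((src, snk, e, common))
    return MeasurementList(np.array(rows, dtype=int), common,
                           includes_injection=not exclude_injection)


# ---------------------------------------------------------------------------
# Frequency plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanEntry:
    """One carrier of the injection schedule.

    ``injection_time_ms`` is the rounded duration ``1000 * periods /
    carrier``; synthesis and segmentation use the exact value
    ``periods / carrier`` (see :meth:`duration_s`).
    """

    carrier_hz: float
    amplitude_ua: float
    periods: int
    injection_time_ms: int
    filter_spec: FilterSpec | None = None

    @property
    def duration_s(self) -> float:
        return self.periods / self.carrier_hz

    def segment_samples(self, fs: float) -> int:
        # floor: the trimming stage makes the pipeline insensitive to the
        # +-1 sample boundary choice
        return int(np.floor(self.duration_s * fs))

    def validate(self) -> None:
        expected = round(1000.0 * self.periods / self.carrier_hz)
        if self.injection_time_ms != expected:
            raise PlanError(
                f"row at {self.carrier_hz} Hz: injection time "
                f"{self.injection_time_ms} ms inconsistent with "
                f"{self.periods} periods (expected {expected} ms)")
        if self.amplitude_ua <= 0:
            raise PlanError(f"row at {self.carrier_hz} Hz: non-positive amplitude")


@dataclass(frozen=True)
class FrequencyPlan:
    """Ordered multi-frequency injection schedule."""

    entries: tuple[PlanEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise PlanError("empty frequency plan")
        for e in self.entries:
            e.validate()
        carriers = [e.carrier_hz for e in self.entries]
        if not all(a < b for a, b in zip(carriers, carriers[1:])):
            raise PlanError("carrier frequencies must be strictly increasing")
        amps = [e.amplitude_ua for e in self.entries]
        if not all(a <= b for a, b in zip(amps, amps[1:])):
            raise PlanError("current amplitudes must be non-decreasing with frequency")

    @property
    def n_frequencies(self) -> int:
        return len(self.entries)

    @property
    def carriers(self) -> np.ndarray:
        return np.array([e.carrier_hz for e in self.entries])

    @property
    def amplitudes_ua(self) -> np.ndarray:
        return np.array([e.amplitude_ua for e in self.entries])

    @property
    def max_amplitude_ua(self) -> float:
        return float(self.amplitudes_ua.max())

    def filter_overrides(self) -> dict[float, FilterSpec]:
        return {e.carrier_hz: e.filter_spec for e in self.entries
                if e.filter_spec is not None}

    def frame_duration_s(self, n_injections: int = 1) -> float:
        """Active injection time of one frame (sum over carriers x injections)."""
        return n_injections * sum(e.duration_s for e in self.entries)

    # -- construction / serialisation ----------------------------------

    @classmethod
    def table1(cls) -> "FrequencyPlan":
        """The built-in 17-carrier full-spectrum schedule."""
        return cls(tuple(
            PlanEntry(c, a, p, round(1000.0 * p / c), FilterSpec.from_string(f, c))
            for c, a, p, f in TABLE1_ROWS))

    @classmethod
    def table1_td(cls) -> "FrequencyPlan":
        """The reduced-spectrum (time-difference) subset: 200/1200/2000 Hz."""
        full = cls.table1()
        return cls(tuple(e for e in full.entries if e.carrier_hz in TD_CARRIERS))

    @classmethod
    def from_config(cls, source: str | Path) -> "FrequencyPlan":
        cp = configparser.ConfigParser()
        cp.read_string(Path(source).read_text())
        entries = []
        for section in cp.sections():
            if not section.startswith("carrier"):
                raise PlanError(f"unexpected config section {section!r}")
            carrier = float(section.split(None, 1)[1])
            sec = cp[section]
            filt = sec.get("filter", "").strip()
            entries.append(PlanEntry(
                carrier,
                float(sec["amplitude_ua"]),
                int(sec["periods"]),
                int(sec["injection_time_ms"]),
                FilterSpec.from_string(filt, carrier) if filt else None,
            ))
        entries.sort(key=lambda e: e.carrier_hz)
        return cls(tuple(entries))

    def to_config(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for e in self.entries:
            sec = f"carrier {e.carrier_hz:g}"
            cp[sec] = {
                "amplitude_ua": f"{e.amplitude_ua:g}",
                "periods": str(e.periods),
                "injection_time_ms": str(e.injection_time_ms),
            }
            if e.filter_spec is not None:
                cp[sec]["filter"] = e.filter_spec.to_string()
        buf = io.StringIO()
        cp.write(buf)
        Path(path).write_text(buf.getvalue())


def load_frequency_plan(source: str | Path) -> FrequencyPlan:
    """Load a frequency plan from a built-in name or a config file.

    ``"table1"`` is the full 17-carrier schedule; ``"table1_td"`` the
    3-carrier reduced-spectrum variant; anything else is read as a config
    file path (one ``[carrier <Hz>]`` section per entry).
    """
    if source == "table1":
        return FrequencyPlan.table1()
    if source == "table1_td":
        return FrequencyPlan.table1_td()
    return FrequencyPlan.from_config(source)
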