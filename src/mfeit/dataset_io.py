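"""Published dataset records: EITDATA / EITSETTINGS JSON and file naming.

The final processed voltages are published as a list of per-recording
``EITDATA`` records (classification, full and cleaned 930 x 17 voltage
matrices, removal metadata) plus one shared ``EITSETTINGS`` record (carrier
frequencies, the n_protocol x 4 measurement protocol and electrode
positions).  Removed measurements are NaN in memory and the literal string
``"_NaN_"`` in JSON, keeping matrix dimensions fixed while remaining valid
strict JSON.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

import numpy as np

from .errors import SchemaError, SerializationError

NAN_SENTINEL = "_NaN_"
NAME_TAG_RE = re.compile(r"^[PS]\d+[AB]?$")

CLASSIFICATIONS = ("Healthy", "Ischaemia", "Haemorrhage")
SUB_CLASSIFICATIONS = ("Healthy", "small ischaemia", "big ischaemia",
                       "small haemorrhage", "big haemorrhage")


@dataclass
class EITDataset:
    """One recording session's published record."""

    name_tag: str
    classification: str
    sub_classification: str
    voltages_full: np.ndarray
    voltages_cleaned: np.ndarray
    removed_channels: list = field(default_factory=list)
    diagnosis: str = ""
    study_id: str = ""
    comments: str = ""

    def __post_init__(self):
        self.voltages_full = np.asarray(self.voltages_full, dtype=float)
        self.voltages_cleaned = np.asarray(self.voltages_cleaned, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not NAME_TAG_RE.match(self.name_tag):
            raise SchemaError(f"NameTag {self.name_tag!r} does not match "
                              f"{NAME_TAG_RE.pattern}")
        if self.classification not in CLASSIFICATIONS:
            raise SchemaError(f"Classification {self.classification!r} not in "
                              f"{CLASSIFICATIONS}")
        if self.sub_classification not in SUB_CLASSIFICATIONS:
            raise SchemaError(f"SubClassification {self.sub_classification!r} "
                              f"not in {SUB_CLASSIFICATIONS}")
        if self.voltages_full.shape != self.voltages_cleaned.shape:
            raise SchemaError(
                f"VoltagesFull {self.voltages_full.shape} and VoltagesCleaned "
                f"{self.voltages_cleaned.shape} differ in shape")
        keep = ~np.isnan(self.voltages_cleaned)
        if not np.array_equal(self.voltages_cleaned[keep],
                              self.voltages_full[keep]):
            raise SchemaError("VoltagesCleaned differs from VoltagesFull on "
                              "surviving entries")

    def to_record(self) -> dict:
        return {
            "NameTag": self.name_tag,
            "Classification": self.classification,
            "SubClassification": self.sub_classification,
            "VoltagesFull": _encode_array(self.voltages_full),
            "VoltagesCleaned": _encode_array(self.voltages_cleaned),
            "RemovedChannels": self.removed_channels,
            "Diagnosis": self.diagnosis,
            "StudyID": self.study_id,
            "Comments": self.comments,
        }

    _FIELDS = {"NameTag": "name_tag", "Classification": "classification",
               "SubClassification": "sub_classification",
               "VoltagesFull": "voltages_full",
               "VoltagesCleaned": "voltages_cleaned",
               "RemovedChannels": "removed_channels",
               "Diagnosis": "diagnosis", "StudyID": "study_id",
               "Comments": "comments"}

    @classmethod
    def from_record(cls, rec: dict) -> "EITDataset":
        unknown = set(rec) - set(cls._FIELDS)
        if unknown:
            warnings.warn(f"ignoring unknown EITDATA fields {sorted(unknown)}",
                          stacklevel=2)
        missing = {"NameTag", "Classification", "SubClassification",
                   "VoltagesFull", "VoltagesCleaned"} - set(rec)
        if missing:
            raise SchemaError(f"EITDATA record missing fields {sorted(missing)}")
        kwargs = {attr: rec[name] for name, attr in cls._FIELDS.items()
                  if name in rec}
        kwargs["voltages_full"] = _decode_array(kwargs["voltages_full"],
                                                "VoltagesFull")
        kwargs["voltages_cleaned"] = _decode_array(kwargs["voltages_cleaned"],
                                                   "VoltagesCleaned")
        return cls(**kwargs)


@dataclass
class EITSettings:
    """Acquisition parameters shared by every record."""

    freq: np.ndarray
    protocol: np.ndarray
    electrode_positions: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.protocol = np.asarray(self.protocol, dtype=int)
        self.electrode_positions = np.asarray(self.electrode_positions,
                                              dtype=float)
        if np.any(np.diff(self.freq) <= 0):
            raise SchemaError("Freq must be strictly increasing")
        if self.protocol.ndim != 2 or self.protocol.shape[1] != 4:
            raise SchemaError(f"Protocol must be n x 4, got {self.protocol.shape}")
        n_el = len(self.electrode_positions)
        if self.protocol.min() < 1 or self.protocol.max() > n_el + 1:
            raise SchemaError("Protocol electrode indices out of layout range")

    def to_record(self) -> dict:
        return {
            "Freq": _encode_array(self.freq),
            "Protocol": self.protocol.tolist(),
            "ElectrodePositions": _encode_array(self.electrode_positions),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "EITSettings":
        missing = {"Freq", "Protocol", "ElectrodePositions"} - set(rec)
        if missing:
            raise SchemaError(f"EITSETTINGS missing fields {sorted(missing)}")
        return cls(_decode_array(rec["Freq"], "Freq"),
                   np.asarray(rec["Protocol"]),
                   _decode_array(rec["ElectrodePositions"], "ElectrodePositions"))


# ---------------------------------------------------------------------------
# The "_NaN_" JSON dialect
# ---------------------------------------------------------------------------

def _encode_array(arr: np.ndarray):
    """Nested row-major lists with NaN as the sentinel string."""
    def enc(v):
        if isinstance(v, list):
            return [enc(x) for x in v]
        if math.isnan(v):
            return NAN_SENTINEL
        if not math.isfinite(v):
            raise SerializationError(
                f"non-finite value {v!r} has no published JSON encoding")
        return v
    return enc(np.asarray(arr, dtype=float).tolist())


def _decode_array(obj, where: str) -> np.ndarray:
    def dec(v):
        if isinstance(v, list):
            return [dec(x) for x in v]
        if v == NAN_SENTINEL:
            return math.nan
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise SchemaError(f"{where}: unexpected value {v!r}")
        return float(v)
    try:
        return np.asarray(dec(obj), dtype=float)
    except ValueError as exc:
        raise SchemaError(f"{where}: ragged or non-numeric array") from exc


# ---------------------------------------------------------------------------
# File-level read/write
# ---------------------------------------------------------------------------

def write_dataset_json(datasets: list[EITDataset], settings: EITSettings,
                       path: str | Path) -> None:
    """Write the published JSON container (canonical key order, 1-space
    indent); floats use Python's shortest round-trip repr, so a
    write -> read -> write cycle is byte-identical."""
    doc = {
        "EITDATA": [d.to_record() for d in datasets],
        "EITSETTINGS": settings.to_record(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, allow_nan=False) + "\n")


def read_dataset_json(path: str | Path) -> tuple[list[EITDataset], EITSettings]:
    doc = json.loads(Path(path).read_text())
    missing = {"EITDATA", "EITSETTINGS"} - set(doc)
    if missing:
        raise SchemaError(f"dataset file missing top-level {sorted(missing)}")
    datasets = [EITDataset.from_record(rec) for rec in doc["EITDATA"]]
    settings = EITSettings.from_record(doc["EITSETTINGS"])
    return datasets, settings


# ---------------------------------------------------------------------------
# Archive file naming
# ---------------------------------------------------------------------------

_KIND_RE = re.compile(r"^(MF|TD|Z)(\d*)$")


def resolve_files(tag: str, kind: str, root: str | Path = "") -> PurePosixPath:
    """Expected raw-file path for a recording, per the archive convention.

    ``("P5", "MF")`` resolves to ``Patients/Patient_5/P5_MF1.bdf``;
    ``("S3", "Z2")`` to ``Subjects/Subject_3/S3_Z2.bdf``.  Session suffixes
    (``P12B``) keep the numbered folder and the full tag in the file name.
    Pure function: existence is not checked.
    """
    m = re.match(r"^([PS])(\d+)([AB]?)$", tag)
    if not m:
        raise SchemaError(f"invalid NameTag {tag!r}")
    group, num, _suffix = m.groups()
    km = _KIND_RE.match(kind)
    if not km:
        raise SchemaError(f"invalid recording kind {kind!r} (MF, TD or Z#)")
    base, idx = km.groups()
    idx = idx or "1"
    top = "Patients" if group == "P" else "Subjects"
    folder = f"{'Patient' if group == 'P' else 'Subject'}_{num}"
    return PurePosixPath(root) / top / folder / f"{tag}_{base}{idx}.bdf"
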