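"""Exception hierarchy for the MFEIT processing chain."""


class MFEITError(Exception):
    """Base class for all package errors."""


class ProtocolError(MFEITError):
    """Invalid electrode layout, injection pair or measurement protocol."""


class PlanError(MFEITError):
    """Inconsistent or unparseable frequency plan."""


class FilterDesignError(MFEITError):
    """A filter cannot be designed for the requested carrier/segment."""


class SynthesisError(MFEITError):
    """Synthetic recording parameters are infeasible."""


class ModelError(MFEITError):
    """Resistor-network phantom is singular or disconnected."""


class SegmentationError(MFEITError):
    """Trigger layout does not match the expected protocol structure."""


class DemodulationError(MFEITError):
    """A segment is too short (or otherwise unusable) for demodulation."""


class SchemaError(MFEITError):
    """Dataset record violates the published structure."""


class SerializationError(MFEITError):
    """Value cannot be represented in the published JSON dialect."""
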