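"""Exception hierarchy shared across the toolkit."""


class BiomechError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(BiomechError, ValueError):
    """A parameter is outside its admissible range (e.g. cutoff >= Nyquist)."""


class SignalTooShortError(BiomechError, ValueError):
    """The signal is shorter than the filter's edge-padding requirement."""


class UnitMismatchError(BiomechError, ValueError):
    """An operation received a signal in the wrong physical units."""


class NoContractionError(BiomechError, ValueError):
    """No contraction window is available where at least one is required."""


class StimulusNotFoundError(BiomechError, ValueError):
    """No stimulation artefact (trigger edge or torque transient) was found."""


class InsufficientPlateauError(BiomechError, ValueError):
    """The requested pre-stimulus plateau window extends outside the contraction."""


class CannotNormalizeError(BiomechError, ValueError):
    """An envelope with no strictly positive maximum cannot be normalized."""


class MeshError(BiomechError, ValueError):
    """The surface mesh violates a geometric precondition (e.g. not watertight)."""
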