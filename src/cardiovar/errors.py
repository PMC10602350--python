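"""Exception types shared across the package."""


class CardiovarError(Exception):
    """Base class for all package-specific errors."""


class UnsegmentableRecordError(CardiovarError):
    """Raised when a pressure-volume record contains no detectable cardiac cycles."""


class NonPhysicalParametersError(CardiovarError):
    """Raised when a circulation-model step would drive a compartment volume negative."""


class UnstableMapError(CardiovarError):
    """Raised when the stroke-volume map has |A| >= 1 and no stationary regime exists."""
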