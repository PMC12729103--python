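"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`PocketforgeError`
so callers can catch pipeline failures distinctly from programming errors.
"""


class PocketforgeError(Exception):
    """Base class for all pocketforge errors."""


class FormatError(PocketforgeError):
    """A file could not be parsed in the expected dialect."""


class EmptyStructureError(FormatError):
    """A structure file contained no ATOM records."""


class ParseError(FormatError):
    """A malformed token; carries the offending line number when known."""


class JoinError(PocketforgeError):
    """A residue identifier could not be resolved against a structure."""


class EmptyPocketError(PocketforgeError):
    """A geometric pocket rule selected no residues."""


class DegenerateInputError(PocketforgeError):
    """Input too small or empty for the requested operation."""


class ParameterError(PocketforgeError):
    """A parameter outside its documented range."""


class ConfigError(PocketforgeError):
    """An invalid run or filter configuration."""


class FeaturizationError(PocketforgeError):
    """A pocket example could not be turned into a feature matrix."""


class TrainingError(PocketforgeError):
    """Model training failed (shape mismatch, divergence)."""


class DataError(PocketforgeError):
    """Required per-residue data (e.g. pLDDT) missing."""
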