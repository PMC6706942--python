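"""Exception hierarchy shared across the package."""


class PiscapeError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(PiscapeError):
    """Malformed FASTA input; the message names the offending entry."""


class ValidationError(PiscapeError, ValueError):
    """Input violates a documented contract (alphabet, duplicates, labels...)."""


class SchemaError(PiscapeError):
    """A tabular input is missing required columns or uses unknown labels."""


class ConfigurationError(PiscapeError):
    """Incompatible parameter combination (e.g. bin layout vs. pI ranges)."""
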