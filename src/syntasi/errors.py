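"""Exception hierarchy shared across the package.

All errors derive from :class:`SynTasiError` so callers (and the CLI) can
catch package failures in one clause while still distinguishing categories.
"""


class SynTasiError(Exception):
    """Base class for all package errors."""


class LengthError(SynTasiError, ValueError):
    """A sequence component has the wrong length."""


class AlphabetError(SynTasiError, ValueError):
    """A sequence contains characters outside the nucleotide alphabet."""


class EmptyCassetteError(SynTasiError, ValueError):
    """A precursor was requested with no guide sequences."""


class NotFoundError(SynTasiError, ValueError):
    """A target-site sequence to be replaced is absent from the precursor."""


class AmbiguousSiteError(SynTasiError, ValueError):
    """A target-site sequence occurs more than once in the precursor."""


class DuplicateGuideError(SynTasiError, ValueError):
    """Two guides in one cassette share the same sequence."""


class FormatError(SynTasiError, ValueError):
    """A sequence file does not parse under its declared standard."""


class EmptyProfileError(SynTasiError, ValueError):
    """No reads mapped within the profiled size range."""


class NoWindowReadsError(SynTasiError, ValueError):
    """No reads fall inside the processing-accuracy window of a guide."""


class EmptyTableError(SynTasiError, ValueError):
    """No qualifying 21-nt reads downstream of the cleavage site."""


class ConfigError(SynTasiError, ValueError):
    """Invalid simulation or run configuration."""
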