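"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: DataError/FormatError -> 1, ConfigError -> 2.
"""


class RiboreporterError(Exception):
    """Base class for all package errors."""


class FormatError(RiboreporterError):
    """A file does not conform to the expected on-disk format."""


class DataError(RiboreporterError):
    """The data violate an invariant of the analysis (bad grids, empty series...)."""


class ConfigError(RiboreporterError):
    """A configuration file or parameter set is invalid."""
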