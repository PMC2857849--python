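"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class SnpblupError(Exception):
    """Base class for all package errors."""


class ConfigError(SnpblupError):
    """Invalid or infeasible configuration."""


class DataError(SnpblupError):
    """Malformed or inconsistent input data."""


class PedigreeError(DataError):
    """Pedigree structure problem (cycles, missing parents, ordering)."""


class FormatError(DataError):
    """File or matrix format problem."""


class NumericalError(SnpblupError):
    """Numerical failure (singular system, undefined metric, ...)."""
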