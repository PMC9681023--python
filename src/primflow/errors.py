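"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes (config errors -> 2,
data errors -> 3); library users catch them like any ValueError.
"""


class PrimflowError(Exception):
    """Base class for package errors."""


class ConfigError(PrimflowError):
    """Invalid configuration: bad window geometry, split sizes, grids, ..."""


class DataError(PrimflowError):
    """Invalid data content: degenerate quaternions, mismatched rates, ..."""


class SchemaError(DataError):
    """A table does not have the expected columns."""


class ParseError(DataError):
    """A cell of a table could not be parsed; carries the row index."""
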