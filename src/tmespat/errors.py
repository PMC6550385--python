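"""Exception hierarchy.

Configuration problems (bad parameters, unknown markers, broken schemas) and
data problems (unparsable rows, violated invariants) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class TmespatError(Exception):
    """Base class for all package errors."""


class ConfigError(TmespatError):
    """Invalid configuration: bad parameter value, unknown marker, bad rule."""


class SchemaError(ConfigError):
    """Column mapping does not match the input table."""


class DataError(TmespatError):
    """Input data violates a contract (parse failure, invariant breach)."""
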