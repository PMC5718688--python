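"""Exception hierarchy for mosdose.

All domain errors derive from :class:`MosdoseError` so callers (and the CLI)
can catch one base class; the concrete subclasses also inherit the matching
builtin (``ValueError``/``RuntimeError``) so they behave idiomatically.
"""


class MosdoseError(Exception):
    """Base class for all mosdose errors."""


class InvalidParameterError(MosdoseError, ValueError):
    """A parameter violates its physical or numerical precondition."""


class OutOfRangeError(MosdoseError, ValueError):
    """A depth, shift or position falls outside the supported domain."""


class FittingError(MosdoseError, RuntimeError):
    """A least-squares / optimisation step failed or is infeasible."""


class UndefinedDoseError(MosdoseError, ValueError):
    """Dose (and hence a dose-weighted quantity) is undefined at a point,
    e.g. a correction factor requested outside the radiation field."""


class ConfigError(MosdoseError, ValueError):
    """A run configuration file failed validation."""


class CSVFormatError(MosdoseError, ValueError):
    """A tabular input file is malformed (missing column, bad cell)."""
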