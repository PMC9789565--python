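"""Exception hierarchy for microcf.

Every error raised on a contract violation derives from :class:`MicrocfError`
so callers can distinguish pipeline failures from programming errors.
"""


class MicrocfError(Exception):
    """Base class for all microcf errors."""


class ConfigurationError(MicrocfError, ValueError):
    """An invalid configuration value (names the offending field)."""


class FormatError(MicrocfError, ValueError):
    """A malformed input file (merged abundance table or metadata)."""


class DataError(MicrocfError, ValueError):
    """Input data violate a statistical precondition (e.g. all-zero sample)."""


class DegenerateInputError(DataError):
    """A statistic is undefined on the input (e.g. constant vector)."""


class StratificationError(DataError):
    """A cross-validation fold lost one of the classes."""


class ContractError(MicrocfError, ValueError):
    """Mismatched shapes / feature sets between composed components."""


class InputError(MicrocfError, ValueError):
    """A single input instance violates a precondition (e.g. out of bounds)."""


class ModelError(MicrocfError, RuntimeError):
    """A learner failed to fit."""


class TrainingError(MicrocfError, RuntimeError):
    """Neural-network training diverged or was misconfigured."""


class NumericalError(MicrocfError, ArithmeticError):
    """A numerical operation failed (e.g. singular association matrix)."""
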