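"""Exception hierarchy.

``ConfigurationError`` signals an invalid model/parameter set (exit code 2 at
the CLI); every other error is a data/runtime problem (exit code 1).
"""


class AmplicloneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmplicloneError):
    """Invalid configuration: bad probabilities, conflicting barcodes, ..."""


class InputError(AmplicloneError):
    """Malformed input data (non-ACGTN sequence, missing columns, ...)."""


class SimulationError(AmplicloneError):
    """A simulation request that cannot be honoured (bad signature etc.)."""


class UndefinedStatisticError(AmplicloneError):
    """A statistic whose value is undefined for the given input
    (e.g. no single-cell pens, non-increasing growth series)."""
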