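"""Exception hierarchy.

``InputError`` marks invalid user input (malformed data, bad configuration);
``EstimationError`` marks a model that cannot be estimated from otherwise
valid input (single-group data, improper full conditionals).
"""


class BayesRmaError(Exception):
    """Base class for all package errors."""


class InputError(BayesRmaError, ValueError):
    """Invalid input: malformed dataset, dimension mismatch, bad option."""


class ConfigError(InputError):
    """Invalid run configuration (schema violation, unknown key)."""


class EstimationError(BayesRmaError, RuntimeError):
    """Estimation cannot proceed (degenerate design, improper conditional)."""
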