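"""Package-wide exception types."""


class GslMppError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(GslMppError):
    """A hyperparameter, column name or option is invalid or inconsistent."""


class InputError(GslMppError):
    """Input data cannot be used (empty, unlabeled, wrong split, ...)."""


class SmilesParseError(GslMppError):
    """A SMILES string could not be parsed; carries the offending string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class NumericalError(GslMppError):
    """Non-finite values encountered during model evaluation or training."""
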