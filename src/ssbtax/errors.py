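"""Exception types shared across the pipeline."""


class SSBTaxError(Exception):
    """Base class for all package errors."""


class InputValidationError(SSBTaxError):
    """An input table or configuration violates a declared invariant.

    Carries the full list of violations so callers can report all of them,
    not just the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ResidualRateError(SSBTaxError):
    """Residual (non-modelled) mortality or pYLD went negative in a cell."""


class PipelineError(SSBTaxError):
    """A runtime failure during scenario execution."""
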