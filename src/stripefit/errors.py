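"""Exception hierarchy shared across the package."""


class StripefitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StripefitError):
    """An input file does not conform to the expected dialect."""


class ValidationError(StripefitError):
    """A data structure violates one of its invariants."""


class LookupChannelError(StripefitError, KeyError):
    """A requested gene/channel/cohort is not present."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class GenerationError(StripefitError):
    """Synthetic-atlas generation is infeasible for the requested geometry."""


class DegenerateResponseError(StripefitError):
    """Training response is all-ON or all-OFF; no logistic fit is possible."""
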