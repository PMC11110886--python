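"""Exception hierarchy shared across the package."""


class CpceaError(Exception):
    """Base class for all package errors."""


class ValidationError(CpceaError, ValueError):
    """A configuration value or input violates a documented precondition."""


class InputFormatError(CpceaError, ValueError):
    """A tabular input does not conform to the expected schema."""


class EarningsLookupError(CpceaError, KeyError):
    """A caregiver key is absent from the earnings table."""

    def __init__(self, key):
        super().__init__(key)
        self.key = key

    def __str__(self) -> str:  # KeyError repr-quotes its payload
        return f"no earnings entry for caregiver key {self.key!r}"


class UnimputableError(CpceaError, ValueError):
    """A variable cannot be imputed (e.g. no observed values at all)."""
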