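"""Exception hierarchy for the deweather package."""


class DeweatherError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DeweatherError, ValueError):
    """An input object violates a documented invariant; the message names the field."""


class CoverageError(DeweatherError):
    """A period has too few non-missing days to yield a trustworthy mean."""


class CalendarError(DeweatherError, KeyError):
    """The holiday calendar has no entry for the requested winter season."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return self.args[0] if self.args else ""
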