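"""Exception hierarchy for forageval.

All package-raised errors derive from :class:`ForagevalError` so callers can
catch one base class; they also derive from ``ValueError`` so that generic
validation handling keeps working.
"""


class ForagevalError(ValueError):
    """Base class for all forageval errors."""


class ConfigError(ForagevalError):
    """A configuration value is inconsistent with the trial design."""


class ValidationError(ForagevalError):
    """An input value violates a documented invariant; names the field."""


class DomainError(ForagevalError):
    """A numeric argument is outside the mathematical domain of a formula."""


class DesignError(ForagevalError):
    """The data do not have the balanced, complete structure an analysis assumes."""
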