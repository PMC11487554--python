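"""Exception hierarchy for gutcore.

All errors raised by the package derive from :class:`GutcoreError` so callers
can catch one type at the CLI boundary.
"""


class GutcoreError(Exception):
    """Base class for all gutcore errors."""


class ValidationError(GutcoreError, ValueError):
    """An input violated a documented precondition."""


class DegenerateSampleError(ValidationError):
    """A sample column sums to zero and cannot be closed to 100%."""

    def __init__(self, sample: str):
        self.sample = sample
        super().__init__(f"sample {sample!r} has zero total abundance; cannot normalize")


class UnknownTaxonError(GutcoreError, KeyError):
    """A taxon identifier was not found in the table."""


class TaxonNameError(ValidationError):
    """A taxon identifier could not be parsed (e.g. no genus token)."""


class UndefinedPercentError(ValidationError):
    """A percentage was requested with a zero denominator."""


class InsufficientDataError(ValidationError):
    """Too few paired observations for the requested statistic."""


class UndefinedCorrelationError(GutcoreError, ValueError):
    """A ranked vector has zero variance; the correlation is undefined."""


class AlignmentError(ValidationError):
    """Abundance and clinical tables share no samples."""
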