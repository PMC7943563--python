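"""Exception hierarchy shared across the package."""


class NescoreError(Exception):
    """Base class for all package errors."""


class FormatError(NescoreError):
    """A file does not conform to its declared format."""


class ValidationError(NescoreError):
    """An in-memory object violates its invariants."""


class InsufficientOverlapError(NescoreError):
    """Too few signature genes found in the profile.

    Carries ``n_found`` and ``n_required`` so callers can report the count.
    """

    def __init__(self, n_found: int, n_required: int, sample_id: str | None = None):
        self.n_found = n_found
        self.n_required = n_required
        self.sample_id = sample_id
        where = f" for sample {sample_id!r}" if sample_id else ""
        super().__init__(
            f"only {n_found} signature genes found{where}; {n_required} required"
        )


class UndefinedCorrelationError(NescoreError):
    """A Pearson correlation is undefined (zero-variance vector)."""


class EmptyResultError(NescoreError):
    """An operation produced no scoreable output at all."""
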