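"""Exception hierarchy shared across the package."""


class EutsolError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EutsolError, ValueError):
    """An argument is outside the physically meaningful domain."""


class ParseError(EutsolError, ValueError):
    """A file does not conform to its documented schema."""


class ValidationError(EutsolError, ValueError):
    """A value violates a type invariant."""


class AlignmentError(EutsolError, ValueError):
    """Two series that must share an index (temperatures, grids, labels) do not."""


class FitError(EutsolError, ValueError):
    """A regression cannot be carried out (degenerate or rank-deficient design)."""
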