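"""Exception hierarchy.

All exceptions raised deliberately by this package derive from
:class:`RhythmdiffError`, so callers can catch one type at an application
boundary (e.g., the CLI) while still distinguishing failure modes.
"""


class RhythmdiffError(Exception):
    """Base class for all errors raised by rhythmdiff."""


class IdentityError(RhythmdiffError):
    """Gene or sample identifiers are duplicated, missing, or misaligned."""


class ParseError(RhythmdiffError):
    """A file could not be parsed into the expected tabular structure."""


class DomainError(RhythmdiffError):
    """A numeric input lies outside the domain an operation requires."""


class DesignError(RhythmdiffError):
    """A design matrix is rank deficient or otherwise unusable."""


class ConfigError(RhythmdiffError):
    """A model/workflow/simulation specification is invalid."""


class EvaluationError(RhythmdiffError):
    """An evaluation was requested on degenerate inputs (e.g., empty class)."""
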