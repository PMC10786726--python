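"""Exception hierarchy shared across the package."""


class ApobecToolsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ApobecToolsError):
    """A record or data structure violates a documented invariant."""


class FormatError(ApobecToolsError):
    """A file could not be parsed as the declared format."""


class UndefinedResultError(ApobecToolsError):
    """The requested quantity is mathematically undefined on this input
    (e.g. an ITH ratio with zero altered bases, fractions of an empty sample)."""


class NotAnSNV(ApobecToolsError):
    """Skip signal: the variant is not a single-nucleotide substitution."""


class NoContext(ApobecToolsError):
    """No-context signal: the flanking window is out of range or contains
    non-ACGT bases; the mutation is counted but excluded from statistics."""


class UnattributableError(ApobecToolsError):
    """A mutation channel has probability zero under every active signature."""
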