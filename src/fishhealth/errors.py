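"""Exception hierarchy for the fishhealth package."""


class FishHealthError(Exception):
    """Base class for all package errors."""


class ValidationError(FishHealthError):
    """A value violates a domain invariant (negative weight, bad season token, ...)."""


class SchemaError(FishHealthError):
    """A table is missing a required column or has an unusable header."""


class AlignmentError(FishHealthError):
    """Sequences that should form an alignment have unequal lengths."""


class SaturationError(FishHealthError):
    """A p-distance at or beyond 0.75, where the Jukes-Cantor correction diverges."""


class InsufficientDataError(FishHealthError):
    """Too few observations for the requested computation."""


class ConfigurationError(FishHealthError):
    """A generator or pipeline configuration violates its invariants."""
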