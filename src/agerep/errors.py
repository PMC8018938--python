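"""Exception hierarchy shared across the package."""


class AgerepError(ValueError):
    """Base class for all model/validation errors raised by agerep."""


class DegenerateInputError(AgerepError):
    """An input is structurally valid but makes the requested quantity undefined
    (e.g. an Euler-Lotka equation with no age-dependent term)."""


class GuardViolationError(AgerepError):
    """A dynamic system was evaluated at a state where one of its divisions is
    numerically undefined (near-empty age class, boundary sex ratio, ...)."""


class ConfigError(AgerepError):
    """A scenario configuration file is missing keys or violates an invariant."""


class SchemaError(AgerepError):
    """A trajectory file does not follow the tidy CSV schema."""
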