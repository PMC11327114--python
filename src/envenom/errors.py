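"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An operation precondition was violated."""


class NonConvergenceError(RuntimeError):
    """An iterative procedure exhausted its iteration budget.

    Carries the last class offsets of the land allocator when raised there.
    """

    def __init__(self, message: str, offsets=None):
        super().__init__(message)
        self.offsets = offsets


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; names the offending class."""


class DegenerateDataError(ValueError):
    """Data carry no information for the requested fit (e.g. all-zero counts)."""


class ChecksumError(IOError):
    """A fixture file does not match its manifest checksum."""


class ConfigError(ValueError):
    """A run configuration failed schema validation."""
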