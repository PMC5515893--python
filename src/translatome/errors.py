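"""Exception hierarchy shared across the package."""


class TranslatomeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TranslatomeError):
    """A configuration value violates its documented constraints."""


class WrongUnitError(TranslatomeError):
    """An operation received a matrix in the wrong unit (counts vs RPKM)."""


class PairingError(TranslatomeError):
    """RPF/RNA samples or conditions cannot be matched one-to-one."""


class DegenerateSampleError(TranslatomeError):
    """A sample column is unusable (e.g. zero total counts)."""


class EmptyInputError(TranslatomeError):
    """An operation that needs at least one record received none."""
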