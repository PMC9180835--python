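class MemomirError(Exception):
    """Base class for package errors."""


class ConfigurationError(MemomirError, ValueError):
    """Inconsistent or incomplete configuration / reference setup."""


class InputError(MemomirError, ValueError):
    """Invalid input to an operation (bad coordinates, too few replicates, ...)."""
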