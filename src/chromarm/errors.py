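"""Exception hierarchy shared across chromarm modules."""


class ChromarmError(Exception):
    """Base class for all chromarm errors."""


class FormatError(ChromarmError, ValueError):
    """A file violates the expected on-disk format."""


class ParameterError(ChromarmError, ValueError):
    """A function argument is outside its valid domain."""


class DegenerateInputError(ChromarmError, ValueError):
    """Statistically degenerate input (e.g. zero variance in both samples)."""


class PartitionError(ChromarmError, ValueError):
    """A sequence cannot be split into arms (no, or multiple, central gaps)."""


class PairingError(ChromarmError, ValueError):
    """Arm scaffolds cannot be paired into a chromosome plan."""


class BuildError(ChromarmError, ValueError):
    """A chromosome plan references parts that are unavailable."""


class InputError(ChromarmError, ValueError):
    """Invalid in-memory input (e.g. asymmetric contact matrix)."""
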