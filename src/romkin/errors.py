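"""Exception hierarchy.

All package-specific failures derive from :class:`RomkinError` so callers
(and the CLI) can distinguish bad input/config (exit code 2) from bugs.
"""


class RomkinError(Exception):
    """Base class for all romkin errors."""


class FormatError(RomkinError):
    """A file does not conform to the documented dialect."""


class ConfigError(RomkinError):
    """An invalid configuration (palette, backend, generator, CLI options)."""


class InputError(RomkinError):
    """Invalid in-memory input (length mismatch, incomplete matrix, domain)."""


class InsufficientDataError(RomkinError):
    """Too few valid samples to produce a result."""


class DegenerateGeometryError(RomkinError):
    """A vector is too short to define a direction."""


class UndefinedStatisticError(RomkinError):
    """A statistic is undefined for this input (constant vector, zero mean)."""
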