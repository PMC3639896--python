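"""Exception hierarchy shared across the package."""


class MirtargetError(Exception):
    """Base class for all package errors."""


class InputError(MirtargetError, ValueError):
    """Malformed user input: bad sequence characters, negative counts, unknown ids."""


class ConfigError(MirtargetError, ValueError):
    """Inconsistent configuration, e.g. a rule region outside the miRNA length."""


class FormatError(MirtargetError, ValueError):
    """Malformed file content (FASTA/TSV/config)."""


class GenerationError(MirtargetError, RuntimeError):
    """The synthetic generator cannot satisfy a requested construction."""
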