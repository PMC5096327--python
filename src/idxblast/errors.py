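"""Exception hierarchy: user-facing input errors vs internal invariant failures."""


class IdxblastError(Exception):
    """Base class for all package errors."""


class InputError(IdxblastError):
    """Malformed or unusable user input (FASTA, parameters, file paths)."""


class FormatError(IdxblastError):
    """Corrupt or incompatible on-disk database/index file."""


class IntegrityError(IdxblastError):
    """Internal invariant violated (e.g. a subject reported from two blocks)."""
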