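"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (bad channel label,
    Nyquist violation, mismatched segment lengths, ...)."""


class FormatError(ValueError):
    """A file or container is structurally unusable: corrupted HDF5,
    unknown schema version, ragged segment bank, checkpoint/spec mismatch."""
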