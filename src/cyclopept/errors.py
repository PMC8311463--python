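"""Exception types shared across the package."""


class CyclopeptError(ValueError):
    """Base class for all data/validation errors raised by cyclopept."""


class SequenceError(CyclopeptError):
    """Invalid peptide sequence (unknown residue, bad topology, ...)."""


class FormatError(CyclopeptError):
    """Malformed input file or table."""


class FitError(CyclopeptError):
    """Degenerate input to a curve-fitting routine."""
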