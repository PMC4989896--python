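"""Exception hierarchy.

The CLI maps these onto exit codes: input/parse problems exit 3,
numerical failures exit 4.
"""


class KqdistError(Exception):
    """Base class for all package errors."""


class InputError(KqdistError):
    """A file could not be read or parsed."""


class FastqParseError(InputError):
    """Malformed FASTQ record."""


class PhredDialectError(InputError):
    """Decoded quality is negative; the other phred offset is likely."""


class SampleListError(InputError):
    """Problem in a file-of-files sample list."""


class NewickParseError(InputError):
    """Malformed Newick; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class NumericalError(KqdistError):
    """A statistic could not be computed (empty profile, bad background...)."""
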