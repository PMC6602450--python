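"""Error taxonomy shared across the package.

The CLI maps these onto exit codes; library users catch them directly.
"""


class GdtqaError(Exception):
    """Base class for all package errors."""


class FormatError(GdtqaError):
    """Malformed input file (PDB, FASTA, TSV, tabular hits)."""


class ValidationError(GdtqaError):
    """Input parsed but violates a documented invariant."""


class InputError(GdtqaError):
    """Missing files, bad paths, or unusable argument combinations."""
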