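"""Exception hierarchy for the pipeline."""


class PhylodemError(Exception):
    """Base class for all package errors."""


class FormatError(PhylodemError):
    """Malformed input file (bad FASTA syntax, illegal characters, empty file)."""


class AlignmentError(PhylodemError):
    """Sequences that should form an alignment do not (ragged lengths)."""


class SchemaError(PhylodemError):
    """A required column is missing from a metadata table."""


class DegenerateInputError(PhylodemError):
    """Input is syntactically valid but leaves nothing to analyze
    (e.g. every alignment column removed by complete deletion)."""


class FitFailureError(PhylodemError):
    """A model fit could not be performed on the given data."""
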