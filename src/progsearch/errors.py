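"""Exception taxonomy.

``FormatError`` covers malformed input files (exit code 1 in the CLI);
``ConsistencyError`` covers inputs that violate the progressive-search
precondition — mismatched parameters, a results file not produced from the
stated old database, negative histogram bins (exit code 2).
"""


class ProgsearchError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ProgsearchError):
    """Malformed input file (FASTA / MGF / TSV / parameter file)."""


class ConsistencyError(ProgsearchError):
    """Inputs violate the equivalence precondition of a progressive run."""
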