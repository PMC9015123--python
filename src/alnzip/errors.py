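"""Exception hierarchy.

``UsageError`` style validation problems raise ``ValueError`` subclasses so
library users get ordinary Python semantics; the CLI maps them onto exit
codes.
"""


class AlnzipError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(AlnzipError, ValueError):
    """Input is not parseable FASTA (no records, or data before a header)."""


class NotAnAlignmentError(AlnzipError, ValueError):
    """FASTA parsed fine but the records do not have equal lengths."""


class UnrecognizedArchiveError(AlnzipError, ValueError):
    """Bytes do not start with this tool's magic/version."""


class CorruptArchiveError(AlnzipError, ValueError):
    """Archive recognized but truncated, checksum-failed, or inconsistent."""


class UnsupportedBackendError(AlnzipError, ValueError):
    """Unknown entropy-backend identifier."""
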