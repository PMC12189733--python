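"""Exception hierarchy shared across the pipeline.

Validation problems (bad config, malformed input files) are kept separate
from runtime failures so the command-line layer can map them to distinct
exit codes.
"""


class EffbiasError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EffbiasError, ValueError):
    """Invalid parameter, specification or cross-table inconsistency."""


class FormatError(ValidationError):
    """Malformed on-disk input (bad delimiter, duplicate ids, bad labels)."""
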