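"""Exception hierarchy shared across the package."""


class MhcVoteError(Exception):
    """Base class for all package errors."""


class DataError(MhcVoteError):
    """Invalid input data: malformed FASTA, duplicate IDs, bad labels."""


class EncodingError(MhcVoteError):
    """A sequence cannot be encoded under the active encoder configuration."""


class ModelError(MhcVoteError):
    """Ensemble fitting, prediction or serialization failure."""
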