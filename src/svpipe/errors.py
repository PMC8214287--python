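"""Exception hierarchy shared across the pipeline."""


class SVPipeError(Exception):
    """Base class for all svpipe errors."""


class CigarError(SVPipeError):
    """Malformed CIGAR text; the message names the offending position."""


class MDFormatError(SVPipeError):
    """MD tag inconsistent with the CIGAR, or syntactically invalid."""


class FastqFormatError(SVPipeError):
    """Malformed FASTQ record; the message carries the record index."""


class SchemaError(SVPipeError):
    """Feature-vector / model schema version or dimension mismatch."""


class ReferenceMismatchError(SVPipeError):
    """Two alignment streams disagree on @SQ contig names or lengths."""


class CapabilityError(SVPipeError):
    """An external binary required for a stage is unavailable."""


class CapacityError(SVPipeError):
    """A simulated reference cannot host the requested variants."""
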