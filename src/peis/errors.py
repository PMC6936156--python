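"""Exception hierarchy for peis."""


class PeisError(Exception):
    """Base class for all peis errors."""


class ParseError(PeisError):
    """Malformed or invalid input file."""


class DataError(PeisError):
    """Structurally valid input that violates a data contract."""


class DegenerateTestError(DataError):
    """A per-site hypothesis test cannot be computed (e.g. zero variance)."""
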