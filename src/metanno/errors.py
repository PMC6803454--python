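"""Exception hierarchy for the annotation engine.

Every failure mode that callers are expected to handle gets its own class;
all inherit from :class:`MetannoError` so a pipeline driver can catch one
root type.
"""


class MetannoError(Exception):
    """Base class for all errors raised by this package."""


class DuplicateIdError(MetannoError):
    """Two input sequences share an identifier; the run must terminate."""

    def __init__(self, dup_id: str):
        self.dup_id = dup_id
        super().__init__(f"duplicate sequence id: {dup_id!r}")


class EmptyInputError(MetannoError):
    """An input that must contain at least one record was empty."""


class DegenerateSequenceError(MetannoError):
    """A sequence became empty after gap/pad removal."""


class ParseError(MetannoError):
    """A structured text file violated its dialect."""

    def __init__(self, message: str, path=None, line_no=None):
        self.path = path
        self.line_no = line_no
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line_no}]" if line_no is not None else "]"
        super().__init__(message + loc)


class CoordinateError(MetannoError):
    """A feature interval had end < start or otherwise invalid coordinates."""


class OutOfBoundsError(MetannoError):
    """A feature extends past the end of its contig."""


class MissingSubjectError(MetannoError):
    """A best hit's subject id is absent from the lineage reference map."""


class LineageFormatError(MetannoError):
    """A lineage string had an unknown rank prefix or out-of-order ranks."""


class GrammarError(MetannoError):
    """A FOAM model name did not match the KO:K#####[_EC] grammar."""


class NegativeWeightError(MetannoError):
    """A gene weight was negative; abundance weights must be >= 0."""


class NoClassifiedGenesError(MetannoError):
    """A MAG has no genes classified at the requested rank."""


class ZeroTotalError(MetannoError):
    """A sample's total weight is zero; proportions are undefined."""


class UnknownContigError(MetannoError):
    """A gene references a contig absent from the depth table (strict mode)."""


class DuplicateGeneError(MetannoError):
    """A spectral-count table listed the same gene id twice."""


class InfeasibleDensityError(MetannoError):
    """Requested feature density cannot be placed without overlap."""
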