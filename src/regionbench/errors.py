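"""Exception hierarchy.

``InvalidArgument`` covers precondition violations (bad parameters, malformed
requests); ``DataError`` covers problems with the data itself (unparseable
files, impossible extractions).  The CLI maps usage errors to exit code 1 and
data errors to exit code 2.
"""


class RegionBenchError(Exception):
    """Base class for all package errors."""


class InvalidArgument(RegionBenchError, ValueError):
    """A parameter violates a documented precondition."""


class DataError(RegionBenchError):
    """Input data cannot be processed (parse failures, impossible requests)."""


class NewickParseError(DataError):
    """Malformed newick input; message carries the offending position."""


class NoAmplicon(DataError):
    """No valid primer pair placement on a sequence."""

    def __init__(self, genome_id: str, region_label: str, reason: str = ""):
        self.genome_id = genome_id
        self.region_label = region_label
        self.reason = reason
        msg = f"no amplicon for region {region_label!r} on genome {genome_id!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class AmpliconLengthError(DataError):
    """Amplicon found but its length falls outside the accepted range."""

    def __init__(self, genome_id: str, region_label: str, length: int,
                 lo: int, hi: int):
        self.genome_id = genome_id
        self.region_label = region_label
        self.length = length
        super().__init__(
            f"amplicon for region {region_label!r} on genome {genome_id!r} "
            f"has length {length}, outside [{lo}, {hi}]"
        )
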