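"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: usage/config errors -> 2,
input parse errors -> 3, computation errors -> 4.
"""


class EetError(Exception):
    """Base class for all package errors."""


class UsageError(EetError):
    """Invalid arguments, configuration, or unsupported requests."""


class StructureParseError(EetError):
    """An input coordinate file could not be parsed."""


class ComputationError(EetError):
    """A pipeline computation failed on otherwise valid inputs."""


class GeometryError(ComputationError):
    """Degenerate or missing geometry (zero vectors, absent atoms...)."""


class CouplingError(ComputationError):
    """A pairwise coupling could not be evaluated."""


class ParameterError(ComputationError):
    """A spectral or thermodynamic parameter is out of range."""


class PartitionError(ComputationError):
    """A domain partition does not cover the site set or overlaps."""


class PathwayError(ComputationError):
    """A requested pathway is missing an edge or is unreachable."""


class ResidueLookupError(ComputationError):
    """A residue referenced by (chain, number) does not exist."""
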