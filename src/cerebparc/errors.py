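"""Exception types shared across the package."""


class CerebparcError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CerebparcError, ValueError):
    """A parameter violates a documented precondition."""


class IncompatibleInputError(CerebparcError, ValueError):
    """Inputs that must agree (shapes, geometries, lengths) do not."""


class RankDeficiencyError(CerebparcError, ValueError):
    """A regression design matrix is rank deficient.

    ``components`` names the offending rows/columns when identifiable.
    """

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = list(components) if components is not None else []


class EmptyResultError(CerebparcError, ValueError):
    """An operation found no qualifying data (e.g. no eligible voxel pairs)."""


class UndefinedResultError(CerebparcError, ValueError):
    """A statistic is undefined for the given inputs (e.g. no eligible bins)."""


class FormatError(CerebparcError, ValueError):
    """A file on disk does not match the expected format or geometry."""
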