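"""Exception types raised across the pipeline stages."""


class PsyconnError(Exception):
    """Base class for all pipeline errors."""


class InvalidMomentError(PsyconnError, ValueError):
    """A requested score distribution moment is invalid (e.g. SD <= 0)."""


class PlacementError(PsyconnError, ValueError):
    """A planted focus lies outside the simulation grid."""


class DegenerateDesignError(PsyconnError, ValueError):
    """A regression design is degenerate (constant predictor)."""


class InsufficientDataError(PsyconnError, ValueError):
    """Too few subjects for the requested fit."""


class CollinearityError(PsyconnError, ValueError):
    """A confound matrix is rank deficient; names the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"confound matrix is rank deficient; offending columns: {self.columns}"
        )


class DegenerateSeriesError(PsyconnError, ValueError):
    """A time-series column is constant; identifies the ROI."""


class AlignmentError(PsyconnError, ValueError):
    """Subject ids, ROI ids or edge ids do not align across inputs."""
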