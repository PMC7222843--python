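"""Exception hierarchy for slurrycbc.

All package errors derive from :class:`SlurryCBCError` so callers can catch
one base class at batch boundaries and keep per-record failures isolated.
"""


class SlurryCBCError(Exception):
    """Base class for all slurrycbc errors."""


class FormatError(SlurryCBCError):
    """A titration log or manifest does not have the expected structure."""


class DataError(SlurryCBCError):
    """Parsed data violate an invariant (e.g. non-monotone cumulative volume)."""


class InsufficientDataError(DataError):
    """Too few points for the requested operation."""


class ParameterError(SlurryCBCError):
    """An invalid parameter value (non-positive mass, bad window, ...)."""


class FitError(SlurryCBCError):
    """Polynomial regression failed (rank deficiency, ill-conditioning)."""


class DegenerateFitError(FitError):
    """The fitted curve is too flat over too much of the window for a
    meaningful reciprocal-slope transform."""


class CoverageError(SlurryCBCError):
    """The pH trajectory or CBC curve does not cover a requested pH range."""

    def __init__(self, message: str, deepest_ph: float | None = None):
        super().__init__(message)
        self.deepest_ph = deepest_ph


class CompositionError(SlurryCBCError):
    """A buffer mixture admits no charge-balance solution in (0, 14)."""


class ProtocolError(SlurryCBCError):
    """A simulated titration cannot reach its target pH."""
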