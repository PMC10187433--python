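"""Exception hierarchy for redoxtf.

All errors derive from :class:`RedoxTFError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline stages (bad parameters, malformed
inputs, unreachable calibration targets, impossible render geometry,
degenerate series, and groups too small to summarize).
"""


class RedoxTFError(Exception):
    """Base class for all redoxtf errors."""


class ParameterError(RedoxTFError, ValueError):
    """A model parameter violates its constraints (negative rate, bad thresholds...)."""


class InputError(RedoxTFError, ValueError):
    """An input table, series, or grid violates a precondition."""


class SchemaError(InputError):
    """A CSV header does not match the required schema; names the missing column."""


class CalibrationError(RedoxTFError, RuntimeError):
    """A calibration target cannot be reached within the search bounds."""


class GeometryError(InputError):
    """Requested cell layout does not fit in the field without nucleus overlap."""


class InsufficientDataError(InputError):
    """Too few cells/events to compute the requested summary."""


class DegenerateSeriesError(InputError):
    """A series is constant (zero variance) where variation is required."""


class UndefinedMeasureError(InputError):
    """A ratio measure is undefined (e.g. nuclear and ring intensity both zero)."""
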