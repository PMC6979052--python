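"""Structured exceptions raised across the pipeline."""


class EmPredictError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EmPredictError, ValueError):
    """A value violates a precondition (non-positive concentration,
    negative volume, single-class labels, ...)."""


class TraceInvariantError(EmPredictError, ValueError):
    """A fluorescence trace or its event log violates a structural
    invariant (non-monotone time, KCl before valinomycin, ...)."""


class WindowTooShortError(EmPredictError, ValueError):
    """Not enough samples to extract a plateau around a named event."""


class InsufficientCalibrationError(EmPredictError, ValueError):
    """Fewer than two calibration points are available."""


class DegenerateFitError(EmPredictError, ValueError):
    """The calibration abscissa has zero variance; no line can be fit."""


class FlatCalibrationError(EmPredictError, ValueError):
    """Calibration slope is zero; fluorescence cannot be inverted to mV."""


class InsufficientDataError(EmPredictError, ValueError):
    """A statistical routine received fewer observations than it needs."""


class DataLoadError(EmPredictError, ValueError):
    """A file could not be parsed into a valid domain object."""
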