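"""Exception hierarchy shared across the package."""


class TaaError(Exception):
    """Base class for all package errors."""


class ParameterError(TaaError, ValueError):
    """A caller-supplied parameter is outside its admissible range."""


class DataError(TaaError, ValueError):
    """Input data are malformed (non-finite values, wrong shapes, ...)."""


class DataFormatError(TaaError):
    """A persisted dataset container is missing groups or has wrong dtypes."""


class NumericalError(TaaError):
    """A numerical procedure failed (factorization, non-monotone bracket, ...)."""


class SimulationError(TaaError):
    """The wall simulator failed to converge at one or more nodes."""


class CalibrationError(TaaError):
    """A calibration target is unreachable within the admissible bracket."""


class PipelineError(TaaError):
    """Repeated failures while assembling the synthetic dataset."""


class MetricError(TaaError, ValueError):
    """An evaluation metric is undefined for the given inputs."""
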