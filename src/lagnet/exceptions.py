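"""Exception hierarchy shared across the pipeline stages."""


class LagnetError(Exception):
    """Base class for all package-specific errors."""


class PanelFormatError(LagnetError):
    """A wide-table column header does not follow the ``<variable><sep><year>`` rule."""


class EmptyDataError(LagnetError):
    """No complete rows survived loading."""


class DegenerateIntervalError(LagnetError):
    """Interpolation endpoints share the same year."""


class TemporalOrderError(LagnetError):
    """An edge or design matrix would point backwards (or sideways) in time."""


class SyntheticSpecError(LagnetError):
    """A synthetic-panel specification is internally inconsistent."""


class DegenerateResponseError(LagnetError):
    """A (binarized) response contains a single class, so a logistic fit is undefined."""


class UndefinedCPTError(LagnetError):
    """A parent configuration was never observed and no smoothing was requested."""


class NullEvidenceError(LagnetError):
    """Conditioning on evidence that has probability zero under the network."""


class UnknownFormatError(LagnetError):
    """Unrecognized graph export/import format."""


class PipelineError(LagnetError):
    """A pipeline stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
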