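"""Exception hierarchy for the qcmdslb package."""


class QcmdError(Exception):
    """Base class for all qcmdslb errors."""


class InvalidParameterError(QcmdError, ValueError):
    """A physical or algorithmic parameter is outside its valid range."""


class TraceParseError(QcmdError, ValueError):
    """A trace file does not conform to the CSV dialect."""


class InvalidWindowError(QcmdError, ValueError):
    """A requested time window is outside the trace or overlaps lipid flow."""


class NormalizationStateError(QcmdError, RuntimeError):
    """Attempt to overtone-normalize a trace that is already normalized."""


class OvertoneNotFoundError(QcmdError, KeyError):
    """The requested overtone is not present in the trace."""


class PlateauNotFoundError(QcmdError, RuntimeError):
    """No terminal plateau detected before the end of the trace."""


class ExtrapolationError(QcmdError, RuntimeError):
    """The dissipation/frequency extrapolation is ill-conditioned."""


class InconsistentFeaturesError(QcmdError, ValueError):
    """Extracted features violate their mutual constraints."""


class UnknownSpeciesError(QcmdError, KeyError):
    """A buffer solute has no registered osmotic dissociation count."""


class UnknownPresetError(QcmdError, KeyError):
    """The requested simulation preset name is not defined."""


class AnalysisStageError(QcmdError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
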