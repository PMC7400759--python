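"""Exception hierarchy for the fundus A/V-ratio pipeline."""


class FundusAVRError(Exception):
    """Base class for all pipeline errors."""


class PhantomSpecError(FundusAVRError, ValueError):
    """A phantom or cohort specification violates an invariant; the message names the field."""


class VideoReadError(FundusAVRError, IOError):
    """A video container or frame directory could not be read."""


class NoUsableFramesError(FundusAVRError):
    """No frame survived screening / registration; nothing to measure."""


class DiscNotFoundError(FundusAVRError):
    """No compact bright region above the contrast floor inside the field of view."""


class RegistrationError(FundusAVRError):
    """Pose estimation similarity fell below the acceptance floor."""


class SeedOffVesselError(FundusAVRError):
    """No dark ridge within the search radius of the supplied vessel seed."""


class MeasurementRejectedError(FundusAVRError):
    """Too few valid diameter points along the vessel; carries per-reason counts."""

    def __init__(self, message: str, rejection_counts: dict | None = None):
        super().__init__(message)
        self.rejection_counts = dict(rejection_counts or {})


class SchemaError(FundusAVRError, ValueError):
    """An observation table violates the expected schema; the message names the column/row."""


class ConvergenceError(FundusAVRError):
    """A mixed-effects fit did not converge or was singular; no estimates are reported."""
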