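"""Exception hierarchy for fenestration planning."""


class FenPlanError(Exception):
    """Base class for all fenplan errors."""


class DescriptorError(FenPlanError):
    """A graft-template descriptor is missing required keys."""


class ValidationError(FenPlanError):
    """Inputs are structurally present but physically inconsistent."""


class InputError(FenPlanError):
    """An anatomy input (labelmap, ostia table, config) is unusable."""


class ParameterError(FenPlanError):
    """A numeric parameter is out of its admissible range."""


class OutOfCoverageError(FenPlanError):
    """An ostium projects outside the graft's axial coverage.

    Carries the vessel label so operating-room reports can name the
    offending target vessel.
    """

    def __init__(self, vessel: str, message: str | None = None):
        self.vessel = vessel
        super().__init__(message or f"vessel {vessel!r} lies outside graft coverage")


class NoValidFitError(FenPlanError):
    """The rigid alignment search found no strut-free configuration.

    The caller is expected to fall back to the relaxed (per-vessel
    posterior shift) search.
    """


class MeshError(FenPlanError):
    """The graft surface mesh violates a manifoldness/topology requirement."""
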