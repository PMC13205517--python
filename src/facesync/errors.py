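"""Exception hierarchy for the facesync toolbox."""


class FaceSyncError(Exception):
    """Base class for all facesync errors."""


class ConfigurationError(FaceSyncError):
    """A required column or setting is missing or inconsistent."""


class InputError(FaceSyncError):
    """Input data is absent or unusable (e.g. empty folder)."""


class ContractError(FaceSyncError):
    """An operation was called on data violating its preconditions."""


class AlignmentError(FaceSyncError):
    """Recordings cannot be aligned (e.g. empty temporal overlap)."""


class ScalingError(FaceSyncError):
    """Pixel-to-centimetre scaling is degenerate (bad inter-ocular distance)."""


class SurrogateError(FaceSyncError):
    """Series too short to admit a legal circular-shuffle offset."""


class ChannelNameError(FaceSyncError):
    """Requested channel does not exist; message lists available channels."""


class NumericIntegrityError(FaceSyncError):
    """An internal numerical guarantee was violated beyond tolerance."""
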