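"""Exception hierarchy for ceusflow."""


class CeusflowError(Exception):
    """Base class for all ceusflow errors."""


class InvalidConfigError(CeusflowError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class FormatError(CeusflowError, ValueError):
    """A cine container or sidecar file is malformed or incomplete."""


class GeometryError(CeusflowError, ValueError):
    """An ROI specification is empty or falls outside the image grid."""


class FlashDetectionError(CeusflowError, RuntimeError):
    """No destruction (flash) window could be located in a clip.

    Raised when no frame shows the intensity drop expected after a
    microbubble destruction pulse; callers should then supply the flash
    end index explicitly in the clip metadata.
    """


class InputError(CeusflowError, ValueError):
    """A statistical or fitting routine received unusable input."""


class ExcludedFitError(CeusflowError, ValueError):
    """Perfusion parameters were requested from an excluded (unreliable) fit."""
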