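"""Exception hierarchy for the autolia pipeline."""


class AutoLIAError(Exception):
    """Base class for all autolia errors."""


class InvalidInputError(AutoLIAError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSpecError(AutoLIAError, ValueError):
    """A synthetic scene specification is geometrically impossible."""


class NoPlantError(AutoLIAError):
    """No detection reached the confidence threshold; the frame is skipped."""


class EmptyDepthError(AutoLIAError):
    """A disparity/depth map contains no valid pixel."""


class KeypointDepthError(AutoLIAError):
    """A leaf's vein lies entirely over invalid depth; the leaf is skipped."""
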