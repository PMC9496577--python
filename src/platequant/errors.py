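"""Exception hierarchy.

Every module raises a subclass of :class:`PlatequantError` so the CLI can
report module-qualified failures with a nonzero exit status.
"""


class PlatequantError(Exception):
    """Base class for all platequant errors."""


class SceneError(PlatequantError):
    """Invalid synthetic scene specification or rendering failure."""


class FiducialError(PlatequantError):
    """Fiducial detection or registration failure."""


class CalibrationError(PlatequantError):
    """Flat-field construction or application failure."""


class SegmentationError(PlatequantError):
    """Well segmentation / intensity readout failure."""


class FitError(PlatequantError):
    """Standard-curve fitting failure."""
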