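"""Typed exceptions shared across the toolkit.

Every stage of the contact-detection pipeline raises a distinct error type so
that the orchestrating state machine (``contactflow.run_process``) can halt
with a machine-readable status instead of a bare traceback.
"""


class PatchContactError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PatchContactError, ValueError):
    """A scene/trace/config specification violates its invariants."""


class FocusNotFoundError(PatchContactError):
    """The motion-based focus sweep ended without a clarity step."""


class TipNotFoundError(PatchContactError):
    """No scanning line in the ROI crossed the darkness threshold."""


class NeuronNotFoundError(PatchContactError):
    """No fused 3D bounding box survived the grouping strategies."""


class StreamAlignmentError(PatchContactError):
    """Image frames and resistance samples are too far apart in time."""


class FormatError(PatchContactError, ValueError):
    """An on-disk artifact (stack, trace, box list) is malformed."""
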