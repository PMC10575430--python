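"""Grayscale frames and z-stacks with physical focal positions.

A *frame* is a 2D uint8 array (rows x cols). A :class:`ZStack` bundles an
ordered sequence of frames with the focal-plane height (in micrometres) each
frame was acquired at; every downstream stage (motion focusing, neuron
fusion, contact detection) consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

Frame = np.ndarray  # 2D uint8 grayscale image


@dataclass
class ZStack:
    """Ordered set of grayscale frames with strictly increasing z (um)."""

    frames: np.ndarray  # (n, rows, cols) uint8
    z_um: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("stack frames must be a (n, rows, cols) array")
        if len(self.z_um) != len(self.frames):
            raise FormatError(
                f"{len(self.frames)} frames but {len(self.z_um)} z positions"
            )
        if len(self.z_um) == 0:
            raise FormatError("empty stack")
        if np.any(np.diff(self.z_um) <= 0):
            raise FormatError("z positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return zip(self.z_um, self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TimedFrame:
    """A frame stamped with acquisition time, for the contact stream."""

    time_s: float
    image: Frame
    meta: dict = field(default_factory=dict)
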