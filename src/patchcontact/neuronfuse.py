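"""Fusion of per-plane neuron detections into 3D bounding boxes.

Neurons are detected plane by plane in a z-stack (1 um steps over ~50 um).
Per-plane boxes belonging to one neuron are accumulated by three rules:

1. consecutive member planes may not be further than ``max_gap`` (2 um)
   apart in depth — a larger gap means two different neurons stacked at
   the same location;
2. the accumulated group must span more than ``min_thickness`` (3 um,
   i.e. more than 3 sequential planes at a 1 um step) — thinner groups are
   impurities that merely resemble neurons;
3. boxes overlap by at least ``overlap_min`` (60%, intersection over
   union) to count as the same neuron.

Surviving groups become a :class:`Box3D` whose xy extent is the union of
its members and whose optimal focus height is the middle of its depth
interval — the plane where the cross-section is maximal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError

__all__ = ["Box2D", "Box3D", "overlap_fraction", "fuse_boxes", "optimal_focus"]


@dataclass(frozen=True)
class Box2D:
    """Half-open axis-aligned detection box in one focal plane."""

    x0: float
    y0: float
    x1: float
    y1: float
    z: float  # um
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise InvalidSpecError(f"box must have positive area: {self}")
        if not np.isfinite(self.z):
            raise InvalidSpecError("box z must be finite")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class Box3D:
    """Fused volumetric neuron box with its depth interval."""

    x0: float
    y0: float
    x1: float
    y1: float
    z_min: float
    z_max: float
    member_count: int
    optimal_z: float


def overlap_fraction(a: Box2D, b: Box2D, mode: str = "iou") -> float:
    """Overlap between two boxes: intersection over union by default, or
    intersection over the smaller area with ``mode='iomin'``."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    if mode == "iou":
        denom = a.area + b.area - inter
    elif mode == "iomin":
        denom = min(a.area, b.area)
    else:
        raise InvalidSpecError(f"unknown overlap mode {mode!r}")
    return inter / denom


def _union_extent(boxes: list[Box2D]) -> tuple[float, float, float, float]:
    return (
        min(b.x0 for b in boxes),
        min(b.y0 for b in boxes),
        max(b.x1 for b in boxes),
        max(b.y1 for b in boxes),
    )


def fuse_boxes(
    detections: list[Box2D],
    z_step: float = 1.0,
    overlap_min: float = 0.6,
    max_gap: float = 2.0,
    min_thickness: float = 3.0,
    overlap_mode: str = "iou",
) -> list[Box3D]:
    """Group per-plane detections into 3D neuron boxes.

    Boxes link when they overlap by at least ``overlap_min`` and are within
    ``max_gap`` in depth; linking is transitive (single-link), mirroring
    sequential accumulation plane by plane.  Groups are then split at
    depth gaps of ``max_gap`` or more between consecutive member planes,
    and groups whose thickness (depth span plus one z step) does not
    exceed ``min_thickness`` are discarded as impurities.  The result is
    deterministic and invariant to the order of ``detections``.
    """
    if z_step <= 0:
        raise InvalidSpecError("z_step must be > 0")
    boxes = sorted(detections, key=lambda b: (b.z, b.x0, b.y0, b.x1, b.y1))
    n = len(boxes)
    if n == 0:
        return []

    # single-link grouping via union-find
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(boxes[i].z - boxes[j].z) > max_gap:
                continue
            if overlap_fraction(boxes[i], boxes[j], overlap_mode) >= overlap_min:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[Box2D]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(boxes[i])

    fused: list[Box3D] = []
    for members in groups.values():
        members.sort(key=lambda b: b.z)
        # split where consecutive member planes gap by >= max_gap
        segments: list[list[Box2D]] = [[members[0]]]
        for b in members[1:]:
            if b.z - segments[-1][-1].z >= max_gap and b.z != segments[-1][-1].z:
                segments.append([b])
            else:
                segments[-1].append(b)
        for seg in segments:
            z_vals = sorted({b.z for b in seg})
            z_min, z_max = z_vals[0], z_vals[-1]
            thickness = z_max - z_min + z_step
            if thickness <= min_thickness:
                continue  # too thin: impurity, not a neuron
            x0, y0, x1, y1 = _union_extent(seg)
            fused.append(
                Box3D(
                    x0=x0, y0=y0, x1=x1, y1=y1,
                    z_min=z_min, z_max=z_max,
                    member_count=len(z_vals),
                    optimal_z=(z_min + z_max) / 2.0,
                )
            )
    fused.sort(key=lambda b: (b.z_min, b.x0, b.y0))
    return fused


def optimal_focus(box: Box3D) -> float:
    """Optimal focus height: the middle of the box's depth interval, where
    the neuron's cross-sectional area peaks."""
    return (box.z_min + box.z_max) / 2.0
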