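"""Resistance-constrained contact detection between pipette tip and neuron.

The pipette's bath resistance (measured after it enters the extracellular
solution) is the baseline; membrane contact shows up as a small rise.  The
state machine holds the focal plane at the neuron's maximum-area height,
lowers the pipette, and *arms* the visual defocus check only while the
resistance rise dR sits inside the detection window (default
0.1-0.5 MOhm, the measurement being quantised in 0.1 MOhm steps).  While
armed, the defocus network runs on the ROI around the cell; the first
frame whose defocus degree drops below the focus threshold (default 0.2)
declares contact.  If dR crosses the window ceiling without a trigger the
run ends with ``no_contact_window_exceeded`` — a resistance rise that the
camera cannot confirm as the pipette focusing on the cell plane is, by
itself, no proof of neuron contact.

``run_process`` strings the whole experiment together: pipette
qualification, neuron 3D fusion, motion focusing plus scanline tip
localisation, and the armed descent — emitting a structured stage log.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    FocusNotFoundError,
    InvalidSpecError,
    NeuronNotFoundError,
    PatchContactError,
    StreamAlignmentError,
    TipNotFoundError,
)
from .stacks import TimedFrame, ZStack

__all__ = [
    "ResistanceTrace",
    "ContactEvent",
    "ProcessConfig",
    "qualify_pipette",
    "detect_contact",
    "run_process",
]


@dataclass
class ResistanceTrace:
    """Quantised pipette-resistance samples over time."""

    times: np.ndarray  # (n,) seconds, strictly increasing
    resistance: np.ndarray  # (n,) MOhm on the quantisation grid
    bath_resistance: float | None = None  # baseline; estimated if omitted

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.times.shape != self.resistance.shape or self.times.ndim != 1:
            raise InvalidSpecError("trace times/values must be equal-length 1D")
        if self.times.size == 0:
            raise InvalidSpecError("empty resistance trace")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidSpecError("trace times must be strictly increasing")
        if self.bath_resistance is None:
            # baseline: median of the first 10 samples after solution entry
            head = self.resistance[: min(10, len(self.resistance))]
            self.bath_resistance = float(np.median(head))

    def at(self, t: float) -> tuple[float, float]:
        """(resistance, |dt|) of the sample nearest to time t."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.resistance[i]), float(abs(self.times[i] - t))

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ContactEvent:
    """Outcome of one armed descent."""

    status: str  # contact | no_contact_window_exceeded | aborted
    time_s: float | None = None
    pipette_z_um: float | None = None
    defocus_at_event: float | None = None
    delta_r_mohm: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProcessConfig:
    """Thresholds of the automatic contact process."""

    arm_delta_r: float = 0.1  # MOhm rise that arms the visual check
    max_delta_r: float = 0.5  # MOhm rise that ends the window
    focus_threshold: float = 0.2  # defocus degree declaring contact
    resistance_range_ok: tuple[float, float] = (3.0, 8.0)  # MOhm, pipette QC

    def __post_init__(self) -> None:
        if not 0 < self.arm_delta_r < self.max_delta_r:
            raise InvalidSpecError("need 0 < arm_delta_r < max_delta_r")
        if not 0 < self.focus_threshold <= 1:
            raise InvalidSpecError("focus_threshold must lie in (0, 1]")


def qualify_pipette(trace_head: ResistanceTrace, cfg: ProcessConfig,
                    after_blow: bool = False) -> str:
    """Qualify the pipette from its bath-resistance baseline.

    ``ok`` when the baseline lies inside the accepted range (closed
    interval); otherwise ``blow`` (apply positive pressure to clear a
    blocked tip and re-measure) on the first violation and ``replace`` if
    the pressure pulse did not help.
    """
    lo, hi = cfg.resistance_range_ok
    bath = trace_head.bath_resistance
    if lo <= bath <= hi:
        return "ok"
    return "replace" if after_blow else "blow"


def detect_contact(
    frames: Sequence[TimedFrame],
    trace: ResistanceTrace,
    descent: Sequence[tuple[float, float]],
    model,
    cfg: ProcessConfig,
    cell_center: tuple[int, int],
    predict: Callable | None = None,
) -> ContactEvent:
    """Armed descent: evaluate the defocus network only inside the
    resistance window and declare contact below the focus threshold.

    ``frames`` is the time-stamped image stream (focal plane fixed at the
    neuron's optimal height), ``descent`` the (time_s, z_um) schedule of
    the pipette tip used to report the event height.  The network is never
    evaluated before the rise reaches ``arm_delta_r`` and pauses if the
    rise drops back out of the window.  ``predict`` may override the
    model's inference callable (it receives (model, roi) and must return
    an object with a ``defocus`` attribute).
    """
    from .cunet import crop_roi
    from .cunet import predict_defocus as default_predict

    if len(frames) == 0:
        raise InvalidSpecError("empty frame stream")
    predict = predict or default_predict
    times = np.asarray([f.time_s for f in frames], dtype=float)
    if len(times) > 1:
        frame_dt = float(np.median(np.diff(times)))
    else:
        frame_dt = float(np.median(np.diff(trace.times))) if len(trace) > 1 else 1.0
    d_times = np.asarray([t for t, _ in descent], dtype=float)
    d_z = np.asarray([z for _, z in descent], dtype=float)
    if d_times.size == 0 or np.any(np.diff(d_times) <= 0):
        raise InvalidSpecError("descent schedule must have increasing times")

    bath = trace.bath_resistance
    last = None
    for f in frames:
        r, skew = trace.at(f.time_s)
        if skew > frame_dt + 1e-9:
            raise StreamAlignmentError(
                f"no resistance sample within one frame interval of t={f.time_s}"
            )
        delta_r = r - bath
        z_now = float(np.interp(f.time_s, d_times, d_z))
        last = (f.time_s, z_now, delta_r)
        if delta_r < cfg.arm_delta_r - 1e-9:
            continue  # not armed (or paused below the window)
        if delta_r > cfg.max_delta_r + 1e-9:
            return ContactEvent(
                status="no_contact_window_exceeded",
                time_s=f.time_s, pipette_z_um=z_now, delta_r_mohm=delta_r,
            )
        est = predict(model, crop_roi(f.image, cell_center))
        if est.defocus < cfg.focus_threshold:
            return ContactEvent(
                status="contact", time_s=f.time_s, pipette_z_um=z_now,
                defocus_at_event=est.defocus, delta_r_mohm=delta_r,
            )
    t, z, dr = last
    return ContactEvent(
        status="no_contact_window_exceeded", time_s=t, pipette_z_um=z,
        delta_r_mohm=dr,
    )


# ---------------------------------------------------------------------------
# the end-to-end process
# ---------------------------------------------------------------------------


@dataclass
class ProcessInputs:
    """Everything the four-stage automatic process consumes."""

    trace: ResistanceTrace
    neuron_detections: list  # per-plane Box2D list
    neuron_z_step: float
    pipette_stack: ZStack
    tip_roi: object  # tiplocate.RoiImage
    descent_frames: Sequence[TimedFrame]
    descent: Sequence[tuple[float, float]]
    model: object
    cell_center: tuple[int, int] | None = None  # defaults to fused box centre


def run_process(inputs: ProcessInputs, cfg: ProcessConfig | None = None) -> dict:
    """Run qualification, neuron fusion, pipette positioning and the armed
    descent in order, returning a structured stage log.

    The log is a dict with a ``stages`` list (one entry per attempted
    stage, each with a ``status``) and a final ``status`` that is either
    ``contact`` or the typed failure that halted the run.  Hardware
    motions (stage, manipulator, pump) are outside this package; the
    descent is replayed from the provided schedule.
    """
    from .motionfocus import detect_focus
    from .neuronfuse import fuse_boxes, optimal_focus
    from .tiplocate import locate_tip_scanline

    cfg = cfg or ProcessConfig()
    log: dict = {"stages": [], "status": "running"}

    def stage(name: str, **payload) -> None:
        log["stages"].append({"stage": name, **payload})

    verdict = qualify_pipette(inputs.trace, cfg)
    stage("qualify_pipette", status=verdict,
          bath_resistance_mohm=inputs.trace.bath_resistance)
    if verdict != "ok":
        log["status"] = f"pipette_{verdict}"
        return log

    boxes3d = fuse_boxes(inputs.neuron_detections, z_step=inputs.neuron_z_step)
    if not boxes3d:
        stage("neuron_fusion", status="neuron_not_found")
        log["status"] = "neuron_not_found"
        return log
    target = max(boxes3d, key=lambda b: (b.member_count, (b.x1 - b.x0) * (b.y1 - b.y0)))
    focus_z = optimal_focus(target)
    stage("neuron_fusion", status="ok", n_neurons=len(boxes3d),
          optimal_z_um=focus_z)

    try:
        focus = detect_focus(inputs.pipette_stack)
        tip = locate_tip_scanline(inputs.tip_roi)
    except (FocusNotFoundError, TipNotFoundError) as exc:
        stage("pipette_positioning", status="failed", error=type(exc).__name__)
        log["status"] = "pipette_positioning_failed"
        return log
    stage("pipette_positioning", status="ok", tip_focal_z_um=focus.focal_z_um,
          tip_x_px=tip.x, tip_y_px=tip.y)

    cell_center = inputs.cell_center or (
        int((target.x0 + target.x1) / 2), int((target.y0 + target.y1) / 2)
    )
    try:
        event = detect_contact(
            inputs.descent_frames, inputs.trace, inputs.descent,
            inputs.model, cfg, cell_center,
        )
    except PatchContactError as exc:
        stage("contact_detection", status="failed", error=type(exc).__name__)
        log["status"] = "contact_detection_failed"
        return log
    stage("contact_detection", **event.to_dict())
    log["status"] = event.status
    return log
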