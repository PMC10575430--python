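"""Seeded synthetic microscopy scenes for brain-slice patch-clamp work.

This module renders everything the detection pipeline consumes, together
with exact ground truth, so the whole toolkit can be exercised without a
microscope:

* an oblique micropipette whose sharpness varies along its axis — the tip
  is the lowest point, the taper climbs to the left, and only the axial
  band near the focal plane is rendered sharp;
* ellipsoidal neurons whose cross-section is maximal at mid-depth, plus
  thin impurity blobs that mimic neurons in no more than 3 planes;
* training ROIs for the defocus network, defocus normalised so that
  10 um maps to 1.0;
* pipette-resistance traces quantised to 0.1 MOhm that rise in proportion
  to the descent past the contact height and then plateau or keep rising.

Depth appearance model
----------------------
Two qualitative observations from the bench drive the renderer.  During the
focusing sweep the pipette is invisible while the focal plane is below the
tip and pops into view, sharp at the tip, the moment the plane reaches it;
during the descent toward a cell the tip is visible but increasingly
blurred with its distance from the focal plane.  Both regimes come from one
parametrisation: a pipette axis point at height ``z_p`` seen with the focal
plane at ``focal_z`` has offset ``d = focal_z - z_p`` and is drawn with
Gaussian blur ``sigma = blur_per_um * |d|``, its contrast fading linearly
to zero over ``vis_range_um`` for ``d >= 0`` (plane above the point) and
over ``vis_range_above_um`` for ``d < 0`` (plane below the point).  The
default ``vis_range_above_um = 0`` hides the pipette completely until the
plane reaches the tip, which is the focusing-sweep phenomenology; contact
scenes use a positive value so the approaching tip is visible with blur
growing with its defocus distance.  ``blur_per_um = 0`` switches the depth
model off entirely (the analytic blur-free limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidSpecError
from .stacks import Frame, ZStack

__all__ = [
    "SceneSpec",
    "NeuronSpec",
    "TraceSpec",
    "render_pipette_frame",
    "focus_scene",
    "render_focus_stack",
    "render_neuron_stack",
    "make_cunet_dataset",
    "simulate_resistance_trace",
    "pipette_mask",
    "detect_neurons_oracle",
    "make_tip_rois",
    "contact_scene",
    "descent_schedule",
    "make_contact_sequence",
    "make_process_inputs",
    "render_descent_frames",
    "BRIGHTNESS_GAINS",
]

#: Illumination sweep used for robustness checks: four brightness levels.
BRIGHTNESS_GAINS = (0.6, 0.8, 1.0, 1.2)


@dataclass(frozen=True)
class SceneSpec:
    """Imaging geometry and appearance of one synthetic pipette scene.

    The pipette axis runs horizontally in the image, tube to the left and
    tip at ``pipette_tip_xy`` (sub-pixel float coordinates, x rightward and
    y downward).  ``pipette_angle`` tilts the axis in depth: a column
    ``dx`` pixels left of the tip sits ``dx * pixel_size * tan(angle)``
    micrometres above ``pipette_tip_z``.
    """

    image_size: tuple[int, int] = (320, 320)  # (rows, cols) px
    pixel_size: float = 0.2  # um / px
    pipette_tip_xy: tuple[float, float] = (240.0, 160.0)  # (x, y) px
    pipette_tip_z: float = 0.0  # um
    pipette_angle: float = 25.0  # degrees from horizontal
    tube_intensity: float = 90.0  # gray level of the taper walls
    background_level: float = 180.0  # mean background gray
    brightness_gain: float = 1.0
    blur_per_um: float = 1.2  # Gaussian sigma growth, px per um of defocus
    noise_sd: float = 3.0  # additive Gaussian noise, gray levels
    seed: int = 0
    # -- appearance free parameters (the geometry is not quantified in the
    #    literature; defaults are chosen once to match the qualitative
    #    description: dark converging walls, brighter lumen, very dark tip
    #    bands producing a single grayscale valley at the tip column) --
    vis_range_um: float = 15.0
    vis_range_above_um: float = 0.0
    wall_px: float = 3.0  # wall thickness
    lumen_half_px: float = 2.0  # half-gap between the walls at the tip
    taper_rate: float = 0.08  # half-gap growth per px leftward
    tip_len_px: float = 6.0  # length of the extra-dark tip region
    tip_depth: float = 135.0  # darkness of the tip core below background
    tip_grad: float = 18.0  # tip darkness falloff per row off-axis

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if rows < 32 or cols < 32:
            raise InvalidSpecError(f"degenerate image size {self.image_size}")
        x, y = self.pipette_tip_xy
        if not (0 <= x < cols and 0 <= y < rows):
            raise InvalidSpecError("pipette tip outside image bounds")
        if self.brightness_gain <= 0:
            raise InvalidSpecError("brightness_gain must be > 0")
        if self.blur_per_um < 0:
            raise InvalidSpecError("blur_per_um must be >= 0")
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel_size must be > 0")


@dataclass(frozen=True)
class NeuronSpec:
    """An ellipsoidal neuron (or a thin impurity blob) in the slice.

    ``semi_axes`` are (a, b, c) in micrometres; a and b span the image
    plane, c the depth axis, so the rendered cross-section is largest at
    ``center_z`` and vanishes for ``|z - center_z| >= c``.
    """

    center_xy: tuple[float, float]  # (x, y) px
    center_z: float  # um
    semi_axes: tuple[float, float, float]  # (a, b, c) um
    intensity_contrast: float = 45.0  # gray delta below background
    is_impurity: bool = False

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise InvalidSpecError("neuron semi-axes must be positive")

    def plane_radii_px(self, z_um: float, pixel_size: float) -> tuple[float, float]:
        """In-plane semi-axes (px) of the cross-section at depth z, (0, 0)
        when the plane falls outside the ellipsoid."""
        a, b, c = self.semi_axes
        dz = (z_um - self.center_z) / c
        if abs(dz) >= 1.0:
            return 0.0, 0.0
        scale = math.sqrt(1.0 - dz * dz)
        return a * scale / pixel_size, b * scale / pixel_size


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a simulated pipette-resistance trace."""

    bath_resistance: float = 5.0  # MOhm after entering the bath solution
    rise_per_um: float = 0.2  # MOhm per um of descent past contact
    regime: str = "plateau"  # or "continue_rising"
    quantization: float = 0.1  # MOhm measurement grid
    contact_z: float = 0.0  # um, tip height at first membrane contact
    plateau_delta_r: float = 0.3  # MOhm cap in the plateau regime
    noise_sd: float = 0.0  # MOhm pre-quantisation jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bath_resistance < 0:
            raise InvalidSpecError("bath resistance must be non-negative")
        if self.quantization <= 0:
            raise InvalidSpecError("quantization must be > 0")
        if self.regime not in ("plateau", "continue_rising"):
            raise InvalidSpecError(f"unknown regime {self.regime!r}")
        if not 0 < self.plateau_delta_r < 0.5:
            raise InvalidSpecError("plateau rise must lie in (0, 0.5) MOhm")


# ---------------------------------------------------------------------------
# pipette rendering
# ---------------------------------------------------------------------------


def _axis_z_um(spec: SceneSpec, x_px: np.ndarray) -> np.ndarray:
    """Height (um) of the pipette axis at column x; the taper climbs
    leftward from the tip at the mounting angle."""
    tip_x = spec.pipette_tip_xy[0]
    slope = math.tan(math.radians(spec.pipette_angle)) * spec.pixel_size
    return spec.pipette_tip_z + np.maximum(0.0, tip_x - x_px) * slope


def _sharp_pipette_delta(spec: SceneSpec) -> np.ndarray:
    """Signed gray-level delta of the in-focus pipette against background.

    Two dark converging walls flank a dimmer lumen; over the last
    ``tip_len_px`` columns an extra-dark core ramps in, graded away from
    the axis so the tip column has a single grayscale valley flanked by
    two sub-background wall bands.
    """
    rows, cols = spec.image_size
    tip_x, tip_y = spec.pipette_tip_xy
    x = np.arange(cols, dtype=np.float64)
    y = np.arange(rows, dtype=np.float64)[:, None]

    # sub-pixel fade of all structure right of the tip
    end_fade = np.clip(tip_x - x + 1.0, 0.0, 1.0)[None, :]
    half_gap = spec.lumen_half_px + np.maximum(0.0, tip_x - x) * spec.taper_rate
    half_gap = half_gap[None, :]
    ady = np.abs(y - tip_y)

    lumen_cov = np.clip(half_gap - ady + 0.5, 0.0, 1.0)
    wall_cov = np.clip(ady - half_gap + 0.5, 0.0, 1.0) * np.clip(
        half_gap + spec.wall_px - ady + 0.5, 0.0, 1.0
    )
    lumen_mag = lumen_cov * 40.0
    wall_mag = wall_cov * (spec.background_level - spec.tube_intensity)

    tip_ramp = np.clip((x - (tip_x - spec.tip_len_px)) / spec.tip_len_px, 0.0, 1.0)
    core_mag = tip_ramp[None, :] * np.clip(spec.tip_depth - spec.tip_grad * ady, 0.0, None)

    mag = np.maximum(np.maximum(lumen_mag, wall_mag), core_mag)
    return -mag * end_fade


def _visibility(spec: SceneSpec, offset_um: np.ndarray) -> np.ndarray:
    """Contrast attenuation as a function of focal offset (focal - point)."""
    vis = np.zeros_like(offset_um)
    below = offset_um >= 0
    if spec.vis_range_um > 0:
        vis[below] = np.clip(1.0 - offset_um[below] / spec.vis_range_um, 0.0, 1.0)
    if spec.vis_range_above_um > 0:
        vis[~below] = np.clip(
            1.0 + offset_um[~below] / spec.vis_range_above_um, 0.0, 1.0
        )
    return vis


def _frame_rng(spec: SceneSpec, focal_z: float) -> np.random.Generator:
    # stable per (scene seed, focal plane) noise key
    zkey = int(round(float(focal_z) * 1000.0)) + (1 << 40)
    return np.random.default_rng(np.random.SeedSequence((int(spec.seed), zkey)))


def _finalize(spec: SceneSpec, clean: np.ndarray, focal_z: float) -> Frame:
    img = clean * spec.brightness_gain
    if spec.noise_sd > 0:
        img = img + _frame_rng(spec, focal_z).normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_pipette_frame(spec: SceneSpec, focal_z: float) -> Frame:
    """Render one frame of the tilted pipette seen at focal plane ``focal_z``.

    Each axial segment is blurred with sigma proportional to its distance
    from the focal plane and faded by the depth-visibility profile; the
    region right of the tip is pure background.  Identical spec and
    ``focal_z`` reproduce the frame bit for bit.
    """
    if not np.isfinite(focal_z):
        raise InvalidSpecError("focal_z must be finite")
    rows, cols = spec.image_size
    base = np.full((rows, cols), float(spec.background_level))
    delta = _sharp_pipette_delta(spec)

    if spec.blur_per_um == 0:
        # blur-free limit: the depth model is off, frames do not depend on z
        return _finalize(spec, base + delta, focal_z)

    x = np.arange(cols, dtype=np.float64)
    offset = focal_z - _axis_z_um(spec, x)  # per-column focal offset
    vis = _visibility(spec, offset)
    sigma = spec.blur_per_um * np.abs(offset)

    out = np.zeros_like(delta)
    active = np.nonzero(vis > 1e-3)[0]
    if active.size:
        faded = delta * vis[None, :]
        # bin columns by ~1 um of offset so each bin gets one blur sigma
        bin_ids = np.floor(offset[active]).astype(int)
        for b in np.unique(bin_ids):
            cols_b = active[bin_ids == b]
            c0, c1 = cols_b.min(), cols_b.max() + 1
            sig = float(np.mean(sigma[cols_b]))
            margin = int(math.ceil(3.0 * sig)) + 1
            lo, hi = max(0, c0 - margin), min(cols, c1 + margin)
            piece = np.zeros((rows, hi - lo))
            piece[:, c0 - lo : c1 - lo] = faded[:, c0:c1]
            if sig > 1e-3:
                piece = gaussian_filter(piece, sig, truncate=3.0)
            out[:, lo:hi] += piece
    return _finalize(spec, base + out, focal_z)


def pipette_mask(spec: SceneSpec, threshold: float = 10.0) -> np.ndarray:
    """Ground-truth binary support of the in-focus pipette (bool image)."""
    return -_sharp_pipette_delta(spec) > threshold


def focus_scene(seed: int = 0, brightness_gain: float = 1.0) -> SceneSpec:
    """A randomised focusing-stage scene: tip position, tip depth and
    illumination jittered per seed, pipette hidden below the focal plane."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    rows, cols = SceneSpec().image_size
    return SceneSpec(
        pipette_tip_xy=(
            float(rng.uniform(0.6, 0.82) * cols),
            float(rng.uniform(0.38, 0.62) * rows),
        ),
        pipette_tip_z=float(rng.uniform(-1.5, 1.5)),
        background_level=float(rng.uniform(172, 188)),
        brightness_gain=brightness_gain,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def render_focus_stack(
    spec: SceneSpec, z_range: tuple[float, float], z_step: float
) -> ZStack:
    """Sweep the focal plane from ``z_range[0]`` to ``z_range[1]`` (um).

    Emulates raising the objective during the focusing stage; frames are
    ordered by strictly increasing focal z.
    """
    z0, z1 = z_range
    if z_step <= 0:
        raise InvalidSpecError("z_step must be > 0")
    if z1 < z0:
        raise InvalidSpecError("z_range must be ordered (low, high)")
    z_list = np.arange(z0, z1 + 0.5 * z_step, z_step)
    if len(z_list) == 0:
        raise InvalidSpecError("empty z range")
    frames = np.stack([render_pipette_frame(spec, z) for z in z_list])
    return ZStack(frames=frames, z_um=z_list)


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------


def _neuron_delta(
    specs: list[NeuronSpec], scene: SceneSpec, z_um: float
) -> np.ndarray:
    rows, cols = scene.image_size
    delta = np.zeros((rows, cols))
    x = np.arange(cols, dtype=np.float64)[None, :]
    y = np.arange(rows, dtype=np.float64)[:, None]
    for n in specs:
        ra, rb = n.plane_radii_px(z_um, scene.pixel_size)
        if min(ra, rb) < 0.5:
            continue
        cx, cy = n.center_xy
        ell = np.sqrt(((x - cx) / ra) ** 2 + ((y - cy) / rb) ** 2)
        cov = np.clip((1.0 - ell) * min(ra, rb) + 0.5, 0.0, 1.0)  # ~soft edge
        delta = np.minimum(delta, -cov * n.intensity_contrast)
    return delta


def render_neuron_stack(
    specs: list[NeuronSpec], scene: SceneSpec, z_list: list[float] | np.ndarray
) -> ZStack:
    """Render the brain-slice z-stack of neurons (no pipette).

    Each neuron appears only in planes inside its depth extent, with
    cross-sectional area maximal at its ``center_z``; thin impurity blobs
    (depth semi-axis <= 1.5 um on a 1 um grid) appear in at most 3
    consecutive planes so that thickness-based fusion rejects them.
    """
    z_arr = np.asarray(list(z_list), dtype=float)
    if z_arr.size == 0:
        raise InvalidSpecError("z_list must be nonempty")
    rows, cols = scene.image_size
    frames = []
    for z in z_arr:
        clean = np.full((rows, cols), float(scene.background_level))
        clean = clean + gaussian_filter(_neuron_delta(specs, scene, z), 0.8)
        frames.append(_finalize(scene, clean, z))
    return ZStack(frames=np.stack(frames), z_um=z_arr)


def detect_neurons_oracle(
    specs: list[NeuronSpec],
    scene: SceneSpec,
    z_list: list[float] | np.ndarray,
    jitter_sd: float = 1.0,
    min_radius_px: float = 1.5,
    seed: int = 0,
):
    """Stand-in for the trained per-plane neuron detector.

    Emits one axis-aligned bounding box per neuron per plane where its
    cross-section exists, jittered with Gaussian pixel noise to mimic
    detector regression error.  Impurity blobs are detected like neurons —
    telling them apart is the fusion stage's job.  Returns a list of
    ``neuronfuse.Box2D``.
    """
    from .neuronfuse import Box2D

    rng = np.random.default_rng(seed)
    boxes = []
    for z in np.asarray(list(z_list), dtype=float):
        for n in specs:
            ra, rb = n.plane_radii_px(z, scene.pixel_size)
            if min(ra, rb) < min_radius_px:
                continue
            cx, cy = n.center_xy
            j = rng.normal(0.0, jitter_sd, 4)
            x0, x1 = cx - ra + j[0], cx + ra + j[1]
            y0, y1 = cy - rb + j[2], cy + rb + j[3]
            if x1 - x0 < 1 or y1 - y0 < 1:
                continue
            boxes.append(
                Box2D(
                    x0=float(x0), y0=float(y0), x1=float(x1), y1=float(y1),
                    z=float(z), score=float(np.clip(rng.normal(0.9, 0.05), 0, 1)),
                )
            )
    return boxes


# ---------------------------------------------------------------------------
# tip-localisation ROIs
# ---------------------------------------------------------------------------


def make_tip_rois(
    n: int,
    base_spec: SceneSpec | None = None,
    seed: int = 0,
    box_jitter_sd: float = 2.0,
    left_extent: float = 50.0,
    right_margin: float = 16.0,
    half_height: float = 18.0,
):
    """Seeded ROIs around randomly placed pipette tips, with ground truth.

    Each sample mimics the output of the tip object detector: a bounding
    box extending leftward over the taper (the visible structure) with a
    background margin right of the tip, jittered by detector noise.
    Returns a list of dicts with keys ``roi`` (:class:`tiplocate.RoiImage`),
    ``tip_xy`` (true sub-pixel frame coordinates), ``box``
    (:class:`neuronfuse.Box2D` in frame coordinates) and ``pixel_size``.
    """
    from .neuronfuse import Box2D
    from .tiplocate import RoiImage

    base = base_spec or SceneSpec()
    rows, cols = base.image_size
    out = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        tip = (
            float(rng.uniform(0.55 * cols, 0.85 * cols)),
            float(rng.uniform(0.35 * rows, 0.65 * rows)),
        )
        spec = replace(
            base,
            pipette_tip_xy=tip,
            seed=int(rng.integers(0, 2**31 - 1)),
            background_level=float(rng.uniform(170, 190)),
            # the ROI is grabbed once the tip is focused: the taper climbs
            # away from the plane but stays visible, increasingly blurred
            vis_range_above_um=max(base.vis_range_above_um, 18.0),
        )
        frame = render_pipette_frame(spec, spec.pipette_tip_z)
        j = rng.normal(0.0, box_jitter_sd, 4)
        x0 = int(round(tip[0] - left_extent + j[0]))
        x1 = int(round(tip[0] + right_margin + j[1]))
        y0 = int(round(tip[1] - half_height + j[2]))
        y1 = int(round(tip[1] + half_height + j[3]))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(cols, x1), min(rows, y1)
        roi = RoiImage(image=frame[y0:y1, x0:x1].copy(), origin_in_frame=(x0, y0))
        out.append(
            {
                "roi": roi,
                "tip_xy": tip,
                "box": Box2D(x0=x0, y0=y0, x1=x1, y1=y1, z=spec.pipette_tip_z),
                "pixel_size": spec.pixel_size,
            }
        )
    return out


# ---------------------------------------------------------------------------
# defocus-network dataset
# ---------------------------------------------------------------------------

#: Scene defaults for contact/defocus work: the pipette stays visible on
#: the approach side of the focal plane, so its blur encodes its distance.
_CONTACT_OVERRIDES = dict(
    image_size=(320, 480),
    vis_range_above_um=18.0,
    vis_range_um=18.0,
)


def contact_scene(seed: int = 0, **overrides) -> tuple[SceneSpec, tuple[int, int]]:
    """A scene for the descent/contact stage: returns (spec, cell_center).

    The cell sits under the pipette tip; the focal plane is held at the
    cell's maximum-area height during the whole descent.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    params = dict(_CONTACT_OVERRIDES)
    params.update(overrides)
    rows, cols = params.get("image_size", (320, 480))
    tip = (
        float(rng.uniform(0.58 * cols, 0.68 * cols)),
        float(rng.uniform(0.42 * rows, 0.58 * rows)),
    )
    spec = SceneSpec(
        pipette_tip_xy=tip,
        seed=int(rng.integers(0, 2**31 - 1)),
        background_level=float(rng.uniform(172, 188)),
        **params,
    )
    cell_center = (int(round(tip[0] - rng.uniform(-6, 6))),
                   int(round(tip[1] + rng.uniform(-6, 6))))
    return spec, cell_center


def make_cunet_dataset(
    scene: SceneSpec,
    n_cells: int,
    defocus_levels: list[float] | np.ndarray,
    seed: int = 0,
):
    """Training samples for the defocus network.

    For each of ``n_cells`` synthetic cells the pipette is rendered at every
    requested defocus distance (um, within [0, 10]) on the approach side of
    the focal plane, cropped around the cell per the 384x256 rule and
    resized to the network input size.  Returns a list of
    ``(roi_image, mask, normalized_defocus)`` tuples where the mask is the
    exact in-focus pipette support used in rendering and the label is
    ``defocus_um / 10``.
    """
    from .cunet import crop_roi, resize_mask_roi

    levels = np.asarray(list(defocus_levels), dtype=float)
    if levels.size and (levels.min() < 0 or levels.max() > 10):
        raise InvalidSpecError("defocus levels must lie in [0, 10] um")
    rows, cols = scene.image_size
    samples = []
    for i in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        tip = (
            float(rng.uniform(0.55 * cols, 0.72 * cols)),
            float(rng.uniform(0.35 * rows, 0.65 * rows)),
        )
        spec = replace(
            scene,
            pipette_tip_xy=tip,
            seed=int(rng.integers(0, 2**31 - 1)),
            background_level=float(rng.uniform(172, 188)),
            vis_range_above_um=max(scene.vis_range_above_um, 12.0),
        )
        cell_center = (
            int(round(tip[0] + rng.uniform(-6, 6))),
            int(round(tip[1] + rng.uniform(-6, 6))),
        )
        truth = pipette_mask(spec)
        mask = resize_mask_roi(truth, cell_center)
        for d in levels:
            # the tip approaches from above: focal plane sits d um below it
            frame = render_pipette_frame(spec, spec.pipette_tip_z - d)
            roi = crop_roi(frame, cell_center)
            samples.append((roi.image, mask, float(d) / 10.0))
    return samples


# ---------------------------------------------------------------------------
# descent + resistance
# ---------------------------------------------------------------------------


def simulate_resistance_trace(
    tspec: TraceSpec, descent: list[tuple[float, float]]
):
    """Pipette resistance along a descent schedule ``[(time_s, z_um), ...]``.

    Constant at the bath value while the tip is above ``contact_z``; past
    contact the resistance rises in proportion to the penetration depth and
    then, depending on the regime, keeps rising or plateaus.  All emitted
    values sit on the quantisation grid.
    """
    from .contactflow import ResistanceTrace

    descent = list(descent)
    times = np.asarray([t for t, _ in descent], dtype=float)
    zs = np.asarray([z for _, z in descent], dtype=float)
    if times.size == 0:
        raise InvalidSpecError("empty descent schedule")
    if np.any(np.diff(times) <= 0):
        raise InvalidSpecError("descent times must be strictly increasing")
    depth = np.maximum(0.0, tspec.contact_z - zs)
    rise = tspec.rise_per_um * depth
    if tspec.regime == "plateau":
        rise = np.minimum(rise, tspec.plateau_delta_r)
    r = tspec.bath_resistance + rise
    if tspec.noise_sd > 0:
        rng = np.random.default_rng(tspec.seed)
        r = r + rng.normal(0.0, tspec.noise_sd, r.shape)
    q = tspec.quantization
    r = np.round(r / q) * q
    return ResistanceTrace(
        times=times, resistance=np.maximum(r, 0.0),
        bath_resistance=float(np.round(tspec.bath_resistance / q) * q),
    )


def descent_schedule(
    z_start: float, z_end: float, um_per_s: float = 1.0,
    dt_s: float = 0.5, t0: float = 1.0,
) -> list[tuple[float, float]]:
    """Constant-speed descent sampled once per frame: [(time_s, z_um), ...]."""
    if um_per_s <= 0 or dt_s <= 0 or z_end >= z_start:
        raise InvalidSpecError("descent must move downward at positive speed")
    n = int(math.floor((z_start - z_end) / (um_per_s * dt_s))) + 1
    times = t0 + np.arange(n) * dt_s
    zs = z_start - np.arange(n) * um_per_s * dt_s
    return list(zip(times.tolist(), zs.tolist()))


def make_contact_sequence(seed: int = 0, render: bool = True) -> dict:
    """One full synthetic descent: frames, resistance trace and truth.

    The focal plane is held at z = 0 (the neuron's maximum-area height);
    the tip starts 10 um above it and descends at 1 um/s, touching the
    membrane at ``contact_z`` (jittered around the focal plane).  The
    post-contact regime is sampled 62.5% plateau / 37.5% continue-rising,
    the split reported for real cells.  Returns a dict with keys
    ``spec, cell_center, descent, frames, trace, contact_z, focal_z``.
    """
    from .contactflow import ResistanceTrace

    spec, cell_center = contact_scene(seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 555)))
    focal_z = 0.0
    contact_z = float(np.clip(rng.normal(0.0, 0.3), -0.8, 0.8))
    descent = descent_schedule(10.0, -3.0, um_per_s=1.0, dt_s=0.5, t0=1.0)
    tspec = TraceSpec(
        bath_resistance=round(float(rng.uniform(4.0, 7.0)), 1),
        rise_per_um=float(rng.uniform(0.15, 0.3)),
        regime="plateau" if rng.random() < 0.625 else "continue_rising",
        contact_z=contact_z,
        plateau_delta_r=float(rng.uniform(0.2, 0.45)),
        seed=seed,
    )
    core = simulate_resistance_trace(tspec, descent)
    head_t = np.arange(10) * 0.05  # baseline after entering the bath
    times = np.concatenate([head_t, core.times])
    values = np.concatenate([np.full(10, core.bath_resistance), core.resistance])
    trace = ResistanceTrace(times=times, resistance=values)
    frames = render_descent_frames(spec, focal_z, descent) if render else None
    return {
        "spec": spec, "cell_center": cell_center, "descent": descent,
        "frames": frames, "trace": trace, "trace_spec": tspec,
        "contact_z": contact_z, "focal_z": focal_z,
    }


def make_process_inputs(seed: int, model) -> tuple:
    """Assemble every artifact the four-stage automatic process needs,
    plus its ground truth: returns (ProcessInputs, truth dict)."""
    from .contactflow import ProcessInputs

    seq = make_contact_sequence(seed)
    # neuron stack detections on a 50-plane, 1 um grid; one target neuron
    # under the pipette plus a thin impurity elsewhere
    rng = np.random.default_rng(np.random.SeedSequence((seed, 321)))
    scene = seq["spec"]
    z_list = np.arange(1.0, 51.0)
    center_z = float(rng.uniform(20.0, 30.0))
    neurons = [
        NeuronSpec(center_xy=seq["cell_center"], center_z=center_z,
                   semi_axes=(4.0, 3.5, 4.0)),
        NeuronSpec(center_xy=(60.0, 60.0), center_z=center_z + 5.0,
                   semi_axes=(3.0, 3.0, 1.4), is_impurity=True),
    ]
    detections = detect_neurons_oracle(neurons, scene, z_list, seed=seed)
    pip_spec = SceneSpec(seed=seed)
    stack = render_focus_stack(pip_spec, (-25.0, 25.0), 1.0)
    roi_sample = make_tip_rois(1, seed=seed)[0]
    inputs = ProcessInputs(
        trace=seq["trace"],
        neuron_detections=detections,
        neuron_z_step=1.0,
        pipette_stack=stack,
        tip_roi=roi_sample["roi"],
        descent_frames=seq["frames"],
        descent=seq["descent"],
        model=model,
        cell_center=seq["cell_center"],
    )
    truth = {
        "tip_z_um": pip_spec.pipette_tip_z,
        "tip_xy_px": roi_sample["tip_xy"],
        "neuron_center_z_um": center_z,
        "contact_z_um": seq["contact_z"],
    }
    return inputs, truth


def render_descent_frames(
    spec: SceneSpec,
    focal_z: float,
    descent: list[tuple[float, float]],
) -> list:
    """Frames of the pipette descending through a fixed focal plane.

    Each schedule entry ``(time_s, z_um)`` gives the tip height; the frame
    is rendered with the tip offset ``z_um - focal_z`` from the plane (on
    the visible approach side while above it).  Returns
    :class:`stacks.TimedFrame` objects.
    """
    from .stacks import TimedFrame

    frames = []
    for t, z in descent:
        frame_spec = replace(spec, pipette_tip_z=float(z))
        frames.append(TimedFrame(time_s=float(t), image=render_pipette_frame(frame_spec, focal_z)))
    return frames
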