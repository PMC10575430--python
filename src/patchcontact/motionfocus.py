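"""Mixture-of-Gaussians motion detection and pipette depth focusing.

The tilted pipette never appears fully sharp, so ordinary sharpness scores
cannot focus its tip.  Instead, the focal plane starts below the tip (where
raising it changes nothing in the image) and is swept upward; the moment
the tip crosses the plane, moving structure appears.  Each pixel's history
is modelled as a small mixture of Gaussians

    P(I(x, y, t)) = eta(x; mu_t, sigma_t),

a pixel counting as foreground when its gray value lies further than
``match_sigmas`` standard deviations from every component.  The background
image B assembled from the dominant components is differenced against the
current frame f_n,

    D_n(x, y) = |B(x, y) - f_n(x, y)|,     R_n = 255 where D_n > T else 0,

and the clarity indicator is the rightmost column occupied by a
sufficiently large moving blob, normalised by image width.  The indicator
is ~0 before the tip focuses and jumps like a step function once it does;
the step is where the tip's focal plane is declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .errors import FocusNotFoundError, InvalidSpecError
from .stacks import Frame, ZStack

__all__ = [
    "MixtureConfig",
    "MixtureBackgroundModel",
    "foreground_mask",
    "clarity_indicator",
    "FocusResult",
    "detect_focus",
]


@dataclass(frozen=True)
class MixtureConfig:
    """Knobs of the per-pixel Gaussian mixture and the step detector."""

    n_components: int = 3  # 3-5 components
    learning_rate: float = 0.05  # per-frame adaption fraction
    match_sigmas: float = 2.0  # match window in sigmas
    sigma_min: float = 2.0  # gray-level floor on component sd
    sigma_init: float = 15.0  # sd given to newly created components
    new_weight: float = 0.05  # weight given to replacement components
    threshold_T: float = 15.0  # gray threshold for |B - f| binarisation
    min_blob_px: int = 20  # ignore moving blobs smaller than this
    step_fraction: float = 0.5  # indicator must exceed this x running max
    consecutive: int = 3  # frames the step must persist
    warmup_frames: int = 5  # model-update-only frames at sweep start

    def __post_init__(self) -> None:
        if not 3 <= self.n_components <= 5:
            raise InvalidSpecError("n_components must be within 3..5")
        if not 0 < self.learning_rate < 1:
            raise InvalidSpecError("learning_rate must be in (0, 1)")
        if self.sigma_min <= 0:
            raise InvalidSpecError("sigma_min must be > 0")


class MixtureBackgroundModel:
    """Adaptive per-pixel mixture of ``K`` Gaussians over gray values.

    State arrays have shape (K, rows, cols).  Component weights are kept
    normalised to 1 per pixel after every update and standard deviations
    are floored at ``sigma_min``.
    """

    def __init__(self, shape: tuple[int, int], config: MixtureConfig | None = None):
        self.config = config or MixtureConfig()
        k = self.config.n_components
        self.shape = tuple(shape)
        self.weight = np.zeros((k,) + self.shape, dtype=np.float64)
        self.mean = np.zeros((k,) + self.shape, dtype=np.float64)
        self.var = np.full((k,) + self.shape, self.config.sigma_init**2)
        self._initialised = False

    # -- queries ----------------------------------------------------------

    def background_image(self) -> np.ndarray:
        """Gray image from each pixel's most probable component
        (largest weight / sigma)."""
        fitness = self.weight / np.sqrt(self.var)
        best = np.argmax(fitness, axis=0)
        return np.take_along_axis(self.mean, best[None], axis=0)[0]

    # -- update -----------------------------------------------------------

    def update(self, frame: Frame) -> np.ndarray:
        """Absorb one frame; returns the boolean foreground-flag image.

        A pixel is foreground when no component matches it within
        ``match_sigmas`` standard deviations.  The best-fitting matched
        component is pulled toward the observation; where nothing matches,
        the weakest component is replaced by a fresh wide one.
        """
        x = np.asarray(frame, dtype=np.float64)
        if x.shape != self.shape:
            raise InvalidSpecError(
                f"frame shape {x.shape} does not match model shape {self.shape}"
            )
        cfg = self.config
        if not self._initialised:
            self.weight[0] = 1.0
            self.mean[0] = x
            self._initialised = True
            return np.zeros(self.shape, dtype=bool)

        sd = np.sqrt(self.var)
        dist = np.abs(x[None] - self.mean)
        matched = (dist <= cfg.match_sigmas * sd) & (self.weight > 0)
        has_match = matched.any(axis=0)

        # best matching component per pixel by weight/sigma ranking
        fitness = np.where(matched, self.weight / sd, -np.inf)
        best = np.argmax(fitness, axis=0)
        onehot = np.zeros_like(self.weight, dtype=bool)
        np.put_along_axis(onehot, best[None], True, axis=0)
        winner = onehot & has_match[None]

        lr = cfg.learning_rate
        self.weight = np.where(
            has_match[None], (1 - lr) * self.weight + lr * winner, self.weight
        )
        diff = x[None] - self.mean
        self.mean = np.where(winner, self.mean + lr * diff, self.mean)
        self.var = np.where(winner, (1 - lr) * self.var + lr * diff**2, self.var)

        # no match: replace the lowest-weight component with a wide one at x
        if (~has_match).any():
            weakest = np.argmin(self.weight, axis=0)
            repl = np.zeros_like(onehot)
            np.put_along_axis(repl, weakest[None], True, axis=0)
            repl &= ~has_match[None]
            self.mean = np.where(repl, x[None], self.mean)
            self.var = np.where(repl, cfg.sigma_init**2, self.var)
            self.weight = np.where(repl, cfg.new_weight, self.weight)

        self.var = np.maximum(self.var, cfg.sigma_min**2)
        self.weight /= self.weight.sum(axis=0, keepdims=True)
        return ~has_match


def foreground_mask(background: np.ndarray, frame: np.ndarray, T: float) -> np.ndarray:
    """Binarised background difference: 255 where |B - f_n| > T, else 0."""
    b = np.asarray(background, dtype=np.float64)
    f = np.asarray(frame, dtype=np.float64)
    if b.shape != f.shape:
        raise InvalidSpecError("background/frame shape mismatch")
    if T < 0:
        raise InvalidSpecError("threshold T must be >= 0")
    return np.where(np.abs(b - f) > T, 255, 0).astype(np.uint8)


def clarity_indicator(mask: np.ndarray, min_blob_px: int = 20) -> float:
    """Rightmost moving column, normalised by image width.

    Only connected foreground components of at least ``min_blob_px`` pixels
    count, which suppresses isolated noise speckle; with no qualifying
    pixels the indicator is 0.  The tip is the rightmost structure that
    moves, so this rises sharply when the tip comes into focus.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        return 0.0
    labels = cc_label(m, connectivity=2)
    counts = np.bincount(labels.ravel())
    keep = np.zeros(len(counts), dtype=bool)
    keep[1:] = counts[1:] >= min_blob_px
    big = keep[labels]
    if not big.any():
        return 0.0
    cols = np.nonzero(big.any(axis=0))[0]
    return float(cols.max()) / m.shape[1]


@dataclass
class FocusResult:
    """Declared tip focal plane plus the clarity curve behind it."""

    focal_z_um: float
    curve: list[tuple[float, float]] = field(default_factory=list)  # (z, indicator)


def detect_focus(stack: ZStack, config: MixtureConfig | None = None) -> FocusResult:
    """Sweep the stack (focal z increasing from below the tip) and declare
    the tip focal plane at the clarity step.

    A frame is *eligible* when its indicator is positive and at least
    ``step_fraction`` of the running maximum; the declared plane is the z
    of the first frame of the first run of ``consecutive`` eligible frames.
    The first ``warmup_frames`` frames only train the background model.
    The stored curve is normalised by its maximum.
    """
    cfg = config or MixtureConfig()
    model = MixtureBackgroundModel(stack.shape, cfg)
    curve: list[tuple[float, float]] = []
    run_start: int | None = None
    run_len = 0
    running_max = 0.0
    declared: float | None = None
    for idx, (z, frame) in enumerate(stack):
        background = model.background_image()
        flags = model.update(frame)
        if idx == 0 or idx < cfg.warmup_frames:
            curve.append((float(z), 0.0))
            continue
        # moving pixels: unmatched by the mixture AND above the difference
        # threshold against the assembled background image
        diff_mask = foreground_mask(background, frame, cfg.threshold_T) > 0
        mask = (flags & diff_mask).astype(np.uint8) * 255
        ind = clarity_indicator(mask, cfg.min_blob_px)
        curve.append((float(z), ind))
        running_max = max(running_max, ind)
        if ind > 0 and ind >= cfg.step_fraction * running_max:
            if run_start is None:
                run_start = idx
            run_len += 1
            if run_len >= cfg.consecutive:
                declared = float(stack.z_um[run_start])
                break
        else:
            run_start, run_len = None, 0
    if declared is None:
        raise FocusNotFoundError(
            "no clarity step found in the swept range; the stack may lie "
            "entirely below the pipette tip"
        )
    peak = max(i for _, i in curve) or 1.0
    curve = [(z, i / peak) for z, i in curve]
    return FocusResult(focal_z_um=declared, curve=curve)
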