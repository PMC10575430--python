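"""CU-net: a multi-task U-net that segments the pipette and regresses its
defocus distance from one grayscale ROI.

During the descent toward a neuron the background changes with every
pipette move, so motion cannot tell whether the tip is focused.  Instead a
single 128x128 crop around the target cell is pushed through a shared
convolutional encoder feeding two heads: a U-net style decoder that
predicts the binary pipette mask (binary cross entropy), and a regression
stack — convolution, global pooling, fully connected layer — on the
encoder bottleneck that outputs the tip's defocus degree in [0, 1], 1.0
meaning 10 um from the focal plane (mean squared error).  The mask task
biases the shared features toward pipette pixels, which is what makes the
regression work against cluttered backgrounds.  The total training loss is

    L_total = alpha * L_mask + beta * L_defocus,  alpha = 0.5, beta = 1.

The ROI convention: with the target cell at (cx, cy), take 256 px to the
left (where the taper lies), 128 px to the right, above and below — a
384x256 crop — and resize it to 128x128.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import InvalidSpecError
from .nn import F32
from .stacks import Frame
from .tiplocate import RoiImage

__all__ = [
    "CuNetConfig",
    "DefocusEstimate",
    "CuNet",
    "crop_roi",
    "resize_mask_roi",
    "total_loss",
    "train",
    "predict_defocus",
    "save_model",
    "load_model",
]

# ROI crop rule: (left, right, up, down) pixels around the cell centre
CROP_LEFT, CROP_RIGHT, CROP_UP, CROP_DOWN = 256, 128, 128, 128


@dataclass(frozen=True)
class CuNetConfig:
    """Architecture and training knobs of the defocus network."""

    input_size: tuple[int, int] = (128, 128)
    encoder_depth: int = 4
    base_channels: int = 8
    alpha: float = 0.5  # mask-loss weight
    beta: float = 1.0  # defocus-loss weight
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidSpecError("loss weights must be >= 0")
        if self.input_size[0] != self.input_size[1]:
            raise InvalidSpecError("input must be square")
        if self.input_size[0] % (2**self.encoder_depth) != 0:
            raise InvalidSpecError("input size must be divisible by 2**depth")


@dataclass
class DefocusEstimate:
    """Network output: defocus degree in [0, 1] plus the pipette mask."""

    defocus: float
    mask: np.ndarray  # bool, input resolution

    def __post_init__(self) -> None:
        self.defocus = float(np.clip(self.defocus, 0.0, 1.0))


# ---------------------------------------------------------------------------
# ROI plumbing
# ---------------------------------------------------------------------------


def crop_roi(frame: Frame, cell_center: tuple[int, int],
             out_size: tuple[int, int] = (128, 128)) -> RoiImage:
    """Crop the 384x256 region around the cell and resize to the network
    input size; borders are handled by edge replication."""
    cx, cy = int(round(cell_center[0])), int(round(cell_center[1]))
    rows, cols = frame.shape
    if not (0 <= cx < cols and 0 <= cy < rows):
        raise InvalidSpecError("cell centre outside the frame")
    x0, x1 = cx - CROP_LEFT, cx + CROP_RIGHT
    y0, y1 = cy - CROP_UP, cy + CROP_DOWN
    pl, pr = max(0, -x0), max(0, x1 - cols)
    pt, pb = max(0, -y0), max(0, y1 - rows)
    padded = np.pad(np.asarray(frame, dtype=np.float64),
                    ((pt, pb), (pl, pr)), mode="edge")
    crop = padded[y0 + pt : y1 + pt, x0 + pl : x1 + pl]
    small = resize(crop, out_size, order=1, anti_aliasing=True, preserve_range=True)
    return RoiImage(
        image=np.clip(np.rint(small), 0, 255).astype(np.uint8),
        origin_in_frame=(x0, y0),
    )


def resize_mask_roi(mask: np.ndarray, cell_center: tuple[int, int],
                    out_size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Apply the same crop/resize to a boolean ground-truth mask."""
    cx, cy = int(round(cell_center[0])), int(round(cell_center[1]))
    rows, cols = mask.shape
    x0, x1 = cx - CROP_LEFT, cx + CROP_RIGHT
    y0, y1 = cy - CROP_UP, cy + CROP_DOWN
    pl, pr = max(0, -x0), max(0, x1 - cols)
    pt, pb = max(0, -y0), max(0, y1 - rows)
    padded = np.pad(mask.astype(np.float64), ((pt, pb), (pl, pr)), mode="edge")
    crop = padded[y0 + pt : y1 + pt, x0 + pl : x1 + pl]
    small = resize(crop, out_size, order=0, anti_aliasing=False, preserve_range=True)
    return small > 0.5


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def total_loss(mask_pred, mask_true, defocus_pred, defocus_true,
               cfg: CuNetConfig | None = None) -> float:
    """Weighted multi-task loss on *probability* outputs:
    ``alpha * BCE(mask) + beta * MSE(defocus)``."""
    cfg = cfg or CuNetConfig()
    p = np.asarray(mask_pred, dtype=np.float64)
    t = np.asarray(mask_true, dtype=np.float64)
    d = np.asarray(defocus_pred, dtype=np.float64)
    dt = np.asarray(defocus_true, dtype=np.float64)
    if p.shape != t.shape:
        raise InvalidSpecError("mask shape mismatch")
    for arr, name in ((p, "mask_pred"), (t, "mask_true"), (d, "defocus_pred"),
                      (dt, "defocus_true")):
        if np.any(arr < 0) or np.any(arr > 1):
            raise InvalidSpecError(f"{name} must lie in [0, 1]")
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    bce = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    mse = float(((d - dt) ** 2).mean())
    return cfg.alpha * bce + cfg.beta * mse


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class CuNet:
    """Shared encoder, mask decoder, and defocus regression head."""

    def __init__(self, cfg: CuNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg or CuNetConfig()
        rng = rng or np.random.default_rng(self.cfg.seed)
        d = self.cfg.encoder_depth
        ch = [self.cfg.base_channels * (2**i) for i in range(d)]
        self.enc_channels = ch
        p: dict[str, np.ndarray] = {}
        cin = 1
        for i, c in enumerate(ch):
            p[f"enc{i}_w"] = nn.he_init(rng, c, cin, 3)
            p[f"enc{i}_b"] = np.zeros(c, dtype=F32)
            cin = c
        # defocus head on the bottleneck
        hd = max(ch[-1] // 2, 4)
        p["def_w"] = nn.he_init(rng, hd, ch[-1], 3)
        p["def_b"] = np.zeros(hd, dtype=F32)
        p["fc_w"] = (rng.normal(0, 1.0 / np.sqrt(hd), (hd, 1))).astype(F32)
        p["fc_b"] = np.zeros(1, dtype=F32)
        # decoder: deepest level first
        cur = ch[-1]
        for i in reversed(range(d)):
            cout = ch[max(i - 1, 0)]
            p[f"dec{i}_w"] = nn.he_init(rng, cout, cur + ch[i], 3)
            p[f"dec{i}_b"] = np.zeros(cout, dtype=F32)
            cur = cout
        p["mask_w"] = nn.he_init(rng, 1, cur, 1)
        p["mask_b"] = np.zeros(1, dtype=F32)
        self.params = p
        self.head_channels = hd

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, keep: bool = False):
        """x: (N, H, W, 1) float32 in [0, 1].  Returns
        (mask_logits, defocus) and, with ``keep``, a cache for backward."""
        p = self.params
        d = self.cfg.encoder_depth
        cache: dict = {"enc": [], "dec": []}
        cur = x.astype(F32)
        skips = []
        for i in range(d):
            z, cols = nn.conv2d(cur, p[f"enc{i}_w"], p[f"enc{i}_b"])
            a, rmask = nn.relu(z)
            pooled, pcache = nn.maxpool2(a)
            skips.append(a)
            cache["enc"].append((cols if keep else None, rmask, pcache))
            cur = pooled
        bottleneck = cur

        # defocus head
        zh, cols_h = nn.conv2d(bottleneck, p["def_w"], p["def_b"])
        ah, rmask_h = nn.relu(zh)
        gap = ah.mean(axis=(1, 2))  # (N, hd)
        logit_d = gap @ p["fc_w"] + p["fc_b"]  # (N, 1)
        defocus = nn.sigmoid(logit_d)[:, 0]
        cache["head"] = (cols_h if keep else None, rmask_h, ah.shape, gap, logit_d)

        # decoder
        cur = bottleneck
        for i in reversed(range(d)):
            up = nn.upsample2(cur)
            cat = np.concatenate([up, skips[i]], axis=-1)
            z, cols = nn.conv2d(cat, p[f"dec{i}_w"], p[f"dec{i}_b"])
            a, rmask = nn.relu(z)
            cache["dec"].append((cols if keep else None, rmask, up.shape[-1]))
            cur = a
        mask_logits, cols_m = nn.conv2d(cur, p["mask_w"], p["mask_b"])
        cache["mask"] = (cols_m if keep else None, cur.shape)
        return (mask_logits, defocus), cache

    # -- backward ---------------------------------------------------------

    def backward(self, cache, d_mask_logits: np.ndarray, d_logit_d: np.ndarray):
        """Accumulate gradients; ``d_logit_d`` is dL/d(pre-sigmoid defocus)."""
        p = self.params
        d = self.cfg.encoder_depth
        g: dict[str, np.ndarray] = {}

        cols_m, _ = cache["mask"]
        dcur, g["mask_w"], g["mask_b"] = nn.conv2d_backward(
            d_mask_logits.astype(F32), cols_m, p["mask_w"]
        )
        dskips = [None] * d
        # decoder backward: forward ran levels d-1..0, so walk 0..d-1 here;
        # cache["dec"] holds level i at position d-1-i
        for i in range(d):
            cols, rmask, up_ch = cache["dec"][d - 1 - i]
            dz = dcur * rmask
            dcat, g[f"dec{i}_w"], g[f"dec{i}_b"] = nn.conv2d_backward(
                dz, cols, p[f"dec{i}_w"]
            )
            dup, dskip = dcat[..., :up_ch], dcat[..., up_ch:]
            dskips[i] = dskip
            dcur = nn.upsample2_backward(dup)
        d_bottleneck = dcur

        # defocus head backward
        cols_h, rmask_h, ah_shape, gap, _ = cache["head"]
        dld = d_logit_d.astype(F32)  # (N, 1)
        g["fc_w"] = (gap.T @ dld).astype(F32)
        g["fc_b"] = dld.sum(axis=0).astype(F32)
        dgap = dld @ p["fc_w"].T  # (N, hd)
        n, hh, ww, _ = ah_shape
        dah = np.broadcast_to(dgap[:, None, None, :] / (hh * ww), ah_shape)
        dzh = dah * rmask_h
        dbn_head, g["def_w"], g["def_b"] = nn.conv2d_backward(dzh, cols_h, p["def_w"])
        d_bottleneck = d_bottleneck + dbn_head

        # encoder backward
        dcur = d_bottleneck
        for i in reversed(range(d)):
            cols, rmask, pcache = cache["enc"][i]
            da = nn.maxpool2_backward(dcur, pcache) + (
                dskips[i] if dskips[i] is not None else 0
            )
            dz = da * rmask
            dcur, g[f"enc{i}_w"], g[f"enc{i}_b"] = nn.conv2d_backward(
                dz, cols, p[f"enc{i}_w"]
            )
        return g


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------


def _prepare(img: np.ndarray) -> np.ndarray:
    """Per-image standardisation: gray ROIs are dominated by a flat
    background, so zero-mean/unit-variance scaling is what makes the faint
    pipette structure visible to He-initialised filters."""
    x = np.asarray(img, dtype=F32) / 255.0
    return (x - x.mean()) / (x.std() + F32(1e-6))


def _stack_dataset(dataset, size):
    xs, ms, ys = [], [], []
    for roi, mask, label in dataset:
        img = np.asarray(roi)
        if img.shape != size:
            raise InvalidSpecError(f"sample shape {img.shape}, expected {size}")
        xs.append(_prepare(img))
        ms.append(np.asarray(mask, dtype=F32))
        ys.append(float(label))
    x = np.stack(xs)[..., None]
    m = np.stack(ms)[..., None]
    return x, m, np.asarray(ys, dtype=F32)


def train(dataset, cfg: CuNetConfig | None = None, log=None) -> CuNet:
    """Train a CU-net on ``(roi, mask, normalized_defocus)`` samples.

    Fully seeded (weights, shuffling) so repeated runs on one machine give
    identical models.  ``log``, when given, receives one epoch summary
    string per epoch.
    """
    cfg = cfg or CuNetConfig()
    if not dataset:
        raise InvalidSpecError("empty training dataset")
    x, m, y = _stack_dataset(dataset, cfg.input_size)
    rng = np.random.default_rng(cfg.seed)
    model = CuNet(cfg, rng)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    n = len(x)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, mb, yb = x[idx], m[idx], y[idx]
            (mask_logits, defocus), cache = model.forward(xb, keep=True)
            l_mask, dz_mask = nn.bce_with_logits(mask_logits, mb)
            err = defocus - yb
            l_def = float((err**2).mean())
            # d/d logit of beta * MSE(sigmoid(logit))
            dld = (cfg.beta * 2.0 * err / len(yb) * defocus * (1 - defocus))[:, None]
            grads = model.backward(cache, cfg.alpha * dz_mask, dld)
            opt.step(grads)
            tot += (cfg.alpha * l_mask + cfg.beta * l_def) * len(idx)
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.epochs}: loss {tot / n:.4f}")
    return model


def predict_defocus(model: CuNet, roi: RoiImage | np.ndarray,
                    mask_threshold: float = 0.5) -> DefocusEstimate:
    """Run inference on one ROI already cropped/resized per ``crop_roi``."""
    img = roi.image if isinstance(roi, RoiImage) else np.asarray(roi)
    if img.shape != model.cfg.input_size:
        raise InvalidSpecError(
            f"ROI shape {img.shape} does not match input {model.cfg.input_size}"
        )
    x = _prepare(img)[None, ..., None]
    (mask_logits, defocus), _ = model.forward(x, keep=False)
    mask = nn.sigmoid(mask_logits[0, ..., 0]) > mask_threshold
    return DefocusEstimate(defocus=float(defocus[0]), mask=mask)


def save_model(model: CuNet, path) -> None:
    arrays = dict(model.params)
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> CuNet:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
    cfg = CuNetConfig(**cfg_dict)
    model = CuNet(cfg)
    for k in model.params:
        model.params[k] = data[k].astype(F32)
    return model
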