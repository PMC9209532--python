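"""Modified SRGAN for subject-specific fMRI super-resolution.

Departures from the original SRGAN, following the scheme this package
implements:

* no upsampling block — the low-resolution input is upscaled to the
  target matrix size with Lanczos-3 interpolation *before* entering the
  generator, so generator input and output have the same spatial size
  and the network only learns a residual refinement;
* all batch-normalization layers are removed;
* the discriminator has 10 convolutional layers (3x3 kernels, stride 2
  on every second layer, channel width doubling and capped at 8x base);
* the content loss is pixel-wise MSE (no pretrained perceptual
  network), with a small non-saturating adversarial term.

Training is subject-specific: the only training data are that
subject's own static T2*-weighted slice pairs.  One "iteration" is one
optimizer step on a fresh random batch of aligned 64x64 crops.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from ..io import FunctionalSeries, StructuralImage
from .lanczos import upscale_lanczos
from .nn import Adam, Conv2d, Dense, Flatten, LeakyReLU, Param, PReLU, sigmoid, softplus

__all__ = [
    "GanConfig",
    "Generator",
    "Discriminator",
    "TrainedGenerator",
    "train_subject_model",
    "superresolve_series",
    "match_intensity",
    "psnr",
    "PSNR_CAP",
    "describe_architecture",
    "save_model",
    "load_model",
]

PSNR_CAP = 300.0  # dB sentinel reported for identical images


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the modified SRGAN.

    Defaults follow the scheme's training recipe (Adam beta1 = 0.9,
    scale 2, patch 64, batch 2, lr 1e-4, 100k iterations); tests and
    desk-scale runs use far fewer iterations and smaller networks.
    """

    scale: int = 2
    patch_size: int = 64
    batch_size: int = 2
    lr: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    iterations: int = 100_000
    n_disc_conv: int = 10
    n_resblocks: int = 16
    n_features: int = 64
    disc_base_channels: int = 64
    adv_weight: float = 1e-3
    content_loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scale", "patch_size", "batch_size", "iterations", "n_disc_conv", "n_resblocks", "n_features", "disc_base_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.content_loss != "mse":
            raise ValueError("only the pixel-MSE content loss is supported")
        if not (0 <= self.lr and 0 <= self.adam_beta1 < 1):
            raise ValueError("invalid optimizer settings")


class Generator:
    """Residual-refinement generator operating at the target resolution.

    input -> conv+PReLU -> n residual blocks (conv-PReLU-conv + skip)
    -> conv (+ skip from the first feature map) -> conv to 1 channel,
    added to the input (global skip).  The final conv is zero-
    initialized, so an untrained generator is exactly the identity on
    its (Lanczos-upscaled) input.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        f = cfg.n_features
        self.conv_in = Conv2d(1, f, 3, rng=rng)
        self.act_in = PReLU()
        self.blocks = []
        for _ in range(cfg.n_resblocks):
            self.blocks.append((Conv2d(f, f, 3, rng=rng), PReLU(), Conv2d(f, f, 3, rng=rng)))
        self.conv_mid = Conv2d(f, f, 3, rng=rng)
        self.conv_out = Conv2d(f, 1, 3, zero_init=True)

    def layers(self):
        out = [self.conv_in, self.act_in]
        for c1, a, c2 in self.blocks:
            out += [c1, a, c2]
        out += [self.conv_mid, self.conv_out]
        return out

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h0 = self.act_in.forward(self.conv_in.forward(x))
        h = h0
        for c1, a, c2 in self.blocks:
            h = h + c2.forward(a.forward(c1.forward(h)))
        h = self.conv_mid.forward(h) + h0
        return x + self.conv_out.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv_out.backward(dy)
        dh0 = dh.copy()  # skip from the first feature map
        dh = self.conv_mid.backward(dh)
        for c1, a, c2 in reversed(self.blocks):
            d_branch = c1.backward(a.backward(c2.backward(dh)))
            dh = dh + d_branch  # residual skip
        dh0 = dh0 + dh
        dx = self.conv_in.backward(self.act_in.backward(dh0))
        return dx + dy  # global input skip


class Discriminator:
    """Strided CNN classifier: real HR patch vs generated patch.

    ``n_conv`` 3x3 conv layers, stride 2 on every second layer,
    channels doubling every two layers (capped at 8x base), LeakyReLU
    activations, then a flattened dense layer producing one logit.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator, input_size: int | None = None):
        base = cfg.disc_base_channels
        size = input_size or cfg.patch_size
        self.convs: list[Conv2d] = []
        self.acts: list[LeakyReLU] = []
        c_in = 1
        for i in range(cfg.n_disc_conv):
            c_out = min(base * (2 ** (i // 2)), base * 8)
            stride = 2 if i % 2 == 1 else 1
            self.convs.append(Conv2d(c_in, c_out, 3, stride=stride, rng=rng))
            self.acts.append(LeakyReLU(0.2))
            c_in = c_out
            if stride == 2:
                size = (size + 1) // 2
        if size < 1:
            raise ValueError("patch too small for the discriminator depth")
        self.flatten = Flatten()
        self.head = Dense(c_in * size * size, 1, rng=rng)

    def layers(self):
        out = []
        for c, a in zip(self.convs, self.acts):
            out += [c, a]
        out += [self.flatten, self.head]
        return out

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers():
            h = layer.forward(h)
        return h  # (N, 1) logits

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        d = dlogit
        for layer in reversed(self.layers()):
            d = layer.backward(d)
        return d


def describe_architecture(model) -> list[str]:
    """Layer-type names of a model graph (structural introspection)."""
    return [type(layer).__name__ for layer in model.layers()]


@dataclass
class TrainedGenerator:
    """An optimized generator plus everything needed to apply it.

    ``intensity_offset``/``intensity_scale`` record the affine map used
    to normalise training intensities to [0, 1]; inference applies the
    same map, runs the network, and inverts it, so the generator is a
    fixed deterministic function of its parameters.
    """

    generator: Generator
    config: GanConfig
    loss_history: dict[str, np.ndarray]
    intensity_offset: float
    intensity_scale: float

    def apply_frame(self, frame: np.ndarray) -> np.ndarray:
        """Super-resolve one 2D low-resolution frame."""
        up = upscale_lanczos(frame, self.config.scale)
        norm = (up - self.intensity_offset) / self.intensity_scale
        out = self.generator.forward(norm[None, None].astype(np.float32))[0, 0]
        return out.astype(float) * self.intensity_scale + self.intensity_offset

    def apply_frames(self, frames: np.ndarray) -> np.ndarray:
        """Super-resolve a stack of frames, shape (n, h, w) -> (n, H, W)."""
        ups = np.stack([upscale_lanczos(f, self.config.scale) for f in frames])
        norm = (ups - self.intensity_offset) / self.intensity_scale
        out = self.generator.forward(norm[:, None].astype(np.float32))[:, 0]
        return out.astype(float) * self.intensity_scale + self.intensity_offset


def match_intensity(structural: StructuralImage, reference: FunctionalSeries) -> StructuralImage:
    """Affinely rescale structural intensities onto the fMRI range.

    Monotone affine map sending the structural 1st/99th percentiles to
    the reference series' 1st/99th percentiles (robust to outlier
    pixels).  Raises on a constant structural image.
    """
    s_lo, s_hi = np.percentile(structural.data, [1, 99])
    if s_hi <= s_lo:
        raise ValueError("structural image is (near-)constant; cannot match intensity")
    r_lo, r_hi = np.percentile(reference.data, [1, 99])
    scaled = (structural.data - s_lo) / (s_hi - s_lo) * (r_hi - r_lo) + r_lo
    return StructuralImage(
        scaled, pixel_size=structural.pixel_size, slice_thickness=structural.slice_thickness
    )


def psnr(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs return PSNR_CAP."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if data_range is None:
        data_range = float(a.max() - a.min())
        if data_range == 0:
            data_range = 1.0
    if mse == 0:
        return PSNR_CAP
    return min(float(10.0 * np.log10(data_range**2 / mse)), PSNR_CAP)


def _training_stacks(hi: StructuralImage, lo: StructuralImage, cfg: GanConfig):
    h_side = hi.data.shape[0]
    if hi.data.shape[1] != h_side:
        raise ValueError("training slices must be square")
    if lo.data.shape[0] * cfg.scale != h_side or lo.data.shape[1] * cfg.scale != h_side:
        raise ValueError("hi side must equal lo side times the scale factor")
    if hi.n_slices != lo.n_slices or hi.n_slices < 1:
        raise ValueError("need matching, nonempty slice stacks")
    if cfg.patch_size > h_side:
        raise ValueError(
            f"patch_size {cfg.patch_size} exceeds the training image side {h_side}"
        )
    lr_up = np.stack(
        [upscale_lanczos(lo.data[:, :, s], cfg.scale) for s in range(lo.n_slices)]
    )
    hr = hi.data.transpose(2, 0, 1).astype(float)
    return lr_up, hr


def train_subject_model(
    hi: StructuralImage, lo: StructuralImage, cfg: GanConfig
) -> TrainedGenerator:
    """Adversarial training on one subject's structural slice pairs.

    Per iteration: draw ``batch_size`` aligned random crops of the
    (Lanczos-upscaled LR, HR) slices; update the discriminator on real
    vs generated patches (binary cross-entropy), then update the
    generator on pixel-MSE content loss plus ``adv_weight`` times the
    non-saturating adversarial loss.  Fully deterministic given
    ``cfg.seed``.
    """
    lr_up, hr = _training_stacks(hi, lo, cfg)

    # normalise both stacks to [0, 1] with robust percentiles of the HR data
    p_lo, p_hi = np.percentile(hr, [1, 99])
    if p_hi <= p_lo:
        raise ValueError("training images are (near-)constant")
    offset, scale_i = float(p_lo), float(p_hi - p_lo)
    lr_up = ((lr_up - offset) / scale_i).astype(np.float32)
    hr_n = ((hr - offset) / scale_i).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    opt_g = Adam(gen.params(), lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = Adam(disc.params(), lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    n_slices, side, _ = hr_n.shape
    p = cfg.patch_size
    hist_content = np.empty(cfg.iterations)
    hist_adv = np.empty(cfg.iterations)
    hist_disc = np.empty(cfg.iterations)

    for it in range(cfg.iterations):
        idx = rng.integers(0, n_slices, size=cfg.batch_size)
        ox = rng.integers(0, side - p + 1, size=cfg.batch_size)
        oy = rng.integers(0, side - p + 1, size=cfg.batch_size)
        lr_b = np.stack([lr_up[i, x : x + p, y : y + p] for i, x, y in zip(idx, ox, oy)])[:, None]
        hr_b = np.stack([hr_n[i, x : x + p, y : y + p] for i, x, y in zip(idx, ox, oy)])[:, None]

        fake = gen.forward(lr_b)

        # --- discriminator step: -log D(real) - log(1 - D(fake)) ---
        opt_d.zero_grad()
        logit_real = disc.forward(hr_b)
        d_loss = float(np.mean(softplus(-logit_real)))
        disc.backward(-sigmoid(-logit_real) / logit_real.size)
        logit_fake = disc.forward(fake)
        d_loss += float(np.mean(softplus(logit_fake)))
        disc.backward(sigmoid(logit_fake) / logit_fake.size)
        opt_d.step()

        # --- generator step: MSE content + adv_weight * (-log D(fake)) ---
        opt_g.zero_grad()
        diff = fake - hr_b
        content = float(np.mean(diff**2))
        d_fake = 2.0 * diff / diff.size

        opt_d.zero_grad()  # discard disc grads from the generator pass
        logit_fake_g = disc.forward(fake)
        adv = float(np.mean(softplus(-logit_fake_g)))
        d_adv_in = disc.backward(-sigmoid(-logit_fake_g) / logit_fake_g.size)
        opt_d.zero_grad()

        gen.backward((d_fake + cfg.adv_weight * d_adv_in).astype(np.float32))
        opt_g.step()

        hist_content[it] = content
        hist_adv[it] = adv
        hist_disc[it] = d_loss
        if not (np.isfinite(content) and np.isfinite(adv) and np.isfinite(d_loss)):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: content={content}, "
                f"adv={adv}, disc={d_loss} — try a smaller learning rate"
            )

    return TrainedGenerator(
        generator=gen,
        config=cfg,
        loss_history={
            "content": hist_content,
            "adversarial": hist_adv,
            "discriminator": hist_disc,
        },
        intensity_offset=offset,
        intensity_scale=scale_i,
    )


def superresolve_series(
    series: FunctionalSeries, gen: TrainedGenerator, batch: int = 16
) -> FunctionalSeries:
    """Apply the trained generator frame by frame to a 4D series.

    Every frame of every slice is Lanczos-upscaled and refined
    independently; the time axis is untouched and the in-plane pixel
    size shrinks by the scale factor.  Deterministic.
    """
    nx, ny, nsl, nt = series.shape
    s = gen.config.scale
    out = np.empty((nx * s, ny * s, nsl, nt))
    for sl in range(nsl):
        frames = series.data[:, :, sl, :].transpose(2, 0, 1)
        for start in range(0, nt, batch):
            chunk = frames[start : start + batch]
            out[:, :, sl, start : start + chunk.shape[0]] = gen.apply_frames(chunk).transpose(1, 2, 0)
    return FunctionalSeries(
        data=out,
        tr=series.tr,
        pixel_size=series.pixel_size / s,
        slice_thickness=series.slice_thickness,
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TrainedGenerator, path: str | os.PathLike) -> None:
    """Single-archive checkpoint: config JSON + parameters + loss history."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.generator.params())}
    for key, hist in model.loss_history.items():
        arrays[f"hist_{key}"] = hist
    arrays["meta"] = np.frombuffer(
        json.dumps(
            {
                "config": asdict(model.config),
                "intensity_offset": model.intensity_offset,
                "intensity_scale": model.intensity_scale,
            }
        ).encode(),
        dtype=np.uint8,
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | os.PathLike) -> TrainedGenerator:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta"]))
        cfg = GanConfig(**meta["config"])
        gen = Generator(cfg, np.random.default_rng(cfg.seed))
        for i, p in enumerate(gen.params()):
            p.data = archive[f"param_{i}"].astype(p.data.dtype)
        hist = {
            key[len("hist_"):]: archive[key]
            for key in archive.files
            if key.startswith("hist_")
        }
    return TrainedGenerator(
        generator=gen,
        config=cfg,
        loss_history=hist,
        intensity_offset=float(meta["intensity_offset"]),
        intensity_scale=float(meta["intensity_scale"]),
    )
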