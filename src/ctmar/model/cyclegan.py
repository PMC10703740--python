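"""Paired-supervision CycleGAN for image-domain metal artifact reduction.

Two generators map between the artifacted domain X and the clean domain Y
(G_corr : X -> Y produces the corrected slice, G_art : Y -> X the synthetic
artifact), with PatchGAN discriminators on each domain.  The objective is

    L = L_adv(G_corr) + L_adv(G_art)                     (least-squares GAN)
      + lambda_cycle    * [ |x - G_art(G_corr(x))| + |y - G_corr(G_art(y))| ]
      + lambda_identity * [ |G_corr(y) - y| + |G_art(x) - x| ]
      + lambda_paired   * |G_corr(x) - y|

The last term is the paired-supervision pixel loss: because (x, y) pairs are
manufactured by the artifact simulator, the corrector can be anchored
directly to its ground truth; setting ``lambda_paired = 0`` recovers the
plain unpaired CycleGAN objective.

Generators follow the residual-translation recipe (7x7 ingress, two
stride-2 downsamplers, residual blocks, two nearest-neighbour-upsample +
conv stages, 7x7 tanh egress, instance normalization, reflection padding);
discriminators are 70x70-receptive-field patch classifiers.  Everything
runs in float32 numpy with batch size 1 and is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage import transform as sktf

from ..core import CTSlice, PairedSample
from .data import AugmentToggles, HU_CLIP, augment_pair, denormalize, normalize
from .nn import (Adam, Conv2d, InstanceNorm2d, LeakyReLU, Module, ReLU,
                 ReflectionPad2d, Residual, Sequential, Tanh,
                 UpsampleNearest2x, collect_params)

__all__ = [
    "TrainConfig", "CycleMarModel", "build_generator", "build_discriminator",
    "cyclemar_losses", "train_cyclemar", "apply_mar", "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    The regularization weights default to the validated values
    (lambda_cycle = 10, lambda_identity = 15); lambda_paired = 10 is the
    weight of the supervised pixel term.  The reference-scale profile
    (512 px, 500 epochs, batch 1, Adam) is far beyond what a CPU test run
    can do, so :meth:`desk` provides a small profile used throughout the
    test suite; :meth:`full_scale` records the reference settings.
    """

    lambda_cycle: float = 10.0
    lambda_identity: float = 15.0
    lambda_paired: float = 10.0
    epochs: int = 500
    batch_size: int = 1
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    folds: int = 5
    seed: int = 0
    image_size: int = 512
    ngf: int | None = None        # None -> 64 at >=256 px, 16 below
    ndf: int | None = None
    n_blocks: int | None = None   # None -> 9 at >=256 px, 6 below
    replay_buffer: int = 50
    augment: AugmentToggles = field(default_factory=AugmentToggles)
    checkpoint_every: int = 0     # epochs; 0 = never

    def __post_init__(self) -> None:
        for name in ("lambda_cycle", "lambda_identity", "lambda_paired"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size != 1:
            raise ValueError("the training scheme uses batch size 1")
        if self.image_size % 4:
            raise ValueError("image_size must be divisible by 4")

    @classmethod
    def desk(cls, image_size: int = 64, epochs: int = 30, seed: int = 0,
             **overrides) -> "TrainConfig":
        """Small CPU profile: 64 px, narrow nets, few residual blocks."""
        kw = dict(image_size=image_size, epochs=epochs, seed=seed,
                  ngf=8, ndf=8, n_blocks=3,
                  augment=AugmentToggles(rotation=False, horizontal_flip=True,
                                         resized_crop=False, perspective=False))
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        """Reference profile (GPU-scale; documented, not run in tests)."""
        return cls(image_size=512, epochs=500, **overrides)


def build_generator(image_size: int, ngf: int | None = None,
                    n_blocks: int | None = None,
                    rng: np.random.Generator | None = None,
                    dtype=np.float32) -> Sequential:
    """Residual image-translation generator with tanh egress.

    7x7 ingress conv, two stride-2 downsampling stages, ``n_blocks``
    residual blocks (9 at >= 256 px, 6 below by default), two upsampling
    stages, 7x7 egress; instance normalization and reflection padding
    throughout; output in (-1, 1).
    """
    if image_size % 4:
        raise ValueError("image_size must be divisible by 4 "
                         "(two stride-2 stages)")
    rng = rng or np.random.default_rng(0)
    if ngf is None:
        ngf = 64 if image_size >= 256 else 16
    if n_blocks is None:
        n_blocks = 9 if image_size >= 256 else 6

    def conv(cin, cout, k, stride=1, pad=0):
        return Conv2d(cin, cout, k, stride, pad, rng=rng, dtype=dtype)

    layers: list[Module] = [
        ReflectionPad2d(3), conv(1, ngf, 7), InstanceNorm2d(), ReLU(),
        conv(ngf, 2 * ngf, 3, 2, 1), InstanceNorm2d(), ReLU(),
        conv(2 * ngf, 4 * ngf, 3, 2, 1), InstanceNorm2d(), ReLU(),
    ]
    for _ in range(n_blocks):
        layers.append(Residual(Sequential([
            ReflectionPad2d(1), conv(4 * ngf, 4 * ngf, 3), InstanceNorm2d(),
            ReLU(),
            ReflectionPad2d(1), conv(4 * ngf, 4 * ngf, 3), InstanceNorm2d(),
        ])))
    layers += [
        UpsampleNearest2x(), conv(4 * ngf, 2 * ngf, 3, 1, 1),
        InstanceNorm2d(), ReLU(),
        UpsampleNearest2x(), conv(2 * ngf, ngf, 3, 1, 1),
        InstanceNorm2d(), ReLU(),
        ReflectionPad2d(3), conv(ngf, 1, 7), Tanh(),
    ]
    return Sequential(layers)


def build_discriminator(ndf: int | None = None,
                        rng: np.random.Generator | None = None,
                        dtype=np.float32) -> Sequential:
    """70x70-receptive-field patch discriminator (linear patch scores)."""
    rng = rng or np.random.default_rng(0)
    ndf = ndf or 64

    def conv(cin, cout, stride):
        return Conv2d(cin, cout, 4, stride, 1, rng=rng, dtype=dtype)

    return Sequential([
        conv(1, ndf, 2), LeakyReLU(0.2),
        conv(ndf, 2 * ndf, 2), InstanceNorm2d(), LeakyReLU(0.2),
        conv(2 * ndf, 4 * ndf, 2), InstanceNorm2d(), LeakyReLU(0.2),
        conv(4 * ndf, 8 * ndf, 1), InstanceNorm2d(), LeakyReLU(0.2),
        conv(8 * ndf, 1, 1),
    ])


@dataclass
class CycleMarModel:
    """The trained translation system: two generators, two discriminators."""

    G_corr: Sequential
    G_art: Sequential
    D_X: Sequential
    D_Y: Sequential
    cfg: TrainConfig
    history: list = field(default_factory=list)
    trained: bool = False

    @classmethod
    def build(cls, cfg: TrainConfig) -> "CycleMarModel":
        rng = np.random.default_rng([cfg.seed, 0x6E65745F])
        size, ngf, ndf, nb = cfg.image_size, cfg.ngf, cfg.ndf, cfg.n_blocks
        return cls(
            G_corr=build_generator(size, ngf, nb, rng),
            G_art=build_generator(size, ngf, nb, rng),
            D_X=build_discriminator(ndf, rng),
            D_Y=build_discriminator(ndf, rng),
            cfg=cfg)


def _mse_to(pred: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    d = pred - target
    return float(np.mean(d * d)), (2.0 / d.size) * d


def _mae(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    d = a - b
    return float(np.mean(np.abs(d))), np.sign(d) / d.size


def _as_chw(img: np.ndarray) -> np.ndarray:
    return img[None, :, :].astype(np.float32) if img.ndim == 2 else img


def cyclemar_losses(model: CycleMarModel, x: np.ndarray, y: np.ndarray,
                    cfg: TrainConfig | None = None) -> dict[str, float]:
    """Evaluate every loss component at (x, y) without updating anything.

    ``x`` is a normalized artifacted raster, ``y`` its clean counterpart.
    Returns adv_G, adv_D, cycle, identity, paired and total_G; total_G is
    exactly adv_G + cycle + identity + paired.
    """
    cfg = cfg or model.cfg
    x, y = _as_chw(x), _as_chw(y)
    if x.shape != y.shape:
        raise ValueError("x and y must be congruent")
    fake_y = model.G_corr.forward(x)[0]
    fake_x = model.G_art.forward(y)[0]
    rec_x = model.G_art.forward(fake_y)[0]
    rec_y = model.G_corr.forward(fake_x)[0]
    idt_y = model.G_corr.forward(y)[0]
    idt_x = model.G_art.forward(x)[0]

    adv_g = (_mse_to(model.D_Y.forward(fake_y)[0], 1.0)[0]
             + _mse_to(model.D_X.forward(fake_x)[0], 1.0)[0])
    cyc = cfg.lambda_cycle * (_mae(rec_x, x)[0] + _mae(rec_y, y)[0])
    idt = cfg.lambda_identity * (_mae(idt_y, y)[0] + _mae(idt_x, x)[0])
    paired = cfg.lambda_paired * _mae(fake_y, y)[0]
    adv_d = 0.5 * (_mse_to(model.D_Y.forward(y)[0], 1.0)[0]
                   + _mse_to(model.D_Y.forward(fake_y)[0], 0.0)[0]
                   + _mse_to(model.D_X.forward(x)[0], 1.0)[0]
                   + _mse_to(model.D_X.forward(fake_x)[0], 0.0)[0])
    return {"adv_G": adv_g, "adv_D": adv_d, "cycle": cyc, "identity": idt,
            "paired": paired, "total_G": adv_g + cyc + idt + paired}


class _ReplayBuffer:
    """Pool of past generated images for discriminator stabilization."""

    def __init__(self, size: int, rng: np.random.Generator) -> None:
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, img: np.ndarray) -> np.ndarray:
        if self.size <= 0:
            return img
        if len(self.images) < self.size:
            self.images.append(img.copy())
            return img
        if self.rng.random() < 0.5:
            i = int(self.rng.integers(0, self.size))
            out = self.images[i]
            self.images[i] = img.copy()
            return out
        return img


def _train_step(model: CycleMarModel, x: np.ndarray, y: np.ndarray,
                opt_g: Adam, opt_dx: Adam, opt_dy: Adam,
                buf_x: _ReplayBuffer, buf_y: _ReplayBuffer,
                cfg: TrainConfig) -> dict[str, float]:
    # ---- generator pass -------------------------------------------------
    fake_y, c_fy = model.G_corr.forward(x)
    fake_x, c_fx = model.G_art.forward(y)
    rec_x, c_rx = model.G_art.forward(fake_y)
    rec_y, c_ry = model.G_corr.forward(fake_x)
    idt_y, c_iy = model.G_corr.forward(y)
    idt_x, c_ix = model.G_art.forward(x)
    d_fy, c_dfy = model.D_Y.forward(fake_y)
    d_fx, c_dfx = model.D_X.forward(fake_x)

    adv_y, g_adv_y = _mse_to(d_fy, 1.0)
    adv_x, g_adv_x = _mse_to(d_fx, 1.0)
    l_rx, g_rx = _mae(rec_x, x)
    l_ry, g_ry = _mae(rec_y, y)
    l_iy, g_iy = _mae(idt_y, y)
    l_ix, g_ix = _mae(idt_x, x)
    l_pair, g_pair = _mae(fake_y, y)

    lc, li, lp = cfg.lambda_cycle, cfg.lambda_identity, cfg.lambda_paired
    comp = {"adv_G": adv_y + adv_x, "cycle": lc * (l_rx + l_ry),
            "identity": li * (l_iy + l_ix), "paired": lp * l_pair}
    comp["total_G"] = sum(comp.values())

    opt_g.zero_grad()
    # grads w.r.t. fake_y: adversarial (through D_Y), paired, cycle x-path
    g_fake_y = model.D_Y.backward(c_dfy, g_adv_y.astype(np.float32))
    g_fake_y = g_fake_y + lp * g_pair
    g_fake_y = g_fake_y + model.G_art.backward(c_rx, (lc * g_rx).astype(
        np.float32))
    # grads w.r.t. fake_x: adversarial (through D_X), cycle y-path
    g_fake_x = model.D_X.backward(c_dfx, g_adv_x.astype(np.float32))
    g_fake_x = g_fake_x + model.G_corr.backward(c_ry, (lc * g_ry).astype(
        np.float32))
    model.G_corr.backward(c_fy, g_fake_y.astype(np.float32))
    model.G_art.backward(c_fx, g_fake_x.astype(np.float32))
    model.G_corr.backward(c_iy, (li * g_iy).astype(np.float32))
    model.G_art.backward(c_ix, (li * g_ix).astype(np.float32))
    opt_g.step()

    # ---- discriminator passes (replay buffer for the fakes) -------------
    fy_d = buf_y.query(fake_y)
    fx_d = buf_x.query(fake_x)
    adv_d = 0.0
    for disc, opt, real, fake in ((model.D_Y, opt_dy, y, fy_d),
                                  (model.D_X, opt_dx, x, fx_d)):
        opt.zero_grad()
        p_r, c_r = disc.forward(real)
        l_r, g_r = _mse_to(p_r, 1.0)
        disc.backward(c_r, (0.5 * g_r).astype(np.float32))
        p_f, c_f = disc.forward(fake)
        l_f, g_f = _mse_to(p_f, 0.0)
        disc.backward(c_f, (0.5 * g_f).astype(np.float32))
        opt.step()
        adv_d += 0.5 * (l_r + l_f)
    comp["adv_D"] = adv_d
    return comp


def train_cyclemar(pairs: list[PairedSample],
                   cfg: TrainConfig) -> CycleMarModel:
    """Train the translation system on simulated (ref, art) pairs.

    Alternates generator and discriminator Adam updates, one pair per step;
    per-epoch mean loss components are logged to ``model.history``.  Data
    order, weight initialization and augmentation all derive from
    ``cfg.seed``, so a rerun with the same config is bit-identical.  A
    non-finite generator loss aborts with the offending epoch/step.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    model = CycleMarModel.build(cfg)
    data = []
    for p in pairs:
        x, y = normalize(p.art), normalize(p.ref)
        if x.shape != (cfg.image_size, cfg.image_size):
            raise ValueError(
                f"pair {p.slice_id!r} shape {x.shape} does not match the "
                f"model's native size {cfg.image_size}")
        data.append((x, y))

    opt_g = Adam(collect_params(model.G_corr) + collect_params(model.G_art),
                 lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_dx = Adam(collect_params(model.D_X), lr=cfg.lr, beta1=cfg.beta1,
                  beta2=cfg.beta2)
    opt_dy = Adam(collect_params(model.D_Y), lr=cfg.lr, beta1=cfg.beta1,
                  beta2=cfg.beta2)
    rng = np.random.default_rng([cfg.seed, 0x747261696E])
    buf_x = _ReplayBuffer(cfg.replay_buffer, rng)
    buf_y = _ReplayBuffer(cfg.replay_buffer, rng)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        sums: dict[str, float] = {}
        for step, i in enumerate(order):
            x, y = data[i]
            if cfg.augment.any():
                y, x = augment_pair(y, x, cfg.augment, rng)
            comp = _train_step(model, _as_chw(x), _as_chw(y), opt_g, opt_dx,
                               opt_dy, buf_x, buf_y, cfg)
            if not np.isfinite(comp["total_G"]):
                raise RuntimeError(
                    f"generator loss diverged at epoch {epoch}, step {step}")
            for k, v in comp.items():
                sums[k] = sums.get(k, 0.0) + v
        model.history.append(
            {"epoch": epoch, **{k: v / len(data) for k, v in sums.items()}})
    model.trained = True
    return model


def apply_mar(model: CycleMarModel, ct_art: CTSlice) -> CTSlice:
    """Correct one artifacted slice: CT_cor = denorm(G_corr(norm(CT_art))).

    Input HU outside [-1000, 1000] is clipped (count recorded in metadata);
    slices that do not match the model's native size are resized for
    inference and the result resized back (recorded as well).  Inference is
    deterministic.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    n_clip = int(np.sum(np.abs(ct_art.values) > HU_CLIP))
    x = normalize(ct_art)
    native = model.cfg.image_size
    resized = x.shape != (native, native)
    if resized:
        x = sktf.resize(x, (native, native), order=1, preserve_range=True,
                        anti_aliasing=True).astype(np.float32)
    y = model.G_corr.forward(_as_chw(x))[0][0]
    if resized:
        y = sktf.resize(y, ct_art.shape, order=1, preserve_range=True,
                        anti_aliasing=False)
    out = denormalize(y, like=ct_art)
    out.id = ct_art.id + "-cor"
    out.meta = dict(ct_art.meta, clipped_pixels=n_clip,
                    inference_resized=bool(resized))
    return out


def save_model(model: CycleMarModel, path) -> None:
    """Single-file archive: config + weights + history (bit-exact reload)."""
    arrays = {}
    for gname in ("G_corr", "G_art", "D_X", "D_Y"):
        net = getattr(model, gname)
        for i, (mod, name) in enumerate(collect_params(net)):
            arrays[f"{gname}/{i}/{name}"] = mod.params[name]
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    cfg = asdict(model.cfg)
    cfg["augment"] = asdict(model.cfg.augment)
    manifest = {"config": cfg, "history": model.history,
                "trained": model.trained}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as z:
        z.writestr("weights.npz", buf.getvalue())
        z.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_model(path) -> CycleMarModel:
    with zipfile.ZipFile(path) as z:
        manifest = json.loads(z.read("manifest.json"))
        npz = np.load(io.BytesIO(z.read("weights.npz")))
        cfg_d = dict(manifest["config"])
        cfg_d["augment"] = AugmentToggles(**cfg_d["augment"])
        cfg = TrainConfig(**cfg_d)
        model = CycleMarModel.build(cfg)
        for gname in ("G_corr", "G_art", "D_X", "D_Y"):
            net = getattr(model, gname)
            for i, (mod, name) in enumerate(collect_params(net)):
                mod.params[name][...] = npz[f"{gname}/{i}/{name}"]
        model.history = manifest["history"]
        model.trained = manifest["trained"]
    return model
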