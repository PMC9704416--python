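"""The three network families of the pipeline and their exact accounting.

* **U-Net generators** (G1: RGB→LSCI healthy-anatomy translator, G2:
  LSCI→RGB translator for registration): stride-2 kernel-4 encoder/decoder
  stacks with skip connections, leaky-ReLU encoder, ReLU decoder, batch
  normalization on interior blocks, Tanh output; 50% decoder dropout in G1.
* **PatchGAN discriminators** (D1, D2): fully convolutional classifiers on
  the 6-channel concatenation of a conditioning image and a candidate
  image, returning a patch grid of real/fake scores.
* **Registration network** (R1): kernel-3 convolutional encoder over the
  6-channel RGB⊕LSCI pair, a residual trunk at the bottleneck width, a
  resize-convolution decoder with per-level refinement residual blocks, and
  a 2-channel displacement head whose output is average-pooled onto a
  coarse control grid, bounded by Tanh·max_disp, and densified to a
  full-resolution deformation field by thin-plate-spline interpolation.

The reference channel lists reproduce the published parameter budgets: the
G1/D1 counts correspond to affine batch normalization and the G2/D2 counts
to the same stacks with non-affine batch normalization (the registration
family follows the non-affine convention).
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from ischemap import nn, tps
from ischemap.errors import SpecError, StateError
from ischemap.nn import functional as F
from ischemap.nn.autograd import Tensor

TABLE_GEN_ENC = [64, 128, 256, 512, 512, 512, 512, 512]
TABLE_DISC = [64, 128, 256, 512]
TABLE_REG_ENC = [32, 64, 128]
TABLE_FEATURE_MAPS = {
    "G1": [3, 64, 128, 256, 512, 1024, 512, 256, 128, 3],
    "D1": [6, 64, 128, 256, 512, 1],
    "G2": [3, 64, 128, 256, 512, 1024, 512, 256, 128, 3],
    "D2": [6, 64, 128, 256, 512, 1],
    "R1": [6, 32, 64, 128, 64, 32, 2],
}


@dataclass
class NetworkSpec:
    """Declarative description of one network; builders consume these."""

    role: str                           # generator | discriminator | registration
    enc_channels: list                  # per-level widths
    input_shape: tuple = (256, 256, 3)
    kernel_size: int = 4
    in_channels: int = 3
    out_channels: int = 3
    use_dropout: bool = False
    dropout_rate: float = 0.5
    affine_bn: bool = True
    n_res_blocks: int = 6               # registration trunk depth
    control_grid: tuple = (8, 8)        # TPS control points
    max_disp: float = 16.0              # px at the working resolution
    name: str = ""

    def __post_init__(self):
        if self.role not in ("generator", "discriminator", "registration"):
            raise SpecError(f"unknown role {self.role!r}")
        if self.kernel_size not in (3, 4):
            raise SpecError("kernel_size must be 3 or 4")

    @property
    def feature_maps(self) -> list:
        """The abbreviated printed-style channel list."""
        if self.role == "generator":
            e = self.enc_channels
            return ([self.in_channels] + e[:4] + [2 * e[-1]]
                    + e[3:0:-1] + [self.out_channels]) \
                if len(e) >= 4 else [self.in_channels, *e, self.out_channels]
        if self.role == "discriminator":
            return [self.in_channels, *self.enc_channels, 1]
        e = self.enc_channels
        return [self.in_channels, *e, *e[-2::-1], self.out_channels]

    # -- named reference constructions ------------------------------------
    @classmethod
    def table1(cls, name: str) -> "NetworkSpec":
        name = name.upper()
        if name in ("G1", "G2"):
            spec = cls(role="generator", enc_channels=list(TABLE_GEN_ENC),
                       kernel_size=4, input_shape=(256, 256, 3),
                       in_channels=3, out_channels=3,
                       use_dropout=(name == "G1"),
                       affine_bn=(name == "G1"), name=name)
        elif name in ("D1", "D2"):
            spec = cls(role="discriminator", enc_channels=list(TABLE_DISC),
                       kernel_size=4, input_shape=(256, 256, 6),
                       in_channels=6, out_channels=1,
                       affine_bn=(name == "D1"), name=name)
        elif name == "R1":
            spec = cls(role="registration", enc_channels=list(TABLE_REG_ENC),
                       kernel_size=3, input_shape=(256, 256, 6),
                       in_channels=6, out_channels=2, affine_bn=False,
                       n_res_blocks=6, name=name)
        else:
            raise SpecError(f"unknown Table-1 network {name!r}")
        expected = TABLE_FEATURE_MAPS[name]
        if spec.feature_maps != expected:
            raise SpecError(
                f"{name} channel list {spec.feature_maps} != {expected}")
        return spec

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        d["input_shape"] = tuple(d["input_shape"])
        d["control_grid"] = tuple(d["control_grid"])
        return cls(**d)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class UNetGenerator(nn.Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        if spec.role != "generator":
            raise SpecError("spec.role must be 'generator'")
        self.spec = spec
        e = spec.enc_channels
        k, pad = spec.kernel_size, (spec.kernel_size - 1) // 2
        if k == 4:
            pad = 1
        self.downs = [nn.Conv2d(spec.in_channels if i == 0 else e[i - 1],
                                e[i], k, stride=2, padding=pad, rng=rng)
                      for i in range(len(e))]
        # BN on interior encoder blocks (not first, not innermost)
        self.down_bns = [nn.BatchNorm2d(e[i], affine=spec.affine_bn)
                         for i in range(1, len(e) - 1)]
        ups, up_bns = [], []
        for i in range(len(e) - 1, 0, -1):
            c_in = e[i] if i == len(e) - 1 else 2 * e[i]
            c_out = e[i - 1]
            ups.append(nn.ConvTranspose2d(c_in, c_out, k, stride=2,
                                          padding=pad, rng=rng))
            up_bns.append(nn.BatchNorm2d(c_out, affine=spec.affine_bn))
        ups.append(nn.ConvTranspose2d(2 * e[0], spec.out_channels, k,
                                      stride=2, padding=pad, rng=rng))
        self.ups = ups
        self.up_bns = up_bns
        self.dropouts = [nn.Dropout(spec.dropout_rate)
                         for _ in range(min(3, len(e) - 1))] \
            if spec.use_dropout else []

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for i, conv in enumerate(self.downs):
            if i > 0:
                h = F.leaky_relu(h, 0.2)
            h = conv(h)
            if 0 < i < len(self.downs) - 1:
                h = self.down_bns[i - 1](h)
            skips.append(h)
        n_dec = len(self.ups)
        for j in range(n_dec):
            h = F.relu(h)
            h = self.ups[j](h)
            if j < n_dec - 1:
                h = self.up_bns[j](h)
                if j < len(self.dropouts):
                    h = self.dropouts[j](h)
                h = F.concat([h, skips[n_dec - 2 - j]], axis=1)
        return F.tanh(h)


class PatchDiscriminator(nn.Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        if spec.role != "discriminator":
            raise SpecError("spec.role must be 'discriminator'")
        self.spec = spec
        e = spec.enc_channels
        k, pad = spec.kernel_size, 1
        convs, bns = [], []
        prev = spec.in_channels
        for i, c in enumerate(e):
            stride = 1 if i == len(e) - 1 else 2
            convs.append(nn.Conv2d(prev, c, k, stride=stride, padding=pad,
                                   rng=rng))
            if i > 0:
                bns.append(nn.BatchNorm2d(c, affine=spec.affine_bn))
            prev = c
        convs.append(nn.Conv2d(prev, 1, k, stride=1, padding=pad, rng=rng))
        self.convs = convs
        self.bns = bns

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise SpecError(
                f"discriminator expects {self.spec.in_channels} input "
                f"channels, got {x.shape[1]}")
        h = x
        for i, conv in enumerate(self.convs[:-1]):
            h = conv(h)
            if i > 0:
                h = self.bns[i - 1](h)
            h = F.leaky_relu(h, 0.2)
        return self.convs[-1](h)      # raw patch scores (logits)


class _ResBlock(nn.Module):
    def __init__(self, c: int, affine: bool, rng):
        super().__init__()
        self.c1 = nn.Conv2d(c, c, 3, stride=1, padding=1, rng=rng)
        self.b1 = nn.BatchNorm2d(c, affine=affine)
        self.c2 = nn.Conv2d(c, c, 3, stride=1, padding=1, rng=rng)
        self.b2 = nn.BatchNorm2d(c, affine=affine)

    def forward(self, x):
        h = F.relu(self.b1(self.c1(x)))
        return x + self.b2(self.c2(h))


class RegistrationNet(nn.Module):
    """TPS spatial-transformer: RGB⊕LSCI pair -> dense deformation field."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        if spec.role != "registration":
            raise SpecError("spec.role must be 'registration'")
        self.spec = spec
        e = spec.enc_channels                     # e.g. [32, 64, 128]
        self.stem = nn.Conv2d(spec.in_channels, e[0], 3, 1, 1, rng=rng)
        self.downs = [nn.Conv2d(e[i], e[i + 1], 3, 2, 1, rng=rng)
                      for i in range(len(e) - 1)]
        self.down_bns = [nn.BatchNorm2d(e[i + 1], affine=spec.affine_bn)
                         for i in range(len(e) - 1)]
        self.trunk = [_ResBlock(e[-1], spec.affine_bn, rng)
                      for _ in range(spec.n_res_blocks)]
        ups, up_bns, refine = [], [], []
        for i in range(len(e) - 1, 0, -1):
            ups.append(nn.Conv2d(e[i], e[i - 1], 3, 1, 1, rng=rng))
            up_bns.append(nn.BatchNorm2d(e[i - 1], affine=spec.affine_bn))
            refine.append(_ResBlock(e[i - 1], spec.affine_bn, rng))
        self.ups, self.up_bns, self.refine = ups, up_bns, refine
        self.head = nn.Conv2d(e[0], 2, 3, 1, 1, rng=rng)
        self._basis_cache: dict = {}

    def _basis(self, shape) -> np.ndarray:
        from ischemap.nn.autograd import get_default_dtype

        key = (tuple(shape), np.dtype(get_default_dtype()).name)
        if key not in self._basis_cache:
            # control points sit at the centres of the pooling blocks that
            # produce their values, so value and location agree spatially
            h, w = shape
            gr, gc = self.spec.control_grid
            rows = (np.arange(gr) + 0.5) * (h / gr) - 0.5
            cols = (np.arange(gc) + 0.5) * (w / gc) - 0.5
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
            self._basis_cache[key] = tps.tps_basis(shape, pts).astype(
                get_default_dtype())
        return self._basis_cache[key]

    def forward(self, pair: Tensor) -> Tensor:
        """(N, 6, H, W) concatenated pair -> (N, 2, H, W) displacement field."""
        h = F.leaky_relu(self.stem(pair), 0.2)
        for conv, bn in zip(self.downs, self.down_bns):
            h = F.leaky_relu(bn(conv(h)), 0.2)
        for block in self.trunk:
            h = block(h)
        for conv, bn, ref in zip(self.ups, self.up_bns, self.refine):
            h = F.upsample_nearest(h, 2)
            h = F.relu(bn(conv(h)))
            h = ref(h)
        raw = self.head(h)                       # (N, 2, H, W)
        n, _, hh, ww = raw.shape
        gr, gc = self.spec.control_grid
        if hh % gr or ww % gc:
            raise SpecError(f"image {hh}x{ww} not divisible by control grid")
        pooled = F.avg_pool2d(raw, hh // gr) if gr == gc and hh // gr == ww // gc \
            else None
        if pooled is None:
            raise SpecError("control grid must pool isotropically")
        ctrl = F.tanh(pooled) * self.spec.max_disp   # (N, 2, gr, gc)
        basis = self._basis((hh, ww))                # (HW, M)
        flat = ctrl.reshape(n, 2, gr * gc)
        dense = _tps_apply(flat, basis)              # (N, 2, HW)
        return dense.reshape(n, 2, hh, ww)


def _tps_apply(ctrl: Tensor, basis: np.ndarray) -> Tensor:
    """(N, 2, M) control values -> (N, 2, HW) dense values (linear map)."""
    data = np.einsum("km,ncm->nck", basis, ctrl.data)

    def bw(g):
        ctrl._accumulate(np.einsum("km,nck->ncm", basis, g))

    return Tensor._op(data, (ctrl,), bw)


# ---------------------------------------------------------------------------
# builders and accounting
# ---------------------------------------------------------------------------

def build_generator(spec: NetworkSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: NetworkSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def build_registration_net(spec: NetworkSpec, seed: int = 0) -> RegistrationNet:
    return RegistrationNet(spec, np.random.default_rng(seed))


def build(spec: NetworkSpec, seed: int = 0) -> nn.Module:
    builder = {"generator": build_generator,
               "discriminator": build_discriminator,
               "registration": build_registration_net}[spec.role]
    return builder(spec, seed)


def count_parameters(model: nn.Module) -> int:
    """Total trainable scalars (weights, biases, normalization affine terms)."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Named networks + the specs, config and seed that produced them."""

    models: dict                       # name -> Module
    specs: dict                        # name -> NetworkSpec
    train_config: dict = field(default_factory=dict)
    seed: int = 0
    trained: bool = False
    history: dict = field(default_factory=dict)

    def require_trained(self):
        if not self.trained:
            raise StateError("model bundle has not been trained")

    def save(self, path) -> None:
        meta = {
            "specs": {k: dataclasses.asdict(s) for k, s in self.specs.items()},
            "train_config": self.train_config,
            "seed": self.seed,
            "trained": self.trained,
            "history": {k: list(map(float, v))
                        for k, v in self.history.items()},
        }
        arrays = {}
        for name, model in self.models.items():
            for key, arr in model.state_dict().items():
                arrays[f"{name}|{key}"] = arr
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            npz = np.load(io.BytesIO(zf.read("weights.npz")))
            specs = {}
            for name, d in meta["specs"].items():
                d["input_shape"] = tuple(d["input_shape"])
                d["control_grid"] = tuple(d["control_grid"])
                specs[name] = NetworkSpec(**d)
            models = {name: build(spec) for name, spec in specs.items()}
            states: dict = {name: {} for name in models}
            for full_key in npz.files:
                name, key = full_key.split("|", 1)
                states[name][key] = npz[full_key]
            for name, model in models.items():
                model.load_state_dict(states[name])
                model.eval()
        return cls(models=models, specs=specs,
                   train_config=meta["train_config"], seed=meta["seed"],
                   trained=meta["trained"], history=meta["history"])
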