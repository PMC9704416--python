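"""Healthy-anatomy translation and reconstruction-residual ischemia maps.

A conditional GAN (generator G1, PatchGAN D1) is trained on *healthy*
RGB/LSCI pairs only, to learn the correspondence between tissue morphology
and normal perfusion:

    L_total = L_cGAN(G1, D1) + λ·L_recon(G1),   λ = 100.

At test time G1 translates an RGB image into the speckle pattern healthy
tissue *would* produce; the per-pixel residual r = |y − ŷ| against the
observed LSCI image is therefore near zero on well-perfused tissue and
elevated wherever perfusion deviates from the learned norm.  The residual
is masked to tissue, smoothed by grayscale morphological closing, expressed
in percent of the dynamic range (2 for [−1, 1] images — a fixed scale, so
scores are comparable across samples), and thresholded at 10% to produce
the binary ischemia mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import morphology, transform

from ischemap.errors import (DimensionError, DivergenceError, ValidationError)
from ischemap.networks import ModelBundle, NetworkSpec, build
from ischemap.nn import Adam, functional as F
from ischemap.nn.autograd import Tensor, no_grad
from ischemap.preprocessing import TissueMask

DEFAULT_THRESHOLD = 0.10
DEFAULT_CLOSING_RADIUS = 3


@dataclass
class ResidualMap:
    values: np.ndarray                 # (H, W), nonnegative
    normalization: str = "raw"         # 'raw' | 'percent'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValidationError("residuals must be nonnegative")
        if self.normalization == "percent" and np.any(self.values > 1):
            raise ValidationError("percent residuals must lie in [0, 1]")


@dataclass
class IschemiaProbabilityMap:
    values: np.ndarray                 # (H, W) in [0, 1]; background = 0
    threshold: float = DEFAULT_THRESHOLD
    source_bundle: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class AnomalyTrainConfig:
    epochs: int = 40                   # convergence is typical within 40
    lr: float = 0.0002                 # Adam, G1 and D1
    beta1: float = 0.9
    lambda_recon: float = 100.0
    dropout_rate: float = 0.5          # G1 decoder dropout
    seed: int = 0
    gen_channels: list = dc_field(default_factory=lambda: [16, 32, 64, 64, 64])
    disc_channels: list = dc_field(default_factory=lambda: [16, 32, 64])


def _to3(img: np.ndarray) -> np.ndarray:
    return np.repeat(img[None, None], 3, axis=1)


def _check_finite(value: float, term: str) -> None:
    if not np.isfinite(value):
        raise DivergenceError(f"non-finite loss in term '{term}'")


def train_healthy_model(healthy_pairs: list,
                        lambda_recon: float | None = None,
                        config: AnomalyTrainConfig | None = None
                        ) -> ModelBundle:
    """Train G1 (RGB→LSCI) and D1 on healthy pairs only (batch size 1).

    ``healthy_pairs`` is a sequence of ``(rgb, lsci)`` with rgb (H, W, 3)
    and lsci (H, W), registered and normalised to [−1, 1]; the caller
    asserts they contain no ischemic tissue.  Returns a trained
    ModelBundle with a per-epoch loss history.
    """
    config = config or AnomalyTrainConfig()
    lam = config.lambda_recon if lambda_recon is None else float(lambda_recon)
    if not healthy_pairs:
        raise ValidationError("empty training set")
    size = healthy_pairs[0][0].shape[:2]
    rng = np.random.default_rng(config.seed)
    specs = {
        "G1": NetworkSpec(role="generator",
                          enc_channels=list(config.gen_channels),
                          kernel_size=4, input_shape=(*size, 3), in_channels=3,
                          out_channels=3, use_dropout=True,
                          dropout_rate=config.dropout_rate, affine_bn=True,
                          name="G1"),
        "D1": NetworkSpec(role="discriminator",
                          enc_channels=list(config.disc_channels),
                          kernel_size=4, input_shape=(*size, 6), in_channels=6,
                          out_channels=1, affine_bn=True, name="D1"),
    }
    g1 = build(specs["G1"], seed=config.seed + 11)
    d1 = build(specs["D1"], seed=config.seed + 12)
    g1.set_rng(np.random.default_rng(config.seed + 13))   # dropout stream
    opt_g = Adam(g1.parameters(), lr=config.lr, betas=(config.beta1, 0.999))
    opt_d = Adam(d1.parameters(), lr=config.lr, betas=(config.beta1, 0.999))

    history: dict = {"d_loss": [], "g_adv": [], "recon": [], "total": []}
    for _ in range(config.epochs):
        order = rng.permutation(len(healthy_pairs))
        sums = dict.fromkeys(history, 0.0)
        for idx in order:
            rgb, lsci = healthy_pairs[idx]
            t_rgb = Tensor(rgb.transpose(2, 0, 1)[None])
            t_lsci3 = Tensor(_to3(lsci))

            fake = g1(t_rgb)

            d1.zero_grad()
            d_loss = (F.bce_with_logits(d1(F.concat([t_rgb, t_lsci3], 1)), 1.0)
                      + F.bce_with_logits(
                          d1(F.concat([t_rgb, Tensor(fake.data)], 1)), 0.0))
            _check_finite(d_loss.item(), "LcGAN(D1)")
            d_loss.backward()
            opt_d.step()

            opt_g.zero_grad()
            g_adv = F.bce_with_logits(d1(F.concat([t_rgb, fake], 1)), 1.0)
            recon = F.l1_loss(fake, t_lsci3)
            total = g_adv + lam * recon
            _check_finite(g_adv.item(), "LcGAN(G1)")
            _check_finite(recon.item(), "Lrecon")
            total.backward()
            opt_g.step()

            sums["d_loss"] += d_loss.item()
            sums["g_adv"] += g_adv.item()
            sums["recon"] += recon.item()
            sums["total"] += total.item()
        for k in history:
            history[k].append(sums[k] / len(healthy_pairs))

    for m in (g1, d1):
        m.eval()
    return ModelBundle(models={"G1": g1, "D1": d1}, specs=specs,
                       train_config={"lambda": lam, "lr": config.lr,
                                     "epochs": config.epochs},
                       seed=config.seed, trained=True, history=history)


def reconstruct(bundle: ModelBundle, rgb: np.ndarray) -> np.ndarray:
    """Predicted healthy LSCI ŷ (H, W) in [−1, 1]; deterministic (no dropout)."""
    bundle.require_trained()
    g1 = bundle.models["G1"]
    g1.eval()
    with no_grad():
        out = g1(Tensor(rgb.transpose(2, 0, 1)[None])).data[0]
    return out.mean(axis=0)


def residual(y: np.ndarray, y_hat: np.ndarray,
             percent: bool = False) -> ResidualMap:
    """r = |y − ŷ|; percent form divides by the fixed dynamic range (2)."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise DimensionError("y and ŷ shapes differ")
    r = np.abs(y - y_hat)
    if percent:
        return ResidualMap(np.clip(r / 2.0, 0.0, 1.0), "percent")
    return ResidualMap(r, "raw")


def postprocess(r: ResidualMap, mask: TissueMask,
                closing_radius: int = DEFAULT_CLOSING_RADIUS
                ) -> IschemiaProbabilityMap:
    """Mask to tissue, close small holes, express in percent of range.

    Grayscale morphological closing with a disk element fills holes smaller
    than the element while maintaining internal connectivity; masking is
    applied before and after so the background stays exactly zero.
    """
    values = r.values if r.normalization == "percent" \
        else np.clip(r.values / 2.0, 0.0, 1.0)
    m = mask.values.astype(bool)
    if values.shape != m.shape:
        raise DimensionError("residual and mask shapes differ")
    if not m.any():
        raise ValidationError("tissue mask is empty")
    masked = values * m
    closed = morphology.closing(masked, morphology.disk(closing_radius))
    out = np.clip(closed * m, 0.0, 1.0)
    return IschemiaProbabilityMap(out, threshold=DEFAULT_THRESHOLD)


def threshold_mask(prob_map: IschemiaProbabilityMap | np.ndarray,
                   threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary ischemia mask: 1 where P(ischemia) exceeds the threshold."""
    values = prob_map.values if isinstance(prob_map, IschemiaProbabilityMap) \
        else np.asarray(prob_map)
    return values > threshold


def overlay(rgb_highres: np.ndarray,
            prob_map: IschemiaProbabilityMap | np.ndarray,
            upsample_factor: int = 4,
            threshold: float = DEFAULT_THRESHOLD) -> tuple:
    """Upsample the probability map onto a high-resolution RGB image.

    Returns ``(composite, contour)``: the alpha-blended heat overlay with
    the threshold boundary drawn, and the boundary mask itself.
    """
    values = prob_map.values if isinstance(prob_map, IschemiaProbabilityMap) \
        else np.asarray(prob_map)
    rgb = np.asarray(rgb_highres, dtype=np.float64)
    h, w = values.shape
    if rgb.shape[:2] != (h * upsample_factor, w * upsample_factor):
        raise ValidationError(
            "RGB dimensions must equal probability map times the factor")
    up = transform.resize(values, rgb.shape[:2], order=1, mode="edge",
                          anti_aliasing=False)
    heat = np.zeros_like(rgb)
    heat[..., 0] = up
    alpha = 0.5 * up[..., None]
    composite = np.clip(rgb * (1 - alpha) + heat * alpha, 0.0, 1.0)
    mask_up = up > threshold
    contour = mask_up & ~morphology.erosion(mask_up)
    composite[contour] = (1.0, 1.0, 0.0)
    return composite, contour
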