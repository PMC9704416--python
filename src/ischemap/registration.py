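"""Unsupervised multimodal RGB/LSCI registration.

A registration network R1 predicts a dense deformation field from the
concatenated image pair; a translator G2 maps LSCI into the RGB domain; a
PatchGAN D2 judges translated images conditioned on the LSCI input.  All
three are trained jointly on the composite objective

    L_total = L_cGAN + λ_R·L_recon + λ_S·L_smooth + λ_A·L_anti

with defaults λ_R = 150, λ_S = 130, λ_A = −2.0.  L_recon compares both
composition orders (warp-then-translate and translate-then-warp) against
the RGB image; L_smooth penalises bilateral-weighted field differences over
3×3 neighbourhoods, with weights computed from the (fixed) grayscale RGB
guide; L_anti measures how close each branch alone comes to the identity
and enters with a negative weight so the system cannot collapse onto the
zero deformation while G2 silently absorbs the warp.

Registration runs in one direction only: the LSCI image is warped onto the
RGB frame.  Displacement fields are ``(2, H, W)`` arrays (Δrow, Δcol) in
pixels, added to target coordinates when sampling the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ischemap import tps
from ischemap.errors import (DimensionError, DivergenceError, StateError,
                             ValidationError)
from ischemap.networks import ModelBundle, NetworkSpec, build
from ischemap.nn import Adam, functional as F
from ischemap.nn.autograd import Tensor, no_grad
from ischemap.phantom import LandmarkSet


@dataclass
class DeformationField:
    """Per-pixel displacement (Δrow, Δcol) in pixels, stored as (2, H, W)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != 2:
            raise DimensionError("DeformationField needs a (2, H, W) array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("deformation field must be finite")

    @property
    def shape(self):
        return self.values.shape[1:]


@dataclass
class RegistrationLossWeights:
    lambda_r: float = 150.0
    lambda_s: float = 130.0
    lambda_a: float = -2.0


@dataclass
class RegistrationTrainConfig:
    epochs: int = 300
    lr: float = 0.001                 # Adam, for G2, D2 and R1 alike
    beta1: float = 0.9
    seed: int = 0
    gen_channels: list = dc_field(default_factory=lambda: [8, 16, 32, 32, 32])
    disc_channels: list = dc_field(default_factory=lambda: [8, 16, 32])
    reg_channels: list = dc_field(default_factory=lambda: [8, 16, 32])
    n_res_blocks: int = 2
    control_grid: tuple = (4, 4)
    max_disp: float = 12.0
    sigma_spatial: float = 2.0        # bilateral weights, px
    sigma_range: float = 0.1          # bilateral weights, [-1, 1] intensities
    early_stopping: bool = True
    patience: int = 10
    min_delta: float = 1e-3
    min_epochs: int = 30              # let G2 bootstrap before stopping
    warmup_epochs: int = 0            # epochs with R1 frozen while G2 learns
    # route the translate-then-warp reconstruction gradient to R1 only, so
    # the translator cannot absorb per-scene warps through that path (keeps
    # the translation and alignment branches orthogonal)
    detach_translator_in_warp_path: bool = True


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def warp(image: np.ndarray, field: DeformationField | np.ndarray) -> np.ndarray:
    """Bilinear resampling of ``image`` at (r + Δrow, c + Δcol).

    Border replication outside bounds; integer offsets are exact.
    """
    f = field.values if isinstance(field, DeformationField) else np.asarray(field)
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    if f.shape != (2, h, w):
        raise DimensionError(
            f"field shape {f.shape} does not match image {image.shape}")
    squeeze = image.ndim == 2
    img = image[..., None] if squeeze else image
    from ischemap.nn.autograd import default_dtype

    with default_dtype(np.float64):   # exact for integer displacements
        t_img = Tensor(img.transpose(2, 0, 1)[None])
        t_field = Tensor(f[None])
        out = F.warp_bilinear(t_img, t_field).data[0].transpose(1, 2, 0)
    return out[..., 0] if squeeze else out


def bilateral_weights(guide_image: np.ndarray, sigma_spatial: float = 2.0,
                      sigma_range: float = 0.1) -> np.ndarray:
    """Per-pixel 3×3 neighbour weights B(u, v) from a single-channel guide.

    B(u,v) = exp(−‖u−v‖²/2σs²)·exp(−(I(u)−I(v))²/2σr²), normalised per
    pixel to sum to 1 over the 3×3 neighbourhood.  Out-of-bounds neighbours
    receive weight 0.  Returned shape: (H, W, 3, 3).
    """
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValidationError("bilateral sigmas must be positive")
    guide = np.asarray(guide_image, dtype=np.float64)
    if guide.ndim != 2:
        raise DimensionError("guide must be single-channel")
    h, w = guide.shape
    weights = np.zeros((h, w, 3, 3))
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            spatial = np.exp(-(di * di + dj * dj) / (2 * sigma_spatial ** 2))
            shifted = np.full((h, w), np.nan)
            rs = slice(max(0, di), h + min(0, di))
            cs = slice(max(0, dj), w + min(0, dj))
            rt = slice(max(0, -di), h + min(0, -di))
            ct = slice(max(0, -dj), w + min(0, -dj))
            shifted[rt, ct] = guide[rs, cs]
            rng_term = np.exp(-(guide - shifted) ** 2
                              / (2 * sigma_range ** 2))
            wgt = spatial * rng_term
            wgt[np.isnan(shifted)] = 0.0
            weights[:, :, di + 1, dj + 1] = wgt
    weights /= weights.sum(axis=(2, 3), keepdims=True)
    return weights


def _loss_smooth_t(field: Tensor, weights: np.ndarray,
                   eps: float = 1e-12) -> Tensor:
    """Differentiable Σ_v Σ_u B(u,v)·‖ϕ(u) − ϕ(v)‖₂ / (H·W).

    Displacements are measured in normalized grid coordinates (pixels ×
    2/H, the STN grid convention the published loss weights correspond to)
    so the weighting is resolution-independent.
    """
    _, _, h, w = field.shape
    scale = np.array([2.0 / h, 2.0 / w], dtype=field.data.dtype)
    field = field * Tensor(scale[None, :, None, None])
    total = None
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            rs = slice(max(0, di), h + min(0, di))
            cs = slice(max(0, dj), w + min(0, dj))
            rt = slice(max(0, -di), h + min(0, -di))
            ct = slice(max(0, -dj), w + min(0, -dj))
            diff = field[:, :, rt, ct] - field[:, :, rs, cs]
            norm = F.sqrt((diff * diff).sum(axis=1) + eps)   # (N, h', w')
            term = (norm * Tensor(weights[rt, ct, di + 1, dj + 1][None])).sum()
            total = term if total is None else total + term
    return total * (1.0 / (h * w))


def loss_smooth(field: DeformationField | np.ndarray,
                weights: np.ndarray) -> float:
    """Bilateral-weighted smoothness of a deformation field (nonnegative)."""
    f = field.values if isinstance(field, DeformationField) else np.asarray(field)
    if f.shape[1:] != weights.shape[:2]:
        raise DimensionError("field and weights shapes disagree")
    return float(_loss_smooth_t(Tensor(f[None]), weights).data)


def loss_anti(g2_only_output: np.ndarray, rgb: np.ndarray,
              r1_only_output: np.ndarray, lsci: np.ndarray) -> float:
    """E‖O_G2 − I_RGB‖₁ + E‖O_R1 − I_LSCI‖₁ (identity-behaviour penalty)."""
    a = np.mean(np.abs(np.asarray(g2_only_output) - np.asarray(rgb)))
    b = np.mean(np.abs(np.asarray(r1_only_output) - np.asarray(lsci)))
    return float(a + b)


def landmark_error(landmarks: LandmarkSet,
                   field: DeformationField | np.ndarray) -> dict:
    """Euclidean distances between transported LSCI landmarks and RGB partners.

    The field follows the warp convention (ϕ sampled at target coordinates,
    pointing to the source), so a landmark at LSCI position p_l is carried
    by the warp to the registered-frame position p solving p + ϕ(p) = p_l —
    exactly where the image content at p_l ends up.  That position is found
    by fixed-point inversion and compared with the RGB partner; distances
    are reported per class and overall.
    """
    if len(landmarks) == 0:
        raise ValidationError("empty landmark set")
    f = field.values if isinstance(field, DeformationField) else np.asarray(field)
    moved = tps.invert_at_points(f, landmarks.lsci_points)
    dists = np.linalg.norm(moved - landmarks.rgb_points, axis=1)
    report = {"overall": float(dists.mean())}
    for cls in ("object", "interior", "background"):
        sel = [i for i, c in enumerate(landmarks.classes) if c == cls]
        if sel:
            report[cls] = float(dists[sel].mean())
    return report


def deformation_heatmap(field: DeformationField | np.ndarray) -> np.ndarray:
    """Displacement magnitude normalised to [0, 1] (zero field -> black)."""
    f = field.values if isinstance(field, DeformationField) else np.asarray(field)
    mag = np.sqrt(f[0] ** 2 + f[1] ** 2)
    top = mag.max()
    return mag / top if top > 0 else mag


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_lsci3(lsci: np.ndarray) -> np.ndarray:
    return np.repeat(lsci[None, None], 3, axis=1)


def _gray(rgb: np.ndarray) -> np.ndarray:
    return rgb @ np.array([0.299, 0.587, 0.114])


def _check_finite(value: float, term: str) -> None:
    if not np.isfinite(value):
        raise DivergenceError(f"non-finite loss in term '{term}'")


def _make_specs(cfg: RegistrationTrainConfig, size: tuple) -> dict:
    h, w = size
    return {
        "G2": NetworkSpec(role="generator", enc_channels=list(cfg.gen_channels),
                          kernel_size=4, input_shape=(h, w, 3), in_channels=3,
                          out_channels=3, affine_bn=False, name="G2"),
        "D2": NetworkSpec(role="discriminator",
                          enc_channels=list(cfg.disc_channels),
                          kernel_size=4, input_shape=(h, w, 6), in_channels=6,
                          out_channels=1, affine_bn=False, name="D2"),
        "R1": NetworkSpec(role="registration",
                          enc_channels=list(cfg.reg_channels),
                          kernel_size=3, input_shape=(h, w, 6), in_channels=6,
                          out_channels=2, affine_bn=False,
                          n_res_blocks=cfg.n_res_blocks,
                          control_grid=cfg.control_grid,
                          max_disp=cfg.max_disp, name="R1"),
    }


def train_registration(pairs: list,
                       weights: RegistrationLossWeights | None = None,
                       config: RegistrationTrainConfig | None = None
                       ) -> ModelBundle:
    """Jointly train G2, D2 and R1 on RGB/LSCI pairs (batch size 1).

    ``pairs`` is a sequence of ``(rgb, lsci, landmarks-or-None)`` with rgb
    (H, W, 3) and lsci (H, W), both already normalised to [−1, 1].  Early
    stopping monitors the mean landmark error when landmarks are present,
    otherwise the plateau of L_recon.  Returns a trained ModelBundle whose
    ``history`` holds every loss term per epoch.
    """
    weights = weights or RegistrationLossWeights()
    config = config or RegistrationTrainConfig()
    if len(pairs) < 2:
        raise ValidationError("need at least 2 RGB/LSCI pairs")
    size = pairs[0][0].shape[:2]
    rng = np.random.default_rng(config.seed)
    specs = _make_specs(config, size)
    g2 = build(specs["G2"], seed=config.seed + 1)
    d2 = build(specs["D2"], seed=config.seed + 2)
    r1 = build(specs["R1"], seed=config.seed + 3)
    opt_g = Adam(g2.parameters(), lr=config.lr, betas=(config.beta1, 0.999))
    opt_r = Adam(r1.parameters(), lr=config.lr, betas=(config.beta1, 0.999))
    opt_d = Adam(d2.parameters(), lr=config.lr, betas=(config.beta1, 0.999))

    guides = [bilateral_weights(_gray(p[0]), config.sigma_spatial,
                                config.sigma_range) for p in pairs]
    have_landmarks = all(p[2] is not None and len(p[2]) > 0 for p in pairs)

    history: dict = {k: [] for k in ("d_loss", "g_adv", "recon", "smooth",
                                     "anti", "total", "val")}
    best_val, best_state, stale = np.inf, None, 0
    lam_r, lam_s, lam_a = weights.lambda_r, weights.lambda_s, weights.lambda_a

    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        sums = dict.fromkeys(("d_loss", "g_adv", "recon", "smooth", "anti",
                              "total"), 0.0)
        for idx in order:
            rgb, lsci, _ = pairs[idx]
            t_rgb = Tensor(rgb.transpose(2, 0, 1)[None])
            t_lsci3 = Tensor(_to_lsci3(lsci))
            pair6 = F.concat([t_rgb, t_lsci3], axis=1)

            field = r1(pair6)
            o_r1 = F.warp_bilinear(t_lsci3, field)     # warp alone
            o_r1g2 = g2(o_r1)                          # R1 then G2
            o_g2 = g2(t_lsci3)                         # translate alone
            o_g2_for_warp = Tensor(o_g2.data) \
                if config.detach_translator_in_warp_path else o_g2
            o_g2r1 = F.warp_bilinear(o_g2_for_warp, field)  # G2 then R1

            # -- discriminator update
            d2.zero_grad()
            d_real = F.bce_with_logits(d2(F.concat([t_rgb, t_lsci3], 1)), 1.0)
            d_f1 = F.bce_with_logits(
                d2(F.concat([Tensor(o_r1g2.data), t_lsci3], 1)), 0.0)
            d_f2 = F.bce_with_logits(
                d2(F.concat([Tensor(o_g2r1.data), t_lsci3], 1)), 0.0)
            d_loss = d_real + 0.5 * (d_f1 + d_f2)
            _check_finite(d_loss.item(), "LcGAN(D2)")
            d_loss.backward()
            opt_d.step()

            # -- generator + registration update (non-saturating)
            opt_g.zero_grad()
            opt_r.zero_grad()
            g_adv = 0.5 * (
                F.bce_with_logits(d2(F.concat([o_r1g2, t_lsci3], 1)), 1.0)
                + F.bce_with_logits(d2(F.concat([o_g2r1, t_lsci3], 1)), 1.0))
            recon = F.l1_loss(o_r1g2, t_rgb) + F.l1_loss(o_g2r1, t_rgb)
            smooth = _loss_smooth_t(field, guides[idx])
            anti = F.l1_loss(o_g2, t_rgb) + F.l1_loss(o_r1, t_lsci3)
            total = g_adv + lam_r * recon + lam_s * smooth + lam_a * anti
            for name, term in (("LcGAN(G)", g_adv), ("Lrecon", recon),
                               ("Lsmooth", smooth), ("Lanti", anti)):
                _check_finite(term.item(), name)
            total.backward()
            opt_g.step()
            if epoch >= config.warmup_epochs:
                opt_r.step()

            sums["d_loss"] += d_loss.item()
            sums["g_adv"] += g_adv.item()
            sums["recon"] += recon.item()
            sums["smooth"] += smooth.item()
            sums["anti"] += anti.item()
            sums["total"] += total.item()
        for k, v in sums.items():
            history[k].append(v / len(pairs))

        # -- validation for early stopping
        if have_landmarks:
            val = np.mean([
                landmark_error(p[2], _predict_field(r1, p[0], p[1]))["overall"]
                for p in pairs])
        else:
            val = history["recon"][-1]
        history["val"].append(float(val))
        if val < best_val - config.min_delta:
            best_val, stale = val, 0
            best_state = {"G2": g2.state_dict(), "D2": d2.state_dict(),
                          "R1": r1.state_dict()}
        else:
            stale += 1
        if (config.early_stopping and stale >= config.patience
                and epoch + 1 >= config.min_epochs):
            break

    if best_state is not None:
        g2.load_state_dict(best_state["G2"])
        d2.load_state_dict(best_state["D2"])
        r1.load_state_dict(best_state["R1"])
    for m in (g2, d2, r1):
        m.eval()
    return ModelBundle(models={"G2": g2, "D2": d2, "R1": r1}, specs=specs,
                       train_config={"weights": vars(weights),
                                     "epochs_run": len(history["total"]),
                                     "lr": config.lr},
                       seed=config.seed, trained=True, history=history)


def _predict_field(r1, rgb: np.ndarray, lsci: np.ndarray) -> np.ndarray:
    r1.eval()
    with no_grad():
        pair6 = Tensor(np.concatenate(
            [rgb.transpose(2, 0, 1)[None], _to_lsci3(lsci)], axis=1))
        field = r1(pair6).data[0]
    r1.train()
    return field


def register_pair(bundle: ModelBundle, rgb: np.ndarray,
                  lsci: np.ndarray) -> tuple:
    """Warp an LSCI image onto its RGB partner's frame (LSCI→RGB only)."""
    bundle.require_trained()
    if "R1" not in bundle.models:
        raise StateError("bundle has no registration network")
    r1 = bundle.models["R1"]
    r1.eval()
    with no_grad():
        pair6 = Tensor(np.concatenate(
            [rgb.transpose(2, 0, 1)[None], _to_lsci3(lsci)], axis=1))
        field = r1(pair6).data[0]
    warped = warp(lsci, field)
    return warped, DeformationField(field)
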