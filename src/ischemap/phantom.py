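"""Synthetic paired RGB / flow / speckle phantoms with known ground truth.

Every downstream stage of the pipeline is exercised on these scenes in
lieu of in-vivo intraoperative recordings.  A scene consists of:

* an RGB image: serosa-toned tissue blob with a darker branching vessel
  tree, on a towel-colored background;
* a relative flow map: baseline parenchyma perfusion, elevated flow along
  vessels, zero off-tissue, with an optional ischemic lesion (core
  attenuation plus a smooth transition ramp);
* a raw speckle stack whose local contrast encodes the flow map through
  K = 1/√(1 + c·flow) (gamma intensity model: a gamma variate of shape k
  has σ/μ = 1/√k, which reproduces the speckle-contrast statistic without
  simulating coherent optics), globally modulated frame-by-frame by a
  multi-sinusoid factor bounded by ±10% to emulate physiological motion;
* a known smooth thin-plate-spline misalignment of the speckle/LSCI channel
  against the RGB channel, stored as the exact *alignment* field (the
  displacement that warps the misaligned LSCI back onto the RGB frame);
* 7–9 landmark pairs (object outline / interior vessel / background).

The lesion deliberately leaves the RGB channel untouched: early ischemia is
assumed invisible to color inspection, which is precisely the premise the
anomaly detector is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ischemap import tps
from ischemap.errors import ValidationError
from ischemap.lsci import SpeckleStack, compute_spatial_contrast

SEROSA = np.array([0.80, 0.55, 0.50])
VESSEL_TINT = np.array([0.35, 0.08, 0.10])
TOWEL = np.array([0.16, 0.22, 0.45])
FLOW_BASELINE = 1.0
FLOW_VESSEL_BOOST = 2.5
FLOW_CAPILLARY_BOOST = 0.5
FLOW_COUPLING = 5.0   # c in K_target = 1/sqrt(1 + c * flow)


@dataclass
class LesionSpec:
    center: tuple | None = None        # (row, col); None = auto placement
    radius: float = 0.0                # px; 0 disables the lesion
    severity: float = 0.8              # fraction of flow removed in the core
    transition_width: float = 6.0      # px, smooth ramp core -> background


@dataclass
class PhantomConfig:
    size: tuple = (256, 256)
    n_vessels: int = 3
    lesion: LesionSpec = dc_field(default_factory=LesionSpec)
    n_frames: int = 128
    motion_amplitude: float = 0.10
    warp_magnitude: float = 0.0        # max control-point displacement, px
    warp_grid: tuple = (4, 4)
    seed: int = 0
    flow_coupling: float = FLOW_COUPLING
    contrast_window: int = 5

    def __post_init__(self):
        h, w = self.size
        if h < 64 or w < 64:
            raise ValidationError("phantom size must be at least 64x64")
        if not 0.0 <= self.lesion.severity <= 1.0:
            raise ValidationError("lesion severity must lie in [0, 1]")
        if not 0.0 <= self.motion_amplitude <= 0.10:
            raise ValidationError("motion_amplitude must lie in [0, 0.10]")
        if self.lesion.radius > min(h, w) / 2:
            raise ValidationError("lesion radius larger than the image")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


@dataclass
class LandmarkSet:
    classes: list                      # 'object' | 'interior' | 'background'
    rgb_points: np.ndarray             # (N, 2) row/col
    lsci_points: np.ndarray            # (N, 2) row/col

    def __len__(self):
        return len(self.classes)

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class,row_rgb,col_rgb,row_lsci,col_lsci\n")
            for cls, rp, lp in zip(self.classes, self.rgb_points,
                                   self.lsci_points):
                fh.write(f"{cls},{rp[0]:.4f},{rp[1]:.4f},"
                         f"{lp[0]:.4f},{lp[1]:.4f}\n")

    @classmethod
    def load_csv(cls, path) -> "LandmarkSet":
        rows = np.genfromtxt(path, delimiter=",", names=True,
                             dtype=None, encoding="utf-8")
        rows = np.atleast_1d(rows)
        return cls(classes=[str(r["class"]) for r in rows],
                   rgb_points=np.stack(
                       [[r["row_rgb"], r["col_rgb"]] for r in rows]),
                   lsci_points=np.stack(
                       [[r["row_lsci"], r["col_lsci"]] for r in rows]))


@dataclass
class PhantomScene:
    rgb: np.ndarray                    # (H, W, 3) in [0, 1]
    flow_map: np.ndarray               # (H, W), aligned (RGB-frame) flow
    lesion_mask: np.ndarray            # (H, W) bool, lesion core
    transition_mask: np.ndarray        # (H, W) bool, smooth ramp band
    tissue_mask: np.ndarray            # (H, W) bool ground truth
    speckle: SpeckleStack              # in the (possibly misaligned) LSCI frame
    lsci: np.ndarray                   # frame-averaged contrast image K
    warp_truth: np.ndarray             # (2, H, W) alignment field (zeros if none)
    landmarks: LandmarkSet
    config: PhantomConfig
    albedo: np.ndarray | None = None   # (H, W) NIR reflectance, aligned frame


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _tissue_ellipse(shape, rng) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    ay = (0.40 + rng.uniform(-0.02, 0.02)) * h
    ax = (0.44 + rng.uniform(-0.02, 0.02)) * w
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _draw_vessels(shape, tissue, n_vessels, rng, radius=None,
                  branch_prob=0.045):
    """Biased branching random walks; returns (intensity map, branch points)."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    branch_points = []
    radius = radius if radius is not None else min(h, w) // 96
    ys, xs = np.nonzero(tissue)
    cy, cx = ys.mean(), xs.mean()

    def walk(start, direction, length, depth):
        pos = np.array(start, dtype=float)
        d = np.array(direction, dtype=float)
        d /= np.linalg.norm(d) + 1e-12
        for step in range(length):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w) or not tissue[r, c]:
                break
            rr = slice(max(0, r - radius), min(h, r + radius + 1))
            cc = slice(max(0, c - radius), min(w, c + radius + 1))
            canvas[rr, cc] = True
            d += rng.normal(0.0, 0.25, size=2)
            d /= np.linalg.norm(d) + 1e-12
            pos += d * 1.5
            if depth < 2 and step > 6 and rng.random() < branch_prob:
                branch_points.append((pos[0], pos[1]))
                perp = np.array([-d[1], d[0]]) * rng.choice([-1.0, 1.0])
                walk(pos.copy(), 0.6 * d + 0.8 * perp,
                     int(length * 0.5), depth + 1)

    for _ in range(n_vessels):
        theta = rng.uniform(0, 2 * np.pi)
        start = (cy + 0.30 * h * np.sin(theta), cx + 0.34 * w * np.cos(theta))
        # aim across the tissue at a random interior point, so trees spread
        # over the organ instead of converging on the centroid
        aim = (cy + rng.uniform(-0.22, 0.22) * h,
               cx + rng.uniform(-0.22, 0.22) * w)
        walk(start, (aim[0] - start[0], aim[1] - start[1]),
             int(1.2 * min(h, w)), 0)
    # two renderings of the same tree: a tight one for the flow map (the
    # lumen carrying blood) and a broader one for the RGB appearance (the
    # vessel wall and its shadow read wider than the lumen)
    flow_render = ndimage.gaussian_filter(canvas.astype(float),
                                          sigma=max(0.6, min(h, w) / 160))
    flow_render = np.clip(flow_render / max(flow_render.max(), 1e-9), 0, 1)
    rgb_render = ndimage.gaussian_filter(canvas.astype(float),
                                         sigma=max(1.1, min(h, w) / 80))
    rgb_render = np.clip(rgb_render / max(rgb_render.max(), 1e-9), 0, 1)
    return flow_render * tissue, rgb_render * tissue, branch_points


def _draw_capillaries(shape, tissue, rng, n_walks):
    """Fine secondary network: short thin walks from random tissue points."""
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    ys, xs = np.nonzero(tissue)
    if len(ys) == 0:
        return canvas.astype(float)
    for _ in range(n_walks):
        i = rng.integers(len(ys))
        pos = np.array([float(ys[i]), float(xs[i])])
        d = rng.normal(0.0, 1.0, size=2)
        d /= np.linalg.norm(d) + 1e-12
        for _ in range(int(0.35 * min(h, w))):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < h and 0 <= c < w) or not tissue[r, c]:
                break
            canvas[r, c] = True
            d += rng.normal(0.0, 0.5, size=2)
            d /= np.linalg.norm(d) + 1e-12
            pos += d * 1.3
    blur = ndimage.gaussian_filter(canvas.astype(float), sigma=0.7)
    top = blur.max()
    return np.clip(blur / top, 0.0, 1.0) * tissue if top > 0 else blur


def _background_texture(shape, rng) -> np.ndarray:
    """Towel fold pattern in [0, 1]: oriented stripes plus smooth mottle."""
    h, w = shape
    theta = rng.uniform(0, np.pi)
    period = min(h, w) / rng.uniform(4.0, 7.0)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    t = rr * np.sin(theta) + cc * np.cos(theta)
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * t / period
                                 + rng.uniform(0, 2 * np.pi))
    mottle = ndimage.gaussian_filter(rng.normal(0, 1, size=shape),
                                     sigma=min(h, w) / 16)
    mottle = 0.5 + 0.5 * mottle / (np.abs(mottle).max() + 1e-9)
    return np.clip(0.6 * stripes + 0.4 * mottle, 0.0, 1.0)


def apply_ischemia(flow_map: np.ndarray, lesion_mask: np.ndarray,
                   severity: float, transition_width: float) -> np.ndarray:
    """Attenuate flow in the lesion core with a smooth monotone ramp outward.

    Core flow is multiplied by (1 - severity); a smoothstep ramp of width
    ``transition_width`` px blends the attenuation to zero, so along any ray
    from the core to the background the flow is monotone nondecreasing.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValidationError("severity must lie in [0, 1]")
    if transition_width < 0:
        raise ValidationError("transition_width must be nonnegative")
    flow = np.asarray(flow_map, dtype=np.float64)
    mask = np.asarray(lesion_mask, dtype=bool)
    if severity == 0.0 or not mask.any():
        return flow.copy()
    dist = ndimage.distance_transform_edt(~mask)
    if transition_width > 0:
        t = np.clip(1.0 - dist / transition_width, 0.0, 1.0)
        ramp = t * t * (3.0 - 2.0 * t)      # smoothstep, monotone
    else:
        ramp = (dist == 0).astype(float)
    return flow * (1.0 - severity * ramp)


def synthesize_speckle(flow_map: np.ndarray, n_frames: int,
                       motion_amplitude: float, seed: int,
                       coupling: float = FLOW_COUPLING,
                       mean_intensity: float | np.ndarray = 1.0
                       ) -> SpeckleStack:
    """Raw speckle frames whose local contrast encodes the flow map.

    Per pixel, intensities are gamma variates with shape k = 1 + c·flow so
    the expected contrast is K = 1/√k = 1/√(1 + c·flow); zero flow gives
    fully developed speckle (K = 1).  ``mean_intensity`` may be a scalar or
    an (H, W) NIR albedo map: per-pixel temporal statistics are unaffected
    (K is intensity-normalised) but albedo *edges* inflate spatial-window
    contrast, which is how static structure — towel folds, the tissue
    outline, vessel walls — shows up in real contrast images.  Frames are
    globally modulated by a three-component sinusoid bounded by
    ±``motion_amplitude``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    flow = np.asarray(flow_map, dtype=np.float64)
    if np.any(flow < 0):
        raise ValidationError("flow must be nonnegative")
    rng = np.random.default_rng(seed)
    shape_k = 1.0 + coupling * flow
    scale = mean_intensity / shape_k
    frames = rng.gamma(shape_k[None, :, :],
                       scale[None, :, :],
                       size=(n_frames, *flow.shape))
    if motion_amplitude > 0 and n_frames > 1:
        t = np.arange(n_frames, dtype=np.float64)
        s = np.zeros(n_frames)
        for _ in range(3):
            freq = rng.uniform(0.3, 3.0)          # cycles over the record
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.4, 1.0)
            s += amp * np.sin(2 * np.pi * freq * t / n_frames + phase)
        s /= np.max(np.abs(s)) + 1e-12
        frames *= (1.0 + motion_amplitude * s)[:, None, None]
    return SpeckleStack(frames)


def _average_contrast(stack: SpeckleStack, window: int) -> np.ndarray:
    acc = np.zeros(stack.shape)
    for f in stack.frames:
        acc += compute_spatial_contrast(f, window).values
    return acc / stack.n_frames


def _sample_landmarks(tissue, branch_points, rng, shape, saliency=None):
    h, w = shape
    total = int(rng.integers(7, 10))             # 7..9 pairs per scene
    n_background = int(rng.integers(0, 3))
    n_fore = total - n_background
    n_object = n_fore // 2 + n_fore % 2
    n_interior = n_fore - n_object
    eroded = ndimage.binary_erosion(tissue, iterations=2)
    outline = tissue & ~eroded
    oy, ox = np.nonzero(outline)
    idx = rng.choice(len(oy), size=n_object, replace=False)
    pts = [("object", (float(oy[i]), float(ox[i]))) for i in idx]
    if branch_points:
        bsel = rng.choice(len(branch_points),
                          size=min(n_interior, len(branch_points)),
                          replace=False)
        pts += [("interior", branch_points[i]) for i in bsel]
        n_interior -= len(bsel)
    if n_interior > 0:                            # fall back to vessel pixels
        iy, ix = np.nonzero(eroded)
        idx = rng.choice(len(iy), size=n_interior, replace=False)
        pts += [("interior", (float(iy[i]), float(ix[i]))) for i in idx]
    # background annotations sit on salient towel features (fold edges),
    # as real annotators pick clamps and towel creases, not blank cloth
    bg = ~ndimage.binary_dilation(tissue, iterations=3)
    if saliency is not None:
        grad = np.hypot(*np.gradient(saliency))
        cand = bg & (grad > np.quantile(grad[bg], 0.8))
        if not cand.any():
            cand = bg
    else:
        cand = bg
    by, bx = np.nonzero(cand)
    if n_background and len(by):
        idx = rng.choice(len(by), size=n_background, replace=False)
        pts += [("background", (float(by[i]), float(bx[i]))) for i in idx]
    classes = [c for c, _ in pts]
    coords = np.array([p for _, p in pts], dtype=np.float64)
    coords[:, 0] = np.clip(coords[:, 0], 0, h - 1)
    coords[:, 1] = np.clip(coords[:, 1], 0, w - 1)
    return LandmarkSet(classes, coords, coords.copy())


def generate_scene(config: PhantomConfig) -> PhantomScene:
    """Deterministically build a full phantom scene from its config."""
    rng = np.random.default_rng(config.seed)
    h, w = config.size

    tissue = _tissue_ellipse(config.size, rng)
    vessels, vessels_rgb, branch_points = _draw_vessels(
        config.size, tissue, config.n_vessels, rng)
    fine = _draw_capillaries(config.size, tissue, rng,
                             n_walks=6 * config.n_vessels + 8)

    # RGB: serosa tone with low-frequency shading; the primary vessel tree
    # is strongly darkened, the capillary network faintly — the same
    # anatomy that structures the flow map, so the two modalities share
    # morphological detail at every scale (as real serosa/mesentery does)
    shading = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)),
                                      sigma=min(h, w) / 8)
    shading = 1.0 + 0.08 * shading / (np.abs(shading).max() + 1e-9)
    dark = np.clip(0.62 * vessels_rgb + 0.28 * fine, 0.0, 0.8)
    folds = _background_texture(config.size, rng)   # towel fold pattern
    rgb = np.empty((h, w, 3))
    for ch in range(3):
        base = TOWEL[ch] * (0.75 + 0.5 * folds) \
            + 0.02 * rng.normal(0, 1, size=(h, w))
        fg = SEROSA[ch] * shading * (1.0 - dark) + VESSEL_TINT[ch] * dark
        rgb[..., ch] = np.where(tissue, fg, base)
    rgb = np.clip(rgb, 0.0, 1.0)

    # NIR albedo: the same fold/vessel structure seen by the speckle camera
    albedo = np.where(tissue, 1.0 - 0.25 * vessels_rgb,
                      0.45 + 0.35 * folds)

    # flow: parenchyma baseline + vessel/capillary boost, zero off-tissue
    flow = (FLOW_BASELINE + FLOW_VESSEL_BOOST * vessels
            + FLOW_CAPILLARY_BOOST * fine) * tissue

    # lesion
    lesion = config.lesion
    if lesion.radius > 0 and lesion.severity > 0:
        center = lesion.center or (0.55 * h, 0.46 * w)
        rr, cc = np.mgrid[0:h, 0:w]
        dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
        core = (dist <= lesion.radius) & tissue
        ring = (dist <= lesion.radius + lesion.transition_width) & tissue & ~core
        flow = apply_ischemia(flow, core, lesion.severity,
                              lesion.transition_width)
    else:
        core = np.zeros((h, w), dtype=bool)
        ring = np.zeros((h, w), dtype=bool)

    # misalignment of the LSCI channel (generative warp psi; the stored
    # truth is the exact alignment field phi with phi(p) = psi^-1(p) - p)
    if config.warp_magnitude > 0:
        psi = tps.random_tps_field(config.size, config.warp_magnitude,
                                   np.random.default_rng(config.seed + 101),
                                   grid=config.warp_grid)
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        grid_pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        inv_pts = tps.invert_at_points(psi, grid_pts)
        warp_truth = (inv_pts - grid_pts).T.reshape(2, h, w)
        flow_lsci = _warp_scalar(flow, psi)
        albedo_lsci = _warp_scalar(albedo, psi)
    else:
        psi = None
        warp_truth = np.zeros((2, h, w))
        flow_lsci = flow
        albedo_lsci = albedo

    speckle = synthesize_speckle(flow_lsci, config.n_frames,
                                 config.motion_amplitude,
                                 seed=config.seed + 7,
                                 coupling=config.flow_coupling,
                                 mean_intensity=albedo_lsci)
    lsci = _average_contrast(speckle, config.contrast_window)

    landmarks = _sample_landmarks(tissue, branch_points, rng, config.size,
                                  saliency=albedo)
    if psi is not None:
        landmarks.lsci_points = tps.invert_at_points(psi, landmarks.rgb_points)

    return PhantomScene(rgb=rgb, flow_map=flow, lesion_mask=core,
                        transition_mask=ring, tissue_mask=tissue,
                        speckle=speckle, lsci=lsci, warp_truth=warp_truth,
                        landmarks=landmarks, config=config, albedo=albedo)


def _warp_scalar(image: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Sample ``image`` at p + psi(p) with bilinear interpolation."""
    h, w = image.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = np.stack([(rr + psi[0]).ravel(), (cc + psi[1]).ravel()], axis=1)
    return _bilinear(image, pts).reshape(h, w)


def _bilinear(image: np.ndarray, pts: np.ndarray) -> np.ndarray:
    h, w = image.shape
    r = np.clip(pts[:, 0], 0, h - 1)
    c = np.clip(pts[:, 1], 0, w - 1)
    r0 = np.minimum(np.floor(r), h - 2).astype(int)
    c0 = np.minimum(np.floor(c), w - 2).astype(int)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * image[r0, c0]
            + (1 - fr) * fc * image[r0, c0 + 1]
            + fr * (1 - fc) * image[r0 + 1, c0]
            + fr * fc * image[r0 + 1, c0 + 1])


def misalign(scene: PhantomScene, warp_magnitude: float,
             seed: int) -> PhantomScene:
    """Apply a fresh random TPS misalignment to the LSCI channel only.

    The speckle stack is re-synthesized from the warped flow map (so its
    contrast statistics stay exact rather than being smoothed by
    interpolation), the exact alignment field is stored in ``warp_truth``,
    and LSCI-side landmark coordinates are transported accordingly.
    """
    if warp_magnitude < 0:
        raise ValidationError("warp_magnitude must be nonnegative")
    cfg = scene.config
    h, w = cfg.size
    albedo = scene.albedo if scene.albedo is not None else np.ones((h, w))
    if warp_magnitude == 0:
        psi = np.zeros((2, h, w))
        warp_truth = np.zeros((2, h, w))
        flow_lsci = scene.flow_map
        albedo_lsci = albedo
        lsci_pts = scene.landmarks.rgb_points.copy()
    else:
        psi = tps.random_tps_field(cfg.size, warp_magnitude,
                                   np.random.default_rng(seed),
                                   grid=cfg.warp_grid)
        rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
        grid_pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        inv_pts = tps.invert_at_points(psi, grid_pts)
        warp_truth = (inv_pts - grid_pts).T.reshape(2, h, w)
        flow_lsci = _warp_scalar(scene.flow_map, psi)
        albedo_lsci = _warp_scalar(albedo, psi)
        lsci_pts = tps.invert_at_points(psi, scene.landmarks.rgb_points)
    speckle = synthesize_speckle(flow_lsci, cfg.n_frames,
                                 cfg.motion_amplitude, seed=cfg.seed + 7,
                                 coupling=cfg.flow_coupling,
                                 mean_intensity=albedo_lsci)
    lsci = _average_contrast(speckle, cfg.contrast_window)
    landmarks = LandmarkSet(list(scene.landmarks.classes),
                            scene.landmarks.rgb_points.copy(), lsci_pts)
    return PhantomScene(rgb=scene.rgb, flow_map=scene.flow_map,
                        lesion_mask=scene.lesion_mask,
                        transition_mask=scene.transition_mask,
                        tissue_mask=scene.tissue_mask, speckle=speckle,
                        lsci=lsci, warp_truth=warp_truth,
                        landmarks=landmarks, config=cfg, albedo=scene.albedo)


# ---------------------------------------------------------------------------
# scene I/O
# ---------------------------------------------------------------------------

def save_scene(scene: PhantomScene, directory) -> None:
    import imageio.v3 as iio
    import tifffile

    d = Path(directory)
    (d / "speckle").mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / "rgb.png", (scene.rgb * 255).astype(np.uint8))
    tifffile.imwrite(d / "lsci.tiff", scene.lsci.astype(np.float32))
    tifffile.imwrite(d / "flow.tiff", scene.flow_map.astype(np.float32))
    iio.imwrite(d / "lesion_mask.png",
                (scene.lesion_mask * 255).astype(np.uint8))
    iio.imwrite(d / "tissue_mask.png",
                (scene.tissue_mask * 255).astype(np.uint8))
    for i, frame in enumerate(scene.speckle.frames):
        tifffile.imwrite(d / "speckle" / f"frame_{i:04d}.tiff",
                         frame.astype(np.float32))
    np.savez(d / "warp.npz", warp_truth=scene.warp_truth)
    scene.landmarks.save_csv(d / "landmarks.csv")
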