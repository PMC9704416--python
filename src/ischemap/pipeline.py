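"""End-to-end orchestration: simulate → contrast → preprocess → register →
detect → evaluate, as one reproducible run with a manifest.

A single master seed fans out to per-stage seeds by fixed offsets so stages
have independent but reproducible random streams.  Each stage writes into
its own subdirectory of the run directory and registers every artifact in
``manifest.json`` together with the config hash, library versions and
per-stage wall time.  Disabling registration gives the no-registration
ablation path: the detector then consumes the misaligned LSCI directly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from ischemap import anomaly, evaluation, phantom, preprocessing, registration
from ischemap.errors import ValidationError

SCHEMA_VERSION = 1
STAGE_SEED_OFFSETS = {"simulate": 0, "register": 1000, "detect": 2000,
                      "evaluate": 3000}


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # phantom conditions
    size: tuple = (64, 64)
    n_train: int = 8
    n_test: int = 4
    n_frames: int = 32
    motion_amplitude: float = 0.10
    warp_magnitude: float = 4.0
    lesion_radius: float = 10.0
    lesion_severity: float = 0.8
    transition_width: float = 4.0
    contrast_window: int = 5
    # stage toggles
    registration_enabled: bool = True
    # training (defaults follow the published settings)
    reg_epochs: int = 300
    lambda_r: float = 150.0
    lambda_s: float = 130.0
    lambda_a: float = -2.0
    det_epochs: int = 40
    lambda_recon: float = 100.0
    lr_registration: float = 0.001
    lr_detection: float = 0.0002
    closing_radius: int = 2
    threshold: float = 0.10
    schema: int = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "size" in raw:
            raw["size"] = tuple(raw["size"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _normalized_pair(scene):
    """([-1,1] RGB, [-1,1] LSCI) for one scene; LSCI sign-flipped to flow
    orientation (bright = perfused) before normalization."""
    rgb = preprocessing.normalize(scene.rgb).values
    lsci = preprocessing.normalize(-scene.lsci).values
    return rgb, lsci


def _lib_versions() -> dict:
    import scipy
    import skimage

    import ischemap

    return {"ischemap": ischemap.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every enabled stage in order; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"schema": SCHEMA_VERSION, "config": asdict(config),
                "config_hash": config.digest(),
                "seeds": {k: config.seed + v
                          for k, v in STAGE_SEED_OFFSETS.items()},
                "library_versions": _lib_versions(),
                "registration_enabled": config.registration_enabled,
                "stages": {}, "artifacts": []}

    def record(stage, t0, paths):
        manifest["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3)}
        manifest["artifacts"] += [str(p.relative_to(run_dir)) for p in paths]

    import tifffile

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    sim_seed = config.seed + STAGE_SEED_OFFSETS["simulate"]
    lesion_off = phantom.LesionSpec(radius=0.0, severity=0.0)
    lesion_on = phantom.LesionSpec(radius=config.lesion_radius,
                                   severity=config.lesion_severity,
                                   transition_width=config.transition_width)

    def make(seed, lesion):
        return phantom.generate_scene(phantom.PhantomConfig(
            size=config.size, lesion=lesion, n_frames=config.n_frames,
            motion_amplitude=config.motion_amplitude,
            warp_magnitude=config.warp_magnitude,
            contrast_window=config.contrast_window, seed=seed))

    train_scenes = [make(sim_seed + i, lesion_off)
                    for i in range(config.n_train)]
    test_scenes = [make(sim_seed + 500 + i, lesion_on)
                   for i in range(config.n_test)]
    sim_dir = run_dir / "simulate"
    paths = []
    for group, scenes in (("train", train_scenes), ("test", test_scenes)):
        for i, sc in enumerate(scenes):
            d = sim_dir / f"{group}_{i:03d}"
            d.mkdir(parents=True, exist_ok=True)
            import imageio.v3 as iio

            iio.imwrite(d / "rgb.png", (sc.rgb * 255).astype(np.uint8))
            sc.landmarks.save_csv(d / "landmarks.csv")
            paths += [d / "rgb.png", d / "landmarks.csv"]
    record("simulate", t0, paths)

    # ---- contrast -------------------------------------------------------
    t0 = time.time()
    con_dir = run_dir / "contrast"
    con_dir.mkdir(exist_ok=True)
    paths = []
    for group, scenes in (("train", train_scenes), ("test", test_scenes)):
        for i, sc in enumerate(scenes):
            p = con_dir / f"{group}_{i:03d}_lsci.tiff"
            tifffile.imwrite(p, sc.lsci.astype(np.float32))
            paths.append(p)
    record("contrast", t0, paths)

    # ---- preprocess -----------------------------------------------------
    t0 = time.time()
    pre_dir = run_dir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    train_pairs = [_normalized_pair(sc) for sc in train_scenes]
    test_pairs = [_normalized_pair(sc) for sc in test_scenes]
    p = pre_dir / "pairs.npz"
    np.savez(p,
             train_rgb=np.stack([a for a, _ in train_pairs]),
             train_lsci=np.stack([b for _, b in train_pairs]),
             test_rgb=np.stack([a for a, _ in test_pairs]),
             test_lsci=np.stack([b for _, b in test_pairs]))
    record("preprocess", t0, [p])

    # ---- register -------------------------------------------------------
    t0 = time.time()
    reg_dir = run_dir / "register"
    reg_dir.mkdir(exist_ok=True)
    paths = []
    reg_bundle = None
    if config.registration_enabled:
        reg_pairs = [(r, l, sc.landmarks)
                     for (r, l), sc in zip(train_pairs, train_scenes)]
        reg_bundle = registration.train_registration(
            reg_pairs,
            registration.RegistrationLossWeights(config.lambda_r,
                                                 config.lambda_s,
                                                 config.lambda_a),
            registration.RegistrationTrainConfig(
                epochs=config.reg_epochs, lr=config.lr_registration,
                seed=config.seed + STAGE_SEED_OFFSETS["register"]))
        bpath = reg_dir / "registration_bundle.zip"
        reg_bundle.save(bpath)
        hist = reg_dir / "loss_history.csv"
        _write_history_csv(hist, reg_bundle.history)
        paths += [bpath, hist]
        import imageio.v3 as iio

        for i, (r, l) in enumerate(test_pairs):
            _, fld = registration.register_pair(reg_bundle, r, l)
            hm = registration.deformation_heatmap(fld)
            hp = reg_dir / f"test_{i:03d}_heatmap.png"
            iio.imwrite(hp, (hm * 255).astype(np.uint8))
            paths.append(hp)
    record("register", t0, paths)

    # ---- detect ---------------------------------------------------------
    t0 = time.time()
    det_dir = run_dir / "detect"
    det_dir.mkdir(exist_ok=True)

    def aligned(pairs):
        if reg_bundle is None:
            return pairs
        out = []
        for r, l in pairs:
            wl, _ = registration.register_pair(reg_bundle, r, l)
            out.append((r, wl))
        return out

    det_bundle = anomaly.train_healthy_model(
        aligned(train_pairs), config.lambda_recon,
        anomaly.AnomalyTrainConfig(
            epochs=config.det_epochs, lr=config.lr_detection,
            seed=config.seed + STAGE_SEED_OFFSETS["detect"]))
    bpath = det_dir / "detector_bundle.zip"
    det_bundle.save(bpath)
    paths = [bpath]
    prob_maps = []
    import imageio.v3 as iio

    for i, ((r, l), sc) in enumerate(zip(aligned(test_pairs), test_scenes)):
        y_hat = anomaly.reconstruct(det_bundle, r)
        res = anomaly.residual(l, y_hat)
        mask = preprocessing.TissueMask(sc.tissue_mask, method="phantom")
        prob = anomaly.postprocess(res, mask, config.closing_radius)
        prob_maps.append(prob)
        pm = det_dir / f"test_{i:03d}_prob.tiff"
        tifffile.imwrite(pm, prob.values.astype(np.float32))
        mk = det_dir / f"test_{i:03d}_mask.png"
        iio.imwrite(mk, (anomaly.threshold_mask(prob, config.threshold)
                         * 255).astype(np.uint8))
        paths += [pm, mk]
    record("detect", t0, paths)

    # ---- evaluate -------------------------------------------------------
    t0 = time.time()
    ev_dir = run_dir / "evaluate"
    ev_dir.mkdir(exist_ok=True)
    rows = []
    for i, (prob, sc) in enumerate(zip(prob_maps, test_scenes)):
        gt = np.zeros(sc.lesion_mask.shape, dtype=np.int8)
        gt[sc.lesion_mask] = evaluation.LABEL_ABNORMAL
        gt[sc.transition_mask] = evaluation.LABEL_BUFFER
        window = _lesion_window(sc)
        pred = anomaly.threshold_mask(prob, config.threshold)
        counts = evaluation.confusion(pred, gt, window)
        rep = evaluation.metrics(counts)
        rep.auc = evaluation.auc(prob.values, gt, window)
        rows.append({"scene": i, **asdict(rep)})
    mpath = ev_dir / "metrics.json"
    mpath.write_text(json.dumps(rows, indent=2))
    cpath = ev_dir / "metrics.csv"
    with open(cpath, "w") as fh:
        keys = list(rows[0].keys())
        fh.write(",".join(keys) + "\n")
        for row in rows:
            fh.write(",".join(str(row[k]) for k in keys) + "\n")
    record("evaluate", t0, [mpath, cpath])

    manifest_path = run_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return run_dir


def _lesion_window(scene) -> tuple:
    """Evaluation window: the lesion+ramp bounding box padded to include a
    normal margin, clipped to the image."""
    h, w = scene.lesion_mask.shape
    region = scene.lesion_mask | scene.transition_mask
    if not region.any():
        return (0, h, 0, w)
    ys, xs = np.nonzero(region)
    pad = max(4, (ys.max() - ys.min()) // 2)
    return (max(0, ys.min() - pad), min(h, ys.max() + pad + 1),
            max(0, xs.min() - pad), min(w, xs.max() + pad + 1))


def _write_history_csv(path, history: dict) -> None:
    keys = list(history.keys())
    n = max(len(v) for v in history.values()) if history else 0
    with open(path, "w") as fh:
        fh.write("epoch," + ",".join(keys) + "\n")
        for i in range(n):
            row = [str(history[k][i]) if i < len(history[k]) else ""
                   for k in keys]
            fh.write(f"{i}," + ",".join(row) + "\n")
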