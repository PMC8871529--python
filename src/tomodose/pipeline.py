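"""End-to-end study orchestration.

One configured run covers: phantom construction per thickness, noiseless
forward projection, noisy realizations at the reference and reduced dose
levels, the three processing arms (without pre-reconstruction processing,
MSBF, pix2pix), Ram-Lak FBP of every arm, in-focus image-quality metrics
against the reference-dose reconstruction, and the statistical comparison
of the FWHM measurements.  All randomness derives from a single master
seed; a manifest records seeds and outputs per stage.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .acquisition import (
    DOSE_FACTORS,
    AcquisitionGeometry,
    DoseLevel,
    ProjectionSet,
    apply_dose_noise,
    forward_project,
    make_geometry,
    to_attenuation_norm,
)
from .cgan import PairedDataset, TrainConfig, denoise, select_epoch, train
from .fbp import ReconVolume, reconstruct
from .metrics import (
    RoiSpec,
    background_rois,
    cnr,
    extract_profile,
    fwhm,
    mssim,
    psnr,
)
from .msbf import MsbfParams, msbf_projections
from .phantom import PhantomSpec, PhantomVolume, build_phantom
from .stats import GroupedMeasurements, tukey_kramer, two_way_anova

ARMS = ("without", "msbf", "pix2pix")


@dataclass
class ExperimentConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    thicknesses_mm: tuple[float, ...] = (40.0,)
    dose_labels: tuple[str, ...] = ("reduce50", "reduce75")
    arms: tuple[str, ...] = ARMS
    train: TrainConfig = field(default_factory=TrainConfig)
    n_train_pairs: int = 64
    i0: float = 1e5
    electronic_sigma: float = 5.0
    max_att: float = 4.0
    msbf: MsbfParams = field(default_factory=MsbfParams)
    sum_width: int = 4
    bg_gap_mm: float = 1.5  # guard band between mass edge and background ROIs
    out_dir: str | None = None
    master_seed: int = 0
    save_images: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms {sorted(unknown)}")

    def geometry_for(self, spec: PhantomSpec) -> AcquisitionGeometry:
        """Detector grid covered by the phantom at every view angle.

        The detector is trimmed along the sweep axis by the lateral travel
        of the oblique rays through the full phantom thickness, so no
        projection contains unattenuated (air) regions.
        """
        nz, ny, nx = spec.grid_shape
        pitch = spec.voxel_mm
        arc = 15.0
        mx = int(np.ceil(spec.thickness_mm * np.tan(np.deg2rad(arc / 2)) / pitch)) + 4
        my = 5  # cone divergence across rows is sub-millimetre
        return make_geometry(
            detector_rows=ny - 2 * my,
            detector_cols=nx - 2 * mx,
            pixel_pitch_mm=pitch,
            slice_heights_mm=(spec.feature_depth_mm,),
        )


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (below 2**31) from the master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def noisy_normalized(
    noiseless: ProjectionSet,
    dose: DoseLevel,
    seed: int,
    electronic_sigma: float,
    max_att: float,
) -> ProjectionSet:
    noisy = apply_dose_noise(noiseless, dose, electronic_sigma, seed)
    return to_attenuation_norm(noisy, max_att=max_att)


def make_training_dataset(
    noiseless: ProjectionSet,
    dose_factor: float,
    n_pairs: int,
    patch_px: int,
    seed: int,
    electronic_sigma: float,
    max_att: float,
) -> tuple[PairedDataset, tuple[np.ndarray, np.ndarray]]:
    """Paired low/reference-dose patches from independent noise realizations.

    Patches are sampled uniformly over views and positions.  The returned
    validation pair is the full zero-degree view (low, reference).
    """
    seeds = derive_seeds(seed, 3)
    low_full = noisy_normalized(
        noiseless, DoseLevel("low", dose_factor), seeds[0], electronic_sigma, max_att
    )
    ref_full = noisy_normalized(
        noiseless, DoseLevel("reference", 1.0), seeds[1], electronic_sigma, max_att
    )
    rng = np.random.default_rng(seeds[2])
    n_views, H, W = low_full.images.shape
    if H < patch_px or W < patch_px:
        raise ValueError("projections smaller than the training patch")
    pairs = []
    for _ in range(n_pairs):
        v = int(rng.integers(n_views))
        r = int(rng.integers(H - patch_px + 1))
        c = int(rng.integers(W - patch_px + 1))
        pairs.append(
            (
                low_full.images[v, r : r + patch_px, c : c + patch_px].copy(),
                ref_full.images[v, r : r + patch_px, c : c + patch_px].copy(),
            )
        )
    center = n_views // 2
    val_pair = (low_full.images[center].copy(), ref_full.images[center].copy())
    return PairedDataset(pairs), val_pair


def measure_arm(
    recon: ReconVolume,
    recon_ref: ReconVolume,
    vol: PhantomVolume,
    arm: str,
    dose_label: str,
    thickness_mm: float,
    sum_width: int = 4,
    bg_gap_mm: float = 1.5,
) -> list[dict]:
    """Tidy metric rows for one arm's in-focus reconstruction."""
    rows: list[dict] = []
    z = vol.registry[0].center_mm[2] if vol.registry else recon.slice_heights_mm[0]
    sl = recon.slice_at(z)
    sl_ref = recon_ref.slice_at(z)
    pitch = recon.pixel_pitch_at(z)

    base = {"arm": arm, "dose": dose_label, "thickness_mm": thickness_mm}
    if arm != "reference":
        rows.append({**base, "target": "slice", "direction": "", "metric": "psnr",
                     "value": psnr(sl_ref, sl)})
        rows.append({**base, "target": "slice", "direction": "", "metric": "mssim",
                     "value": mssim(_rescale01(sl_ref), _rescale01(sl))})

    for rec in vol.registry:
        r, c = recon.index_of_xy(rec.center_mm[0], rec.center_mm[1], z)
        if rec.kind == "mc":
            for direction in ("horizontal", "vertical"):
                try:
                    prof = extract_profile(
                        sl, (r, c), direction, sum_width=sum_width,
                        half_len_px=max(int(round(1.6 / pitch)), 8),
                        pitch_mm=pitch,
                    )
                    val = fwhm(prof)
                except ValueError:
                    val = None
                rows.append(
                    {**base, "target": f"mc_{rec.size_mm}", "direction": direction,
                     "metric": "fwhm_mm",
                     "value": np.nan if val is None else val}
                )
        else:
            d_px = rec.size_mm / pitch
            gap_px = (rec.size_mm + bg_gap_mm) / pitch
            feature = RoiSpec((r, c), d_px, role="feature")
            try:
                val = cnr(sl, feature, background_rois(feature, gap_px))
            except ValueError:
                val = np.nan
            rows.append({**base, "target": f"mass_{rec.size_mm}", "direction": "",
                         "metric": "cnr", "value": val})
    return rows


def _rescale01(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured study; returns a results bundle.

    The bundle holds the tidy metrics table, the per-MC-size statistical
    tables, the trained epoch curves, and a manifest of seeds and stages.
    Configured outputs are also written under ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": cfg.master_seed,
        "config": _config_dict(cfg),
        "stages": [],
    }
    metric_rows: list[dict] = []
    curves: dict[str, pd.DataFrame] = {}

    for t_idx, thickness in enumerate(cfg.thicknesses_mm):
        stage = {"thickness_mm": thickness, "outputs": []}
        t0 = time.time()
        spec = dataclasses.replace(
            cfg.phantom, thickness_mm=thickness, seed=cfg.master_seed + t_idx
        )
        vol = build_phantom(spec)
        geom = cfg.geometry_for(spec)
        noiseless = forward_project(vol, geom, i0=cfg.i0)
        seeds = derive_seeds(cfg.master_seed + 1000 + t_idx, 2 + 2 * len(cfg.dose_labels))

        ref_proj = noisy_normalized(
            noiseless, DoseLevel("reference", 1.0), seeds[0],
            cfg.electronic_sigma, cfg.max_att,
        )
        recon_ref = reconstruct(ref_proj, geom.slice_heights_mm)
        metric_rows += measure_arm(
            recon_ref, recon_ref, vol, "reference", "reference", thickness,
            cfg.sum_width, cfg.bg_gap_mm,
        )
        if out_dir and cfg.save_images:
            p = out_dir / f"t{int(thickness)}_reference_recon.tif"
            tio.write_recon(p, recon_ref)
            stage["outputs"].append(str(p))

        for d_idx, dose_label in enumerate(cfg.dose_labels):
            dose = DoseLevel(dose_label, DOSE_FACTORS[dose_label])
            noise_seed = seeds[2 + 2 * d_idx]
            low_proj = noisy_normalized(
                noiseless, dose, noise_seed, cfg.electronic_sigma, cfg.max_att
            )

            arm_projections: dict[str, ProjectionSet] = {}
            if "without" in cfg.arms:
                arm_projections["without"] = low_proj
            if "msbf" in cfg.arms:
                arm_projections["msbf"] = msbf_projections(low_proj, cfg.msbf)
            if "pix2pix" in cfg.arms:
                train_seed = seeds[3 + 2 * d_idx]
                dataset, val_pair = make_training_dataset(
                    noiseless, dose.dose_factor, cfg.n_train_pairs,
                    cfg.train.patch_px, train_seed, cfg.electronic_sigma,
                    cfg.max_att,
                )
                tcfg = dataclasses.replace(cfg.train, seed=train_seed)
                ckpts, curve = train(dataset, tcfg, val_pair=val_pair)
                curves[f"t{int(thickness)}_{dose_label}"] = curve
                best = select_epoch(curve)
                ckpt = next(c for c in ckpts if c.epoch == best)
                arm_projections["pix2pix"] = denoise(low_proj, ckpt)
                if out_dir:
                    curve.to_csv(
                        out_dir / f"t{int(thickness)}_{dose_label}_epochs.csv",
                        index=False,
                    )

            for arm, proj in arm_projections.items():
                recon = reconstruct(proj, geom.slice_heights_mm)
                metric_rows += measure_arm(
                    recon, recon_ref, vol, arm, dose_label, thickness,
                    cfg.sum_width, cfg.bg_gap_mm,
                )
                if out_dir and cfg.save_images:
                    p = out_dir / f"t{int(thickness)}_{dose_label}_{arm}_recon.tif"
                    tio.write_recon(p, recon)
                    stage["outputs"].append(str(p))

        stage["n_projections"] = int(noiseless.n_views)
        stage["n_slices"] = len(geom.slice_heights_mm)
        stage["seconds"] = round(time.time() - t0, 2)
        stage["seeds"] = seeds
        manifest["stages"].append(stage)

    metrics = pd.DataFrame(metric_rows)
    stats_tables = compute_stats(metrics)

    if out_dir:
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        for name, table in stats_tables.items():
            table.to_csv(out_dir / f"stats_{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "metrics": metrics,
        "stats": stats_tables,
        "curves": curves,
        "manifest": manifest,
    }


def compute_stats(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Tukey-Kramer (4 groups) and two-way ANOVA per MC size, on FWHM."""
    tables: dict[str, pd.DataFrame] = {}
    fw = metrics[(metrics["metric"] == "fwhm_mm") & metrics["value"].notna()]
    for target in sorted(fw["target"].unique()):
        sub = fw[fw["target"] == target]
        counts = sub.groupby("arm")["value"].count()
        if len(counts) >= 2 and (counts >= 2).all():
            g = GroupedMeasurements(
                sub["value"].to_numpy(), sub["arm"].to_numpy(), sub["dose"].to_numpy()
            )
            try:
                tables[f"tukey_{target}"] = tukey_kramer(g)
            except ValueError:
                pass
            try:
                tables[f"anova_{target}"] = two_way_anova(g)
            except ValueError:
                pass
    return tables


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["msbf"]["w_alpha"] = np.asarray(d["msbf"]["w_alpha"]).tolist()
    return d
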