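"""Desk-scale study preset.

The full-resolution study (1280 x 2048 detector, 0.1 mm sampling, 300
training epochs on a GPU) is configurable but far too heavy for a
single-CPU run, so this module fixes one compact, fully specified
configuration used by the examples, the acceptance checks and the test
suite: a 40 mm phantom sampled at 0.2 mm on a 27.2 x 48.0 mm lateral
extent, a detector trimmed to the always-covered field of view
(126 x 178 pixels), 15 views over 15 degrees, all three MC sizes and both
masses on the mid-thickness feature plane, and a pix2pix denoiser trained
on 64 projection patch pairs of 64 x 64 pixels for 100 epochs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .acquisition import (
    DOSE_FACTORS,
    AcquisitionGeometry,
    DoseLevel,
    ProjectionSet,
    forward_project,
)
from .cgan import TrainConfig, UNetGenerator, denoise as cgan_denoise, select_epoch, train
from .fbp import ReconVolume, reconstruct
from .msbf import MsbfParams, msbf_projections
from .phantom import PhantomSpec, PhantomVolume, build_phantom
from .pipeline import (
    ExperimentConfig,
    derive_seeds,
    make_training_dataset,
    measure_arm,
    noisy_normalized,
)

# Reference-dose photon fluence per detector pixel per view.  Behind 40 mm
# of 50/50 tissue (mean attenuation ~2.5) this leaves ~160 detected quanta
# at the reference dose and ~80 at the half-dose level: visible quantum
# mottle, the regime the dose-reduction comparison is about.
I0 = 2e3
ELECTRONIC_SIGMA = 5.0
MAX_ATT = 4.0


def desk_phantom_spec(thickness_mm: float = 40.0, seed: int = 0) -> PhantomSpec:
    return PhantomSpec(
        thickness_mm=thickness_mm,
        voxel_mm=0.2,
        lateral_extent_mm=(27.2, 48.0),
        seed=seed,
    )


def desk_experiment_config(
    master_seed: int = 0,
    thicknesses_mm: tuple[float, ...] = (40.0,),
    dose_labels: tuple[str, ...] = ("reduce50",),
    arms: tuple[str, ...] = ("without", "msbf", "pix2pix"),
    epochs: int = 100,
    n_train_pairs: int = 64,
    out_dir: str | None = None,
) -> ExperimentConfig:
    return ExperimentConfig(
        phantom=desk_phantom_spec(seed=master_seed),
        thicknesses_mm=thicknesses_mm,
        dose_labels=dose_labels,
        arms=arms,
        train=TrainConfig(epochs=epochs, seed=master_seed),
        n_train_pairs=n_train_pairs,
        i0=I0,
        electronic_sigma=ELECTRONIC_SIGMA,
        max_att=MAX_ATT,
        out_dir=out_dir,
        master_seed=master_seed,
    )


@dataclasses.dataclass
class DeskBench:
    """Phantom, geometry and noiseless projections shared across trials."""

    spec: PhantomSpec
    vol: PhantomVolume
    geom: AcquisitionGeometry
    noiseless: ProjectionSet


def make_bench(seed: int = 0, thickness_mm: float = 40.0) -> DeskBench:
    spec = desk_phantom_spec(thickness_mm=thickness_mm, seed=seed)
    vol = build_phantom(spec)
    cfg = desk_experiment_config(master_seed=seed)
    geom = cfg.geometry_for(spec)
    noiseless = forward_project(vol, geom, i0=I0)
    return DeskBench(spec, vol, geom, noiseless)


def train_desk_denoiser(
    bench: DeskBench,
    dose_label: str = "reduce50",
    seed: int = 0,
    epochs: int = 100,
    n_pairs: int = 64,
):
    """Train the pix2pix arm on the bench; returns (generator, curve)."""
    dataset, val_pair = make_training_dataset(
        bench.noiseless,
        DOSE_FACTORS[dose_label],
        n_pairs,
        64,
        seed,
        ELECTRONIC_SIGMA,
        MAX_ATT,
    )
    cfg = TrainConfig(epochs=epochs, seed=seed)
    ckpts, curve = train(dataset, cfg, val_pair=val_pair)
    best = select_epoch(curve)
    ckpt = next(c for c in ckpts if c.epoch == best)
    return ckpt.build_generator(), curve


def arm_reconstructions(
    bench: DeskBench,
    dose_label: str,
    noise_seed: int,
    gen: UNetGenerator | None = None,
    arms: tuple[str, ...] = ("without", "msbf", "pix2pix"),
) -> tuple[dict[str, ReconVolume], ReconVolume]:
    """FBP reconstructions per processing arm plus the reference recon.

    The reference arm uses an independent noise realization at full dose;
    the low-dose arms share one realization at ``dose_label``.
    """
    seeds = derive_seeds(noise_seed, 2)
    ref_proj = noisy_normalized(
        bench.noiseless, DoseLevel("reference", 1.0), seeds[0], ELECTRONIC_SIGMA, MAX_ATT
    )
    low_proj = noisy_normalized(
        bench.noiseless,
        DoseLevel(dose_label, DOSE_FACTORS[dose_label]),
        seeds[1],
        ELECTRONIC_SIGMA,
        MAX_ATT,
    )
    heights = bench.geom.slice_heights_mm
    recon_ref = reconstruct(ref_proj, heights)
    recons: dict[str, ReconVolume] = {}
    for arm in arms:
        if arm == "without":
            proj = low_proj
        elif arm == "msbf":
            proj = msbf_projections(low_proj, MsbfParams())
        elif arm == "pix2pix":
            if gen is None:
                raise ValueError("pix2pix arm requires a trained generator")
            proj = cgan_denoise(low_proj, gen)
        else:
            raise ValueError(f"unknown arm {arm!r}")
        recons[arm] = reconstruct(proj, heights)
    return recons, recon_ref


def arm_metric_rows(
    bench: DeskBench,
    recons: dict[str, ReconVolume],
    recon_ref: ReconVolume,
    dose_label: str,
) -> list[dict]:
    # two summed lines at 0.2 mm sampling give the same 0.4 mm physical
    # swath as the four-line summation at full 0.1 mm resolution
    sw = 2
    rows = measure_arm(
        recon_ref, recon_ref, bench.vol, "reference", "reference",
        bench.spec.thickness_mm, sum_width=sw,
    )
    for arm, recon in recons.items():
        rows += measure_arm(
            recon, recon_ref, bench.vol, arm, dose_label, bench.spec.thickness_mm,
            sum_width=sw,
        )
    return rows
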