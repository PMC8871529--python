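"""Multi-page 32-bit float TIFF I/O with JSON sidecars.

Projection sets, phantom volumes and reconstruction stacks are written as
one TIFF page per view/slice; a ``<stem>.json`` sidecar next to the TIFF
carries geometry, dose, seed and registry metadata so a stage can be
re-run from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .acquisition import AcquisitionGeometry, ProjectionSet
from .fbp import ReconVolume
from .phantom import FeatureRecord, PhantomVolume


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _geometry_to_dict(g: AcquisitionGeometry) -> dict:
    return dataclasses.asdict(g)


def _geometry_from_dict(d: dict) -> AcquisitionGeometry:
    d = dict(d)
    d["slice_heights_mm"] = tuple(d.get("slice_heights_mm", ()))
    return AcquisitionGeometry(**d)


def write_projections(path, p: ProjectionSet) -> None:
    path = Path(path)
    tifffile.imwrite(path, p.images.astype(np.float32), photometric="minisblack")
    meta = {
        "kind": "projections",
        "domain": p.domain,
        "dose_factor": p.dose_factor,
        "i0": p.i0,
        "seed": p.seed,
        "arm": p.arm,
        "calib_max_att": p.calib_max_att,
        "geometry": _geometry_to_dict(p.geometry),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    meta = json.loads(_sidecar(path).read_text())
    return ProjectionSet(
        images=images.astype(np.float32),
        domain=meta["domain"],
        geometry=_geometry_from_dict(meta["geometry"]),
        dose_factor=meta["dose_factor"],
        i0=meta["i0"],
        seed=meta["seed"],
        arm=meta.get("arm", "without"),
        calib_max_att=meta.get("calib_max_att"),
    )


def write_phantom(path, vol: PhantomVolume) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.mu.astype(np.float32), photometric="minisblack")
    meta = {
        "kind": "phantom",
        "voxel_mm": vol.voxel_mm,
        "registry": [dataclasses.asdict(r) for r in vol.registry],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_phantom(path) -> PhantomVolume:
    path = Path(path)
    mu = tifffile.imread(path).astype(np.float32)
    meta = json.loads(_sidecar(path).read_text())
    registry = [
        FeatureRecord(r["kind"], tuple(r["center_mm"]), r["size_mm"], r["contrast"])
        for r in meta.get("registry", [])
    ]
    return PhantomVolume(mu, meta["voxel_mm"], registry)


def write_recon(path, vol: ReconVolume) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.slices.astype(np.float32), photometric="minisblack")
    meta = {
        "kind": "recon",
        "slice_heights_mm": list(vol.slice_heights_mm),
        "pixel_pitch_mm": vol.pixel_pitch_mm,
        "geometry": _geometry_to_dict(vol.geometry),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_recon(path) -> ReconVolume:
    path = Path(path)
    slices = tifffile.imread(path).astype(np.float32)
    if slices.ndim == 2:
        slices = slices[None]
    meta = json.loads(_sidecar(path).read_text())
    return ReconVolume(
        slices=slices,
        slice_heights_mm=tuple(meta["slice_heights_mm"]),
        pixel_pitch_mm=meta["pixel_pitch_mm"],
        geometry=_geometry_from_dict(meta["geometry"]),
    )
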