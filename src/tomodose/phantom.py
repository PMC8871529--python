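"""Voxelized BR3D-style digital breast phantom.

The physical phantom this module emulates is a stack of slabs whose
attenuation mimics a 50/50 glandular/adipose breast, with one target slab
containing calcium-carbonate microcalcification (MC) speck groups and
spheroidal epoxy masses.  Here the slab texture is a seeded, spatially
correlated Gaussian random field blended between the two tissue attenuation
coefficients, and features are inserted as partial-volume-weighted spheres
(or spheroids) with an attenuation increment over the local background.

Coordinate convention: right-handed, ``z`` is height above the detector
plane, the volume is stored as ``mu[iz, iy, ix]`` with voxel centers at
``(i + 0.5) * voxel_mm`` along each axis.  Laterally the volume is centered
on the detector center: ``x`` spans the tube-sweep (column) direction,
``y`` the row direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

ALLOWED_THICKNESSES_MM = (40.0, 50.0, 60.0)
MC_SIZES_MM = (0.196, 0.23, 0.29)
MASS_DIAMETERS_MM = (3.9, 4.7)

# Monoenergetic ~20 keV effective attenuation; the physical phantom's
# materials are specified by tissue equivalence, not by coefficient, so
# these are representative defaults and fully configurable.
MU_ADIPOSE_MM = 0.045
MU_GLANDULAR_MM = 0.080
MC_CONTRAST_MM = 0.60
MASS_CONTRAST_MM = 0.010


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom.

    ``target_slab_depth_mm`` is the height of the feature plane above the
    phantom bottom; ``None`` puts it mid-thickness.
    """

    thickness_mm: float = 40.0
    voxel_mm: float = 0.1
    lateral_extent_mm: tuple[float, float] = (25.6, 51.2)  # (y, x)
    glandular_fraction: float = 0.5
    texture_correlation_mm: float = 3.0
    mc_sizes_mm: tuple[float, ...] = MC_SIZES_MM
    mass_diameters_mm: tuple[float, ...] = MASS_DIAMETERS_MM
    target_slab_depth_mm: float | None = None
    margin_mm: float = 1.0
    seed: int = 0
    mu_adipose: float = MU_ADIPOSE_MM
    mu_glandular: float = MU_GLANDULAR_MM
    mc_contrast: float = MC_CONTRAST_MM
    mass_contrast: float = MASS_CONTRAST_MM
    mass_aspect_z: float = 1.0  # z semi-axis / lateral semi-axis of masses
    mc_group_spacing_mm: float = 2.5  # speck spacing inside a 5-speck cross

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if not any(np.isclose(self.thickness_mm, t) for t in ALLOWED_THICKNESSES_MM):
            raise ValueError(
                f"thickness_mm must be one of {ALLOWED_THICKNESSES_MM}, "
                f"got {self.thickness_mm}"
            )
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise ValueError("glandular_fraction must be in [0, 1]")
        if self.texture_correlation_mm <= 0:
            raise ValueError("texture_correlation_mm must be positive")
        if any(e <= 0 for e in self.lateral_extent_mm):
            raise ValueError("lateral_extent_mm must be positive")

    @property
    def feature_depth_mm(self) -> float:
        if self.target_slab_depth_mm is None:
            return self.thickness_mm / 2.0
        return self.target_slab_depth_mm

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nz = int(round(self.thickness_mm / self.voxel_mm))
        ny = int(round(self.lateral_extent_mm[0] / self.voxel_mm))
        nx = int(round(self.lateral_extent_mm[1] / self.voxel_mm))
        return nz, ny, nx


@dataclass(frozen=True)
class FeatureRecord:
    """Ground-truth record of one inserted feature.

    ``center_mm`` is ``(x, y, z)`` in the volume frame (x along tube sweep,
    y across it, z height above the phantom bottom).
    """

    kind: str  # {"mc", "mass"}
    center_mm: tuple[float, float, float]
    size_mm: float
    contrast: float

    def __post_init__(self) -> None:
        if self.kind not in ("mc", "mass"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass
class PhantomVolume:
    """Attenuation volume (mm^-1) plus the feature registry."""

    mu: np.ndarray  # (nz, ny, nx) float32
    voxel_mm: float
    registry: list[FeatureRecord] = field(default_factory=list)

    @property
    def thickness_mm(self) -> float:
        return self.mu.shape[0] * self.voxel_mm

    @property
    def lateral_extent_mm(self) -> tuple[float, float]:
        return (self.mu.shape[1] * self.voxel_mm, self.mu.shape[2] * self.voxel_mm)

    def copy(self) -> "PhantomVolume":
        return PhantomVolume(self.mu.copy(), self.voxel_mm, list(self.registry))

    def index_of_mm(self, center_mm: Sequence[float]) -> tuple[float, float, float]:
        """Fractional voxel index (iz, iy, ix) of an (x, y, z) position."""
        x, y, z = center_mm
        ey, ex = self.lateral_extent_mm
        return (
            z / self.voxel_mm - 0.5,
            (y + ey / 2.0) / self.voxel_mm - 0.5,
            (x + ex / 2.0) / self.voxel_mm - 0.5,
        )


def build_background(spec: PhantomSpec) -> PhantomVolume:
    """Generate the heterogeneous two-tissue background volume.

    A white Gaussian field is smoothed to ``texture_correlation_mm`` and
    mapped through a soft threshold to mixture weights ``w`` in [0, 1]; the
    threshold is bisected so the mean weight (volumetric glandular
    fraction) matches ``spec.glandular_fraction`` closely.  The attenuation
    is ``mu_a + (mu_g - mu_a) * w``.
    """
    if spec.voxel_mm > spec.texture_correlation_mm:
        raise ValueError(
            "voxel_mm exceeds texture_correlation_mm: texture unresolvable"
        )
    nz, ny, nx = spec.grid_shape
    gf = spec.glandular_fraction
    if gf in (0.0, 1.0):
        mu_val = spec.mu_adipose if gf == 0.0 else spec.mu_glandular
        mu = np.full((nz, ny, nx), mu_val, dtype=np.float32)
        return PhantomVolume(mu, spec.voxel_mm)

    rng = np.random.default_rng(spec.seed)
    fieldv = rng.standard_normal((nz, ny, nx))
    sigma_vox = spec.texture_correlation_mm / spec.voxel_mm / 2.0
    fieldv = ndimage.gaussian_filter(fieldv, sigma=sigma_vox, mode="reflect")
    fieldv -= fieldv.mean()
    fstd = fieldv.std()
    if fstd == 0:
        fstd = 1.0
    fieldv /= fstd

    soft = 1.0  # width of the blend band, in field std units

    def frac(thr: float) -> float:
        w = np.clip((fieldv - thr) / soft + 0.5, 0.0, 1.0)
        return float(w.mean())

    lo, hi = float(fieldv.min()) - 1.0, float(fieldv.max()) + 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) > gf:
            lo = mid
        else:
            hi = mid
    thr = 0.5 * (lo + hi)
    w = np.clip((fieldv - thr) / soft + 0.5, 0.0, 1.0)
    mu = (spec.mu_adipose + (spec.mu_glandular - spec.mu_adipose) * w).astype(
        np.float32
    )
    return PhantomVolume(mu, spec.voxel_mm)


def default_feature_layout(spec: PhantomSpec) -> list[FeatureRecord]:
    """Lay out the target-slab features on the feature plane.

    Each MC size gets a five-speck cross (center plus the four axial
    neighbors at ``mc_group_spacing_mm``); masses sit in a row below the MC
    groups.  Groups are spread along x, centered laterally.  Centers snap
    to voxel centers so sub-voxel specks are not arbitrarily split across
    voxel boundaries by layout phase.
    """
    ey, ex = spec.lateral_extent_mm
    d = spec.voxel_mm

    def snap(v_mm: float, offset_mm: float = 0.0) -> float:
        # nearest voxel-center coordinate (grid origin at -extent/2)
        return (np.floor((v_mm + offset_mm) / d) + 0.5) * d - offset_mm

    z = snap(spec.feature_depth_mm)
    records: list[FeatureRecord] = []

    n_groups = len(spec.mc_sizes_mm)
    if n_groups:
        xs = np.linspace(-ex / 2, ex / 2, n_groups + 2)[1:-1]
        s = spec.mc_group_spacing_mm
        # MC row kept well below the mass row so the masses' background
        # ROIs (offset by diameter + guard band) never cover a speck
        y0 = -ey / 4.0
        for size, xg in zip(spec.mc_sizes_mm, xs):
            for dx, dy in ((0, 0), (s, 0), (-s, 0), (0, s), (0, -s)):
                records.append(
                    FeatureRecord(
                        "mc",
                        (snap(xg + dx, ex / 2), snap(y0 + dy, ey / 2), z),
                        size,
                        spec.mc_contrast,
                    )
                )
    n_masses = len(spec.mass_diameters_mm)
    if n_masses:
        xs = np.linspace(-ex / 2, ex / 2, n_masses + 2)[1:-1]
        y1 = ey / 8.0
        for diam, xg in zip(spec.mass_diameters_mm, xs):
            records.append(
                FeatureRecord(
                    "mass", (snap(xg, ex / 2), snap(y1, ey / 2), z), diam,
                    spec.mass_contrast,
                )
            )
    return records


def _check_bounds(rec: FeatureRecord, spec: PhantomSpec) -> None:
    x, y, z = rec.center_mm
    r = rec.size_mm / 2.0
    ey, ex = spec.lateral_extent_mm
    m = spec.margin_mm
    if not (-ex / 2 + r + m <= x <= ex / 2 - r - m):
        raise ValueError(f"feature {rec} outside x bounds")
    if not (-ey / 2 + r + m <= y <= ey / 2 - r - m):
        raise ValueError(f"feature {rec} outside y bounds")
    if not (r <= z <= spec.thickness_mm - r):
        raise ValueError(f"feature {rec} outside z bounds")


def _check_overlaps(records: Sequence[FeatureRecord]) -> None:
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
            if d < (a.size_mm + b.size_mm) / 2.0:
                raise ValueError(f"overlapping features: {a} and {b}")


def _insert_spheroid(
    mu: np.ndarray,
    voxel_mm: float,
    center_idx: tuple[float, float, float],
    radius_vox: float,
    aspect_z: float,
    contrast: float,
    supersample: int,
) -> None:
    """Add ``contrast`` inside a spheroid with partial-volume boundary weights."""
    cz, cy, cx = center_idx
    rz = radius_vox * aspect_z
    z0, z1 = int(np.floor(cz - rz - 1)), int(np.ceil(cz + rz + 1))
    y0, y1 = int(np.floor(cy - radius_vox - 1)), int(np.ceil(cy + radius_vox + 1))
    x0, x1 = int(np.floor(cx - radius_vox - 1)), int(np.ceil(cx + radius_vox + 1))
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1 = min(z1, mu.shape[0] - 1)
    y1 = min(y1, mu.shape[1] - 1)
    x1 = min(x1, mu.shape[2] - 1)

    ss = supersample
    # sub-voxel sample offsets (centers of ss^3 sub-cells), relative to voxel center
    off = (np.arange(ss) + 0.5) / ss - 0.5
    zz = np.arange(z0, z1 + 1)
    yy = np.arange(y0, y1 + 1)
    xx = np.arange(x0, x1 + 1)
    # (nz, ss) sub-sample coordinates per axis, normalized by the semi-axis
    sz = ((zz[:, None] + off[None, :]) - cz) / rz
    sy = ((yy[:, None] + off[None, :]) - cy) / radius_vox
    sx = ((xx[:, None] + off[None, :]) - cx) / radius_vox
    inside = (
        sz[:, None, None, :, None, None] ** 2
        + sy[None, :, None, None, :, None] ** 2
        + sx[None, None, :, None, None, :] ** 2
    ) <= 1.0
    fraction = inside.reshape(len(zz), len(yy), len(xx), -1).mean(axis=3)
    mu[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] += (contrast * fraction).astype(
        mu.dtype
    )


def insert_features(
    vol: PhantomVolume,
    spec: PhantomSpec,
    records: Sequence[FeatureRecord] | None = None,
) -> PhantomVolume:
    """Insert MC specks and masses into a copy of ``vol``.

    Returns a new volume; ``vol`` is left untouched.  ``records=None`` uses
    the default layout derived from the spec.  Overlapping or out-of-bounds
    features raise ``ValueError`` naming the offenders.
    """
    if records is None:
        records = default_feature_layout(spec)
    out = vol.copy()
    if not records:
        return out
    for rec in records:
        _check_bounds(rec, spec)
    _check_overlaps(records)
    for rec in records:
        r_vox = rec.size_mm / 2.0 / vol.voxel_mm
        aspect = spec.mass_aspect_z if rec.kind == "mass" else 1.0
        ss = 8 if r_vox < 5.0 else 4
        _insert_spheroid(
            out.mu,
            vol.voxel_mm,
            out.index_of_mm(rec.center_mm),
            r_vox,
            aspect,
            rec.contrast,
            ss,
        )
        out.registry.append(rec)
    return out


def build_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Background plus default feature layout in one call."""
    return insert_features(build_background(spec), spec)
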