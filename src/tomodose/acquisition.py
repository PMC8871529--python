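"""Limited-angle tomosynthesis acquisition simulator.

Models a partial-isocentric sweep: the X-ray source travels on an arc
(default 15 views over 15 degrees, equally spaced and symmetric about the
vertical) about a pivot in the detector plane, while the detector stays
put.  Forward projection is a sampled Beer-Lambert line integral; quantum
noise is Poisson in the detected photon counts with an additive Gaussian
electronic term.  The dose level enters as a multiplicative factor on the
photon fluence, so halving the dose doubles the relative quantum mottle
variance.

Dose factors for the reduced levels default to the ratios of average
glandular dose between the reduced and reference exposures of a 40 mm
phantom (0.66/1.36 ~ 0.49 and 0.31/1.36 ~ 0.23).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .phantom import PhantomVolume

DOSE_FACTORS = {"reference": 1.0, "reduce50": 0.49, "reduce75": 0.23}

#: photon-equivalent floor for the log transform, avoids -ln(0)
LOG_EPS_PHOTONS = 1.0


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Source trajectory and detector grid.

    The detector lies in the plane ``z = 0`` with pixel (row, col) centers
    at ``((i - (R-1)/2) * pitch, (j - (C-1)/2) * pitch)`` in (y, x); the
    tube sweeps along x (the column axis).  At view angle ``theta`` the
    source sits at ``(SID sin(theta), 0, SID cos(theta))`` where SID is
    ``source_to_detector_mm`` (pivot in the detector plane).
    """

    n_views: int = 15
    arc_deg: float = 15.0
    source_to_detector_mm: float = 700.0
    source_pivot_height_mm: float = 0.0
    detector_rows: int = 256
    detector_cols: int = 512
    pixel_pitch_mm: float = 0.1
    slice_heights_mm: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.n_views == 1 and self.arc_deg != 0.0:
            raise ValueError("n_views=1 with a nonzero arc has undefined spacing")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.source_to_detector_mm <= 0:
            raise ValueError("source must be above the detector")

    @property
    def view_angles_deg(self) -> np.ndarray:
        if self.n_views == 1:
            return np.zeros(1)
        half = self.arc_deg / 2.0
        return np.linspace(-half, half, self.n_views)

    def source_position(self, angle_deg: float) -> np.ndarray:
        """Source (x, y, z) in mm for one view."""
        th = np.deg2rad(angle_deg)
        sid = self.source_to_detector_mm
        return np.array([sid * np.sin(th), 0.0, sid * np.cos(th)])

    def pixel_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Detector pixel center coordinates (y rows, x cols) in mm."""
        y = (np.arange(self.detector_rows) - (self.detector_rows - 1) / 2.0) * (
            self.pixel_pitch_mm
        )
        x = (np.arange(self.detector_cols) - (self.detector_cols - 1) / 2.0) * (
            self.pixel_pitch_mm
        )
        return y, x


def make_geometry(config: Mapping | None = None, **kwargs) -> AcquisitionGeometry:
    """Build a geometry from a mapping (e.g. parsed YAML) and/or kwargs."""
    params = dict(config or {})
    params.update(kwargs)
    if "slice_heights_mm" in params:
        params["slice_heights_mm"] = tuple(params["slice_heights_mm"])
    return AcquisitionGeometry(**params)


@dataclass(frozen=True)
class DoseLevel:
    label: str
    dose_factor: float

    def __post_init__(self) -> None:
        if self.dose_factor <= 0:
            raise ValueError("dose_factor must be positive")
        if self.label == "reference" and self.dose_factor != 1.0:
            raise ValueError("reference dose factor must be 1.0")


def dose_level(label: str) -> DoseLevel:
    return DoseLevel(label, DOSE_FACTORS[label])


@dataclass
class ProjectionSet:
    """Per-view detector images with domain and provenance tags.

    ``domain`` is ``"intensity"`` (photon counts) or ``"attenuation_norm"``
    (log-transformed, affinely rescaled to [0, 1]).
    """

    images: np.ndarray  # (n_views, rows, cols) float32
    domain: str
    geometry: AcquisitionGeometry
    dose_factor: float = 1.0
    i0: float | None = None
    seed: int | None = None
    arm: str = "without"
    calib_max_att: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("intensity", "attenuation_norm"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.images.ndim != 3:
            raise ValueError("images must be (n_views, rows, cols)")

    @property
    def n_views(self) -> int:
        return self.images.shape[0]

    def copy_with(self, **kwargs) -> "ProjectionSet":
        out = ProjectionSet(
            images=kwargs.pop("images", self.images.copy()),
            domain=kwargs.pop("domain", self.domain),
            geometry=self.geometry,
            dose_factor=kwargs.pop("dose_factor", self.dose_factor),
            i0=kwargs.pop("i0", self.i0),
            seed=kwargs.pop("seed", self.seed),
            arm=kwargs.pop("arm", self.arm),
            calib_max_att=kwargs.pop("calib_max_att", self.calib_max_att),
        )
        if kwargs:
            raise TypeError(f"unexpected fields {sorted(kwargs)}")
        return out


def _project_one_view(
    mu: np.ndarray,
    voxel_mm: float,
    geom: AcquisitionGeometry,
    angle_deg: float,
    z_offset_mm: float,
    row_chunk: int = 64,
) -> np.ndarray:
    """Sampled line integral of mu for every detector pixel of one view."""
    nz, ny, nx = mu.shape
    src = geom.source_position(angle_deg)
    ys, xs = geom.pixel_coords_mm()
    step = voxel_mm / 2.0
    z_lo, z_hi = z_offset_mm, z_offset_mm + nz * voxel_mm
    n_steps = max(int(np.ceil((z_hi - z_lo) / step)), 1)
    dz = (z_hi - z_lo) / n_steps
    z_samples = z_lo + (np.arange(n_steps) + 0.5) * dz  # midpoint rule
    # fraction of the way from detector (z=0) to source (z=src_z)
    t = z_samples / src[2]  # (n_steps,)

    ex, ey = nx * voxel_mm, ny * voxel_mm
    out = np.empty((geom.detector_rows, geom.detector_cols), dtype=np.float32)
    for r0 in range(0, geom.detector_rows, row_chunk):
        r1 = min(r0 + row_chunk, geom.detector_rows)
        yb = ys[r0:r1]
        sh = (len(yb), len(xs), n_steps)
        # point on ray: P + t * (S - P), broadcast to (rows, cols, n_steps)
        px = xs[None, :, None] + t[None, None, :] * (src[0] - xs[None, :, None])
        py = yb[:, None, None] + t[None, None, :] * (src[1] - yb[:, None, None])
        pz = z_samples[None, None, :]
        iz = (pz - z_offset_mm) / voxel_mm - 0.5
        iy = (py + ey / 2.0) / voxel_mm - 0.5
        ix = (px + ex / 2.0) / voxel_mm - 0.5
        coords = np.stack(
            [
                np.broadcast_to(iz, sh).ravel(),
                np.broadcast_to(iy, sh).ravel(),
                np.broadcast_to(ix, sh).ravel(),
            ]
        )
        vals = ndimage.map_coordinates(
            mu, coords, order=1, mode="grid-constant", cval=0.0
        ).reshape(sh)
        # chord length per unit z for each pixel's ray
        ray_len = np.sqrt(
            (src[0] - xs[None, :]) ** 2
            + (src[1] - yb[:, None]) ** 2
            + src[2] ** 2
        )
        ds = dz * ray_len / src[2]
        out[r0:r1] = (vals.sum(axis=2) * ds).astype(np.float32)
    return out


def forward_project(
    vol: PhantomVolume,
    geom: AcquisitionGeometry,
    i0: float = 1e5,
    z_offset_mm: float = 0.0,
) -> ProjectionSet:
    """Noiseless cone-beam forward projection, intensity domain.

    For each view and pixel the line integral of ``mu`` along the
    source-to-pixel ray is sampled at half-voxel steps with trilinear
    interpolation (rays missing the volume integrate to zero); the
    recorded intensity is ``i0 * exp(-integral)``.
    """
    line_integrals = np.stack(
        [
            _project_one_view(vol.mu, vol.voxel_mm, geom, ang, z_offset_mm)
            for ang in geom.view_angles_deg
        ]
    )
    images = (i0 * np.exp(-line_integrals)).astype(np.float32)
    return ProjectionSet(images=images, domain="intensity", geometry=geom, i0=i0)


def line_integrals(p: ProjectionSet) -> np.ndarray:
    """Recover noiseless line integrals from an intensity ProjectionSet."""
    return -np.log(np.maximum(p.images, 1e-30) / (p.dose_factor * p.i0))


def apply_dose_noise(
    p: ProjectionSet,
    dose: DoseLevel,
    electronic_sigma: float = 5.0,
    seed: int = 0,
) -> ProjectionSet:
    """Quantum (Poisson) + electronic (Gaussian) noise at a dose level.

    Each pixel becomes ``Poisson(dose_factor * I) + N(0, electronic_sigma^2)``,
    clipped at zero.  The result records the dose factor and seed.
    """
    if p.domain != "intensity":
        raise ValueError("apply_dose_noise expects an intensity-domain ProjectionSet")
    if dose.dose_factor <= 0:
        raise ValueError("dose_factor must be positive")
    rng = np.random.default_rng(seed)
    lam = dose.dose_factor * p.images.astype(np.float64)
    noisy = rng.poisson(lam).astype(np.float64)
    if electronic_sigma > 0:
        noisy += rng.normal(0.0, electronic_sigma, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None).astype(np.float32)
    return p.copy_with(images=noisy, dose_factor=dose.dose_factor, seed=seed)


def to_attenuation_norm(
    p: ProjectionSet, max_att: float = 4.0, eps: float = LOG_EPS_PHOTONS
) -> ProjectionSet:
    """Log-transform and rescale an intensity set to the [0, 1] domain.

    ``pixel -> -ln(max(I, eps) / (dose_factor * i0)) / max_att`` clipped to
    [0, 1].  The calibration constant ``max_att`` must be shared across all
    dose levels and arms of a study so images stay comparable.
    """
    if p.i0 is None:
        raise ValueError("i0 required for normalization")
    att = -np.log(np.maximum(p.images, eps) / (p.dose_factor * p.i0))
    out = np.clip(att / max_att, 0.0, 1.0).astype(np.float32)
    return p.copy_with(images=out, domain="attenuation_norm", calib_max_att=max_att)
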