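"""Filtered back projection for limited-angle tomosynthesis.

Projections are ramp-filtered with the band-limited Ramachandran-
Lakshminarayanan (Ram-Lak) kernel along the tube-travel axis, then
back-projected shift-and-add style: each reconstruction pixel at height z
is mapped through the view's cone geometry to a detector coordinate,
sampled with linear interpolation, and averaged over the views that see
it.  No apodization window is applied to the ramp by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionGeometry, ProjectionSet


@dataclass
class ReconVolume:
    """Stack of in-plane slices at the requested heights."""

    slices: np.ndarray  # (n_heights, rows, cols) float32
    slice_heights_mm: tuple[float, ...]
    pixel_pitch_mm: float
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if self.slices.shape[0] != len(self.slice_heights_mm):
            raise ValueError("one slice per requested height")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("non-finite values in reconstruction")

    def slice_at(self, height_mm: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(np.asarray(self.slice_heights_mm) - height_mm)))
        return self.slices[idx]

    def pixel_pitch_at(self, height_mm: float) -> float:
        """In-plane sample spacing of the slice at ``height_mm``."""
        sid = self.geometry.source_to_detector_mm
        return self.pixel_pitch_mm * (sid - height_mm) / sid

    def index_of_xy(self, x_mm: float, y_mm: float, height_mm: float) -> tuple[float, float]:
        """Fractional (row, col) index of a lateral position in a slice."""
        demag = self.pixel_pitch_at(height_mm)
        r = y_mm / demag + (self.slices.shape[1] - 1) / 2.0
        c = x_mm / demag + (self.slices.shape[2] - 1) / 2.0
        return r, c


def ramlak_kernel(n_taps: int, pitch_mm: float) -> np.ndarray:
    """Spatial taps of the band-limited ramp filter.

    ``h(0) = 1/(4 tau^2)``, ``h(n even) = 0``, ``h(n odd) = -1/(pi^2 n^2 tau^2)``
    with ``tau = pitch_mm``; ``n_taps`` must be odd.
    """
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd")
    tau = pitch_mm
    n = np.arange(n_taps) - n_taps // 2
    h = np.zeros(n_taps)
    h[n == 0] = 1.0 / (4.0 * tau * tau)
    odd = n % 2 != 0
    h[odd] = -1.0 / (np.pi**2 * n[odd].astype(float) ** 2 * tau * tau)
    return h


def _ramp_response(n_fft: int, pitch_mm: float) -> np.ndarray:
    """Frequency response of the ramp, from its periodized spatial kernel."""
    tau = pitch_mm
    n = np.fft.fftfreq(n_fft, d=1.0 / n_fft)  # 0, 1, ..., -1 tap offsets
    h = np.zeros(n_fft)
    h[0] = 1.0 / (4.0 * tau * tau)
    odd = np.abs(n.astype(int)) % 2 == 1
    h[odd] = -1.0 / (np.pi**2 * n[odd] ** 2 * tau * tau)
    H = np.real(np.fft.fft(h))
    H[0] = 0.0  # exact DC suppression
    return H


def filter_projection(
    image: np.ndarray, pitch_mm: float, window: str | None = None
) -> np.ndarray:
    """Ram-Lak filter one projection along the tube-travel (column) axis.

    Rows are edge-replicated to at least twice their length before the FFT
    multiplication: the circular convolution then acts linearly over the
    retained window, and a globally constant row maps to (numerically)
    zero since the periodized row carries only the suppressed DC.
    ``window="hann"`` apodizes the bare ramp (off by default).
    """
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[-1]
    # generous padding keeps the periodized kernel's truncated tail (and the
    # DC correction it forces) well below 1e-6 per tap
    n_fft = max(int(2 ** np.ceil(np.log2(2 * n))), 4096)
    pad_l = (n_fft - n) // 2
    pad_r = n_fft - n - pad_l
    padded = np.pad(image, [(0, 0)] * (image.ndim - 1) + [(pad_l, pad_r)], mode="edge")
    H = _ramp_response(n_fft, pitch_mm)
    if window == "hann":
        f = np.fft.fftfreq(n_fft)
        H = H * (0.5 + 0.5 * np.cos(2.0 * np.pi * f))
    elif window is not None:
        raise ValueError(f"unknown apodization window {window!r}")
    spec = np.fft.fft(padded, axis=-1)
    filtered = np.real(np.fft.ifft(spec * H, axis=-1))[..., pad_l : pad_l + n]
    return filtered


def filter_projections(p: ProjectionSet) -> ProjectionSet:
    """Ramp-filter every view, with the sampling-step scaling.

    The extra ``pitch_mm`` factor is the discrete line-integral scaling that
    keeps reconstruction amplitudes on the order of the projection values
    regardless of detector pitch.
    """
    if p.domain != "attenuation_norm":
        raise ValueError("filtering expects attenuation_norm projections")
    pitch = p.geometry.pixel_pitch_mm
    filt = np.stack(
        [filter_projection(im, pitch) * pitch for im in p.images]
    ).astype(np.float32)
    return p.copy_with(images=filt)


def backproject(
    p: ProjectionSet,
    geom: AcquisitionGeometry | None = None,
    slice_heights_mm=None,
) -> ReconVolume:
    """Shift-and-add back projection of filtered projections.

    The reconstruction grid at height z is the detector grid demagnified
    to the slice plane, so the zero-degree view maps onto it identically
    at z = 0.  Out-of-detector samples are excluded and the view average
    renormalized by the per-pixel hit count.
    """
    geom = geom or p.geometry
    heights = tuple(slice_heights_mm if slice_heights_mm is not None else geom.slice_heights_mm)
    if not heights:
        raise ValueError("no slice heights requested")
    sid = geom.source_to_detector_mm
    for z in heights:
        if not 0 <= z < sid:
            raise ValueError(f"slice height {z} outside source-detector gap")

    R, C = geom.detector_rows, geom.detector_cols
    pitch = geom.pixel_pitch_mm
    rows_out = (np.arange(R) - (R - 1) / 2.0)
    cols_out = (np.arange(C) - (C - 1) / 2.0)
    slices = np.zeros((len(heights), R, C), dtype=np.float64)

    for k, z in enumerate(heights):
        demag = (sid - z) / sid
        x_rec = cols_out * pitch * demag  # lateral position of recon pixels
        y_rec = rows_out * pitch * demag
        acc = np.zeros((R, C))
        hits = np.zeros((R, C))
        for ang, view in zip(geom.view_angles_deg, p.images):
            src = geom.source_position(ang)
            mag = src[2] / (src[2] - z)
            u = src[0] + (x_rec - src[0]) * mag  # detector x of each recon col
            v = (y_rec - src[1]) * mag + src[1]
            col_idx = u / pitch + (C - 1) / 2.0
            row_idx = v / pitch + (R - 1) / 2.0
            rr = np.broadcast_to(row_idx[:, None], (R, C))
            cc = np.broadcast_to(col_idx[None, :], (R, C))
            valid = (
                (rr >= 0) & (rr <= R - 1) & (cc >= 0) & (cc <= C - 1)
            )
            sampled = ndimage.map_coordinates(
                view.astype(np.float64),
                np.stack([rr.ravel(), cc.ravel()]),
                order=1,
                mode="constant",
                cval=0.0,
            ).reshape(R, C)
            acc += np.where(valid, sampled, 0.0)
            hits += valid
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(hits > 0, acc / np.maximum(hits, 1), 0.0)
        slices[k] = mean

    return ReconVolume(
        slices=slices.astype(np.float32),
        slice_heights_mm=heights,
        pixel_pitch_mm=pitch,
        geometry=geom,
    )


def reconstruct(p: ProjectionSet, slice_heights_mm) -> ReconVolume:
    """Filter + back-project in one call."""
    return backproject(filter_projections(p), p.geometry, slice_heights_mm)
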