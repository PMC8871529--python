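"""Image-quality metrics for the phantom study.

MSE/PSNR/SSIM compare an arm's reconstruction (or projection) against the
reference-dose counterpart; CNR measures mass contrast against four
surrounding background ROIs; FWHM of a summed intensity profile through a
microcalcification is the spatial-resolution surrogate.  All images are
single-precision floats nominally in [0, 1] (PV = 1.0 for PSNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

PSNR_PEAK_VALUE = 1.0


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, pv: float = PSNR_PEAK_VALUE) -> float:
    """10 log10(PV^2 / MSE) in dB; identical images give +inf."""
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(pv * pv / err))


def ssim_map(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> np.ndarray:
    """Per-pixel SSIM map (luminance * contrast * structure, unit exponents).

    Uses the original SSIM constants: 11x11 Gaussian window (sigma 1.5),
    C1 = (0.01 PV)^2, C2 = (0.03 PV)^2, C3 = C2/2.
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    _, smap = structural_similarity(
        a,
        b,
        data_range=data_range,
        gaussian_weights=True,
        sigma=1.5,
        win_size=11,
        use_sample_covariance=False,
        full=True,
    )
    return smap


def mssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean of the SSIM map over all pixels."""
    return float(ssim_map(a, b, data_range=data_range).mean())


@dataclass(frozen=True)
class RoiSpec:
    """Circular region of interest on a slice."""

    center: tuple[float, float]  # (row, col), fractional allowed
    diameter_px: float
    role: str = "feature"  # {"feature", "background"}
    shape: str = "circle"

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        r0, c0 = self.center
        rad = self.diameter_px / 2.0
        if (
            r0 - rad < -0.5
            or c0 - rad < -0.5
            or r0 + rad > image_shape[0] - 0.5
            or c0 + rad > image_shape[1] - 0.5
        ):
            raise ValueError(f"ROI {self} not fully inside image {image_shape}")
        rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad * rad


def background_rois(
    feature: RoiSpec, gap_px: float
) -> list[RoiSpec]:
    """Four background ROIs (up, down, left, right) around a feature ROI.

    Centers are offset from the feature center by ``gap_px`` (typically the
    mass diameter plus a guard band), same diameter as the feature ROI.
    """
    r0, c0 = feature.center
    d = feature.diameter_px
    offs = [(-gap_px, 0.0), (gap_px, 0.0), (0.0, -gap_px), (0.0, gap_px)]
    return [
        RoiSpec((r0 + dr, c0 + dc), d, role="background") for dr, dc in offs
    ]


def cnr(image: np.ndarray, feature: RoiSpec, backgrounds: list[RoiSpec]) -> float:
    """Contrast-to-noise ratio (mu_feature - mu_bg) / sigma_bg.

    ``mu_bg`` and ``sigma_bg`` are computed over the pooled pixels of the
    four background ROIs.
    """
    if len(backgrounds) != 4:
        raise ValueError("exactly 4 background ROIs required (up/down/left/right)")
    image = np.asarray(image, dtype=np.float64)
    feat_pix = image[feature.mask(image.shape)]
    bg_pix = np.concatenate([image[b.mask(image.shape)] for b in backgrounds])
    sigma_bg = float(bg_pix.std())
    if sigma_bg == 0.0:
        raise ValueError("degenerate background: sigma_bg = 0")
    return float((feat_pix.mean() - bg_pix.mean()) / sigma_bg)


@dataclass
class ProfileMeasurement:
    """A 1-D intensity profile through a feature plus its sample pitch."""

    direction: str  # {"vertical", "horizontal"}
    sum_width: int
    profile: np.ndarray
    pitch_mm: float
    center_index: float  # profile sample nearest the feature center

    def __post_init__(self) -> None:
        if self.direction not in ("vertical", "horizontal"):
            raise ValueError(f"unknown direction {self.direction!r}")


def extract_profile(
    image: np.ndarray,
    center: tuple[float, float],
    direction: str,
    sum_width: int = 4,
    half_len_px: int = 15,
    pitch_mm: float = 1.0,
    reduce: str = "sum",
) -> ProfileMeasurement:
    """Summed intensity profile through ``center``.

    ``horizontal`` runs along the tube-sweep (column) axis, ``vertical``
    along rows; ``sum_width`` adjacent lines perpendicular to the profile
    direction are summed (the four-line summation used for MC profiles).
    ``reduce="mean"`` averages the lines instead; the FWHM is identical
    either way.
    """
    if reduce not in ("sum", "mean"):
        raise ValueError(f"unknown reduce mode {reduce!r}")
    image = np.asarray(image, dtype=np.float64)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    w_lo = (sum_width - 1) // 2
    w_hi = sum_width - w_lo
    if direction == "horizontal":
        if (
            r0 - w_lo < 0
            or r0 + w_hi > image.shape[0]
            or c0 - half_len_px < 0
            or c0 + half_len_px >= image.shape[1]
        ):
            raise ValueError("profile window exits the image")
        block = image[r0 - w_lo : r0 + w_hi, c0 - half_len_px : c0 + half_len_px + 1]
        profile = block.mean(axis=0) if reduce == "mean" else block.sum(axis=0)
    else:
        if (
            c0 - w_lo < 0
            or c0 + w_hi > image.shape[1]
            or r0 - half_len_px < 0
            or r0 + half_len_px >= image.shape[0]
        ):
            raise ValueError("profile window exits the image")
        block = image[r0 - half_len_px : r0 + half_len_px + 1, c0 - w_lo : c0 + w_hi]
        profile = block.mean(axis=1) if reduce == "mean" else block.sum(axis=1)
    return ProfileMeasurement(
        direction=direction,
        sum_width=sum_width,
        profile=profile,
        pitch_mm=pitch_mm,
        center_index=float(half_len_px),
    )


def fwhm(
    p: ProfileMeasurement,
    pitch_mm: float | None = None,
    baseline: str = "tails",
) -> float | None:
    """Full width at half-maximum of the profile's dominant peak, in mm.

    Baseline is the mean of the outer 25% tails (``baseline="linear"``
    instead fits a line through the two tail means, tolerating a sloped
    background); half-maximum crossings are located by linear
    interpolation on either side of the peak.  Returns ``None`` when a
    crossing is missing (unmeasurable profile, recorded as a missing
    observation rather than an error).
    """
    pitch = pitch_mm if pitch_mm is not None else p.pitch_mm
    y = np.asarray(p.profile, dtype=np.float64)
    n = len(y)
    tail = max(int(round(0.25 * n / 2.0)), 1)  # per-side tail samples
    if baseline == "linear":
        left_m = float(y[:tail].mean())
        right_m = float(y[-tail:].mean())
        x0, x1 = (tail - 1) / 2.0, n - 1 - (tail - 1) / 2.0
        trend = left_m + (right_m - left_m) * (np.arange(n) - x0) / (x1 - x0)
        y = y - trend
        base_val = 0.0
    elif baseline == "tails":
        base_val = float(np.concatenate([y[:tail], y[-tail:]]).mean())
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    baseline = base_val
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= baseline:
        return None
    half = baseline + (peak - baseline) / 2.0

    left = None
    for i in range(peak_idx, 0, -1):
        if y[i - 1] <= half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = (i - 1) + frac
            break
    right = None
    for i in range(peak_idx, n - 1):
        if y[i + 1] <= half <= y[i]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return float((right - left) * pitch)
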