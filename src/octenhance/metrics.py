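"""Objective image-quality measures and paired pre/post statistics.

Covers the evaluation toolbox: the Immerkaer fast noise-variance
estimator, window-based SNR, SSIM, MAE, and the paired Student's t-test
used to compare per-image quality measures before and after enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage.metrics import structural_similarity

from .bscan import BScan
from .errors import DegenerateInputError, InputError

#: 3x3 second-difference mask (difference of two Laplacians); its response
#: vanishes on any locally planar image, isolating zero-mean noise.
IMMERKAER_MASK = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


def _pixels(img: BScan | np.ndarray) -> np.ndarray:
    if isinstance(img, BScan):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def immerkaer_noise(img: BScan | np.ndarray) -> float:
    """Estimate the sigma of additive zero-mean noise from one image.

    Convolves the interior with the 3x3 second-difference mask and scales
    the mean absolute response:

        sigma_hat = sqrt(pi/2) * sum |response| / (6 (W-2) (H-2))

    Exactly zero on constant and planar images (the mask annihilates
    affine intensity surfaces).
    """
    a = _pixels(img)
    h, w = a.shape
    if h < 3 or w < 3:
        raise InputError(f"image must be at least 3x3 for noise estimation, got {h}x{w}")
    resp = signal.convolve2d(a, IMMERKAER_MASK, mode="valid")
    return float(np.sqrt(np.pi / 2.0) * np.abs(resp).sum() / (6.0 * (w - 2) * (h - 2)))


@dataclass(frozen=True)
class WindowPair:
    """Rectangular signal and noise regions (half-open [start, stop) rows/cols)."""

    signal_rows: tuple[int, int]
    signal_cols: tuple[int, int]
    noise_rows: tuple[int, int]
    noise_cols: tuple[int, int]

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for name, (rows, cols) in (
            ("signal", (self.signal_rows, self.signal_cols)),
            ("noise", (self.noise_rows, self.noise_cols)),
        ):
            r0, r1 = rows
            c0, c1 = cols
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise InputError(f"{name} window {rows}x{cols} outside image {h}x{w}")
            if (r1 - r0) * (c1 - c0) < 16:
                raise InputError(f"{name} window has fewer than 16 pixels")
        if self._overlaps():
            raise InputError("signal and noise windows overlap")

    def _overlaps(self) -> bool:
        r_olap = (self.signal_rows[0] < self.noise_rows[1]
                  and self.noise_rows[0] < self.signal_rows[1])
        c_olap = (self.signal_cols[0] < self.noise_cols[1]
                  and self.noise_cols[0] < self.signal_cols[1])
        return r_olap and c_olap


def default_windows(img: BScan | np.ndarray, margin: int = 2) -> WindowPair:
    """Window placement for phantom-like scans: the noise window covers the
    top 20% of rows (vitreous, above the retina) and the signal window the
    rows of the brightest horizontal band below it."""
    a = _pixels(img)
    h, w = a.shape
    noise_rows = (0, max(h // 5, 2))
    row_means = a.mean(axis=1)
    lo = noise_rows[1] + margin
    r = lo + int(np.argmax(row_means[lo:]))
    half = 2
    r0 = max(r - half, lo)
    r1 = min(r + half + 1, h)
    return WindowPair(
        signal_rows=(r0, r1),
        signal_cols=(margin, w - margin),
        noise_rows=noise_rows,
        noise_cols=(margin, w - margin),
    )


def window_snr(img: BScan | np.ndarray, windows: WindowPair) -> float:
    """mean(signal window) / std(noise window).

    Scale-invariant: multiplying the image by c > 0 scales numerator and
    denominator alike.
    """
    a = _pixels(img)
    windows.validate(a.shape)
    sig = a[slice(*windows.signal_rows), slice(*windows.signal_cols)]
    noi = a[slice(*windows.noise_rows), slice(*windows.noise_cols)]
    sd = float(noi.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("noise window has zero variance")
    return float(sig.mean()) / sd


def ssim(a: BScan | np.ndarray, b: BScan | np.ndarray) -> float:
    """Mean local SSIM with an 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03, dynamic range 1.0."""
    x, y = _pixels(a), _pixels(b)
    if x.shape != y.shape:
        raise InputError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(
        structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


def mae(a: BScan | np.ndarray, b: BScan | np.ndarray) -> float:
    """Mean absolute pixel difference."""
    x, y = _pixels(a), _pixels(b)
    if x.shape != y.shape:
        raise InputError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).mean())


def paired_quality_stats(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Paired Student's t-test on before/after quality values.

    Returns (t statistic, two-sided p) with n-1 degrees of freedom.
    """
    x = np.asarray(before, dtype=np.float64)
    y = np.asarray(after, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("before/after must be equal-length 1-D sequences")
    if len(x) < 3:
        raise InputError(f"need at least 3 pairs, got {len(x)}")
    d = x - y
    if np.all(d == d[0]):
        raise DegenerateInputError("differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def quality_report(
    originals: Sequence[BScan],
    enhanced: Sequence[BScan],
    clean: Sequence[BScan] | None = None,
    windows: WindowPair | None = None,
) -> dict:
    """Per-image metrics plus paired pre/post statistics.

    Returns a dict with a tidy per-image DataFrame and a summary of the
    paired t-tests on noise estimates and (when windows are given) SNR.
    """
    if len(originals) != len(enhanced):
        raise InputError("originals and enhanced differ in length")
    if clean is not None and len(clean) != len(originals):
        raise InputError("clean set differs in length")
    rows = []
    for i, (o, e) in enumerate(zip(originals, enhanced)):
        row = {
            "image": i,
            "noise_original": immerkaer_noise(o),
            "noise_enhanced": immerkaer_noise(e),
        }
        if windows is not None:
            row["snr_original"] = window_snr(o, windows)
            row["snr_enhanced"] = window_snr(e, windows)
        if clean is not None:
            row["ssim_original"] = ssim(o, clean[i])
            row["ssim_enhanced"] = ssim(e, clean[i])
            row["mae_original"] = mae(o, clean[i])
            row["mae_enhanced"] = mae(e, clean[i])
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for metric in ("noise", "snr", "ssim", "mae"):
        pre_col, post_col = f"{metric}_original", f"{metric}_enhanced"
        if pre_col in table:
            summary[f"{metric}_original_mean"] = float(table[pre_col].mean())
            summary[f"{metric}_enhanced_mean"] = float(table[post_col].mean())
            try:
                t, p = paired_quality_stats(table[pre_col], table[post_col])
                summary[f"{metric}_t"] = t
                summary[f"{metric}_p"] = p
            except DegenerateInputError:
                pass
    return {"per_image": table, "summary": summary}
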