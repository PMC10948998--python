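"""AP expression profiles from single-frame FISH images.

A fixed-embryo image is reduced to a 1-D AP profile by averaging the middle
band of pixel rows (40 px by default) into 1 %EL bins, then subtracting the
lowest binned value found between 10 and 90 %EL as background. The embryo is
assumed oriented with its AP axis along the image x-axis, anterior left; an
optional two-point annotation remaps arbitrary orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FishProfile", "fish_profile", "background_subtract"]


@dataclass
class FishProfile:
    bin_centers: np.ndarray       # %EL, 100 bins of 1% by default
    raw_mean: np.ndarray
    corrected: np.ndarray | None = None
    background: float | None = None


def fish_profile(image: np.ndarray, band_px: int = 40, n_bins: int = 100,
                 ap_axis: tuple[tuple[float, float], tuple[float, float]] | None = None,
                 subtract: bool = True) -> FishProfile:
    """Binned AP intensity profile from the middle DV band of a FISH image.

    ``ap_axis`` optionally gives ((x_ant, y_ant), (x_post, y_post)) pixel
    coordinates of the anterior and posterior tips; pixels are projected
    onto that axis to obtain %EL. Without it, the image x extent is taken as
    0-100 %EL directly. Bins are half-open with the last bin closed, as in
    the live-imaging profiles.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("fish_profile expects a 2D grayscale image")
    h, w = image.shape
    if band_px > h:
        raise ValueError("band_px exceeds image height")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    top = (h - band_px) // 2
    band = image[top:top + band_px]

    yy, xx = np.mgrid[top:top + band_px, 0:w]
    if ap_axis is None:
        el = (xx + 0.5) / w * 100.0
    else:
        (xa, ya), (xp, yp) = ap_axis
        axis = np.array([xp - xa, yp - ya], dtype=float)
        norm2 = axis @ axis
        if norm2 == 0:
            raise ValueError("ap_axis endpoints coincide")
        el = (((xx - xa) * axis[0] + (yy - ya) * axis[1]) / norm2) * 100.0
    el = np.clip(el, 0.0, 100.0 - 1e-9)

    idx = np.clip((el / (100.0 / n_bins)).astype(int), 0, n_bins - 1).ravel()
    vals = band.ravel()
    count = np.bincount(idx, minlength=n_bins)
    total = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        raw = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * (100.0 / n_bins)
    prof = FishProfile(bin_centers=centers, raw_mean=raw)
    return background_subtract(prof) if subtract else prof


def background_subtract(profile: FishProfile,
                        el_range: tuple[float, float] = (10.0, 90.0)) -> FishProfile:
    """Subtract the lowest binned value whose center lies in 10-90 %EL.

    The corrected profile may go negative outside that range; that is the
    documented behaviour of the min-subtraction rule. Adding a constant to
    the whole image leaves the corrected profile unchanged.
    """
    lo, hi = el_range
    inside = (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    vals = profile.raw_mean[inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"no bins with centers in [{lo}, {hi}] %EL")
    bg = float(vals.min())
    return FishProfile(bin_centers=profile.bin_centers,
                       raw_mean=profile.raw_mean,
                       corrected=profile.raw_mean - bg,
                       background=bg)
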