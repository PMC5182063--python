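"""PALM image rendering for visual QC.

Localizations are accumulated in a 2D histogram, blurred with a Gaussian
whose width reflects the localization uncertainty (sigma = 15 nm by default),
normalized to [0, 1] and gamma-adjusted (gamma = 0.5 by default) to compress
the large dynamic range between dense clusters and single localizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .loc_data import LocalizationTable

__all__ = ["RenderSettings", "render_palm_image", "save_image"]


@dataclass(frozen=True)
class RenderSettings:
    pixel_size_nm: float = 15.0
    blur_sigma_nm: float = 15.0
    gamma: float = 0.5
    colormap: str = "Red Hot"  # metadata only; greyscale data is written

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.blur_sigma_nm < 0:
            raise ValueError("blur_sigma_nm must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


def render_palm_image(
    table: LocalizationTable, settings: RenderSettings = RenderSettings()
) -> np.ndarray:
    """Render a localization table to a [0, 1] intensity image.

    The pre-blur histogram mass equals the localization count; the Gaussian
    kernel (truncated at 4 sigma) conserves mass away from the image edge;
    the gamma adjustment is a monotone intensity transform.
    """
    if len(table) == 0:
        raise ValueError("cannot render an empty localization table")
    s = settings.pixel_size_nm
    xy = table.positions()
    ij = np.floor(xy / s).astype(np.int64)
    # pad so the blur kernel is not clipped for interior clusters
    pad = max(1, int(np.ceil(4.0 * settings.blur_sigma_nm / s)))
    cmin = ij.min(axis=0) - pad
    cmax = ij.max(axis=0) + pad
    hist = np.zeros((int(cmax[1] - cmin[1] + 1), int(cmax[0] - cmin[0] + 1)))
    np.add.at(hist, (ij[:, 1] - cmin[1], ij[:, 0] - cmin[0]), 1.0)
    assert hist.sum() == len(table)
    if settings.blur_sigma_nm > 0:
        hist = ndimage.gaussian_filter(
            hist, sigma=settings.blur_sigma_nm / s, truncate=4.0
        )
    peak = hist.max()
    if peak > 0:
        hist = hist / peak
    return np.power(hist, settings.gamma)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] image as 16-bit greyscale TIFF or PNG (by extension)."""
    import tifffile
    from PIL import Image

    path = Path(path)
    data = np.clip(image, 0.0, 1.0)
    data16 = (data * np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data16)
    elif path.suffix.lower() == ".png":
        Image.fromarray(data16).save(path)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r}")
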