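"""Univariate chemical imaging: band maps, background masks, merged RGB.

The brightness of a pixel in a univariate Raman image is the intensity of
one signature band (peak height or integral within ``center +- 8`` cm^-1 by
default) of that pixel's spectrum.  Background pixels are separated from
cells by thresholding the map (Otsu with a minimum-contrast guard, or a
quantile rule), and three band maps — conventionally nucleic acids (R),
proteins (G) and lipids (B) — are merged into one pseudo-color image that
shows cell morphology together with biomolecule distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.filters import threshold_otsu

from .bands import BandDef
from .containers import RamanCube
from .errors import ConstantMapError, InvalidArgumentError

__all__ = [
    "BandMap",
    "band_intensity_map",
    "threshold_background",
    "merge_rgb",
    "heatmap_rgb",
    "DEFAULT_BAND_HALFWIDTH",
]

#: Half width of the band window in cm^-1 used for peak/integral extraction.
DEFAULT_BAND_HALFWIDTH = 8.0


@dataclass
class BandMap:
    """A rows x cols map of one band's intensity, with an optional mask."""

    band: BandDef
    values: np.ndarray
    mode: str = "peak"
    mask: np.ndarray | None = None  # True = foreground (cell)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def band_intensity_map(
    cube: RamanCube,
    band: BandDef,
    mode: str = "peak",
    halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> BandMap:
    """Per-pixel band intensity: peak height or trapezoidal integral.

    Values may be negative after baseline correction; they are reported
    as-is.
    """
    if mode not in ("peak", "integral"):
        raise InvalidArgumentError("mode must be 'peak' or 'integral'")
    lo, hi = band.center - halfwidth, band.center + halfwidth
    if not (cube.axis.contains(lo) and cube.axis.contains(hi)):
        raise InvalidArgumentError(
            f"band window [{lo}, {hi}] outside axis span {cube.axis.span}"
        )
    mask = cube.axis.window_mask(lo, hi)
    window = cube.intensities[:, :, mask]
    if mode == "peak":
        values = window.max(axis=2)
    else:
        values = np.trapezoid(window, cube.axis.wavenumbers[mask], axis=2)
    return BandMap(band=band, values=values, mode=mode)


def threshold_background(
    values: np.ndarray | BandMap,
    rule: str = "otsu",
    q: float = 0.5,
    min_eta: float = 0.8,
) -> np.ndarray:
    """Boolean foreground mask separating cells from buffer background.

    ``rule="otsu"`` uses Otsu's threshold, guarded by the normalized
    between-class variance eta at the chosen threshold: when the map is not
    genuinely bimodal (eta < ``min_eta``, as for pure background noise) all
    pixels are classed background rather than speckling the noise floor.
    ``rule="quantile"`` marks values above the ``q``-quantile as foreground;
    it is invariant under positive affine rescaling of the map.
    """
    if isinstance(values, BandMap):
        values = values.values
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("map values must be finite")
    if rule == "quantile":
        if not 0 < q < 1:
            raise InvalidArgumentError("quantile q must be in (0, 1)")
        return arr > np.quantile(arr, q)
    if rule != "otsu":
        raise InvalidArgumentError("rule must be 'otsu' or 'quantile'")
    if arr.max() == arr.min():
        raise ConstantMapError("cannot Otsu-threshold a constant map")
    thresh = threshold_otsu(arr)
    fg = arr > thresh
    if fg.sum() == 0 or fg.sum() == arr.size:
        return np.zeros_like(fg)
    # between-class variance fraction at the threshold
    w1 = fg.mean()
    mu0, mu1 = arr[~fg].mean(), arr[fg].mean()
    between = w1 * (1 - w1) * (mu1 - mu0) ** 2
    eta = between / arr.var()
    if eta < min_eta:
        return np.zeros_like(fg)
    return fg


def merge_rgb(maps: list[BandMap] | tuple[BandMap, ...]) -> np.ndarray:
    """Merge three band maps into an 8-bit RGB image.

    Channel order is R = nucleic acids, G = proteins, B = lipids when the
    maps are passed in that order.  All three channels share one min-max
    scale computed over the foreground pixels (whole maps if no masks), so
    the merged colors reflect the *relative* band intensities; background
    pixels are rendered black.
    """
    if len(maps) != 3:
        raise InvalidArgumentError("merge_rgb needs exactly three band maps")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise InvalidArgumentError("band maps have mismatched dimensions")
    out = np.zeros(shape + (3,), dtype=np.uint8)
    fgs = [m.mask if m.mask is not None else np.ones(shape, dtype=bool) for m in maps]
    pooled = np.concatenate([m.values[fg] for m, fg in zip(maps, fgs) if fg.any()])
    if pooled.size == 0:
        return out
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        return out
    for ch, (bmap, fg) in enumerate(zip(maps, fgs)):
        scaled = np.clip((bmap.values - lo) / (hi - lo), 0.0, 1.0)
        out[:, :, ch] = np.where(fg, np.round(scaled * 255).astype(np.uint8), 0)
    return out


def heatmap_rgb(values: np.ndarray, cmap: str = "turbo") -> np.ndarray:
    """Pseudo-color heat map (red = high, blue = low with the default map)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    norm = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    rgba = colormaps[cmap](norm)
    return (rgba[:, :, :3] * 255).round().astype(np.uint8)
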