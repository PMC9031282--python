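"""Text-format readers and writers for cubes, labeled sets and masks.

Two dialects are supported, both plain text so that fixtures and results
stay portable and diffable:

* **long-format TSV** for hyperspectral maps — columns ``x_um``, ``y_um``,
  ``wavenumber``, ``intensity``, one line per (pixel, channel), pixels in
  row-major order with channels innermost (the layout produced by mapping
  spectrometer exports);
* **matrix CSV** for labeled spectra — a header row of wavenumbers plus a
  final ``label`` column, one spectrum per row.

Both round-trip at full float precision.  Readers validate rather than
repair: ragged grids, duplicate records, gaps and non-monotone axes raise
:class:`FormatError` naming the offending record.  Pixel masks are written
as 8-bit grayscale PNG (0 = background, cell ids 1..n as-is).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import LabeledSpectraSet, RamanCube, SpectralAxis
from .errors import FormatError, InvalidArgumentError

__all__ = [
    "read_map_long",
    "write_map_long",
    "read_labeled_csv",
    "write_labeled_csv",
    "cube_to_set",
    "read_mask_png",
    "write_mask_png",
]

_LONG_COLUMNS = ["x_um", "y_um", "wavenumber", "intensity"]


def write_map_long(cube: RamanCube, path: str | Path) -> None:
    """Write a cube as long-format TSV (x_um, y_um, wavenumber, intensity)."""
    x, y = cube.pixel_coords()
    n_ch = cube.axis.n_channels
    df = pd.DataFrame({
        "x_um": np.repeat(x, n_ch),
        "y_um": np.repeat(y, n_ch),
        "wavenumber": np.tile(cube.axis.wavenumbers, cube.n_pixels),
        "intensity": cube.to_matrix().ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def read_map_long(path: str | Path) -> RamanCube:
    """Read a long-format TSV map, inferring grid layout and step."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in _LONG_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(f"{path}: non-numeric value in column {col!r}, "
                              f"line {int(bad[0]) + 2}")
    dup = df.duplicated(subset=["x_um", "y_um", "wavenumber"])
    if dup.any():
        rec = df.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate record (x={rec.x_um}, y={rec.y_um}, "
            f"wn={rec.wavenumber})"
        )
    xs = np.sort(df["x_um"].unique())
    ys = np.sort(df["y_um"].unique())
    # the axis is taken in file order from the first pixel; readers reject
    # rather than silently reorder a non-monotone axis
    first = df[(df.x_um == df.x_um.iloc[0]) & (df.y_um == df.y_um.iloc[0])]
    wn = first["wavenumber"].to_numpy(float)
    if not np.all(np.diff(wn) > 0):
        raise FormatError(f"{path}: wavenumber axis is not strictly increasing")
    axis = SpectralAxis(wn)

    expected = len(xs) * len(ys) * len(wn)
    if len(df) != expected:
        counts = df.groupby(["x_um", "y_um"]).size()
        bad = counts[counts != len(wn)]
        if len(bad):
            (bx, by) = bad.index[0]
            raise FormatError(
                f"{path}: pixel (x={bx}, y={by}) has {int(bad.iloc[0])} records, "
                f"expected {len(wn)}"
            )
        raise FormatError(f"{path}: ragged grid ({len(df)} records, expected {expected})")

    ix = {v: i for i, v in enumerate(xs)}
    iy = {v: i for i, v in enumerate(ys)}
    iwn = {v: i for i, v in enumerate(wn)}
    cube_arr = np.full((len(ys), len(xs), len(wn)), np.nan)
    rows = df["y_um"].map(iy).to_numpy()
    cols = df["x_um"].map(ix).to_numpy()
    chans = df["wavenumber"].map(iwn).to_numpy()
    if np.any(pd.isna(chans)):
        raise FormatError(f"{path}: pixels disagree on the wavenumber grid")
    cube_arr[rows, cols, chans.astype(int)] = df["intensity"].to_numpy(float)
    if np.isnan(cube_arr).any():
        r, c, k = np.argwhere(np.isnan(cube_arr))[0]
        raise FormatError(
            f"{path}: missing record for pixel (x={xs[c]}, y={ys[r]}), "
            f"wavenumber {wn[k]}"
        )

    def _spacing(vals: np.ndarray) -> float | None:
        if len(vals) < 2:
            return None
        d = np.diff(vals)
        if not np.allclose(d, d[0]):
            raise FormatError(f"{path}: irregular pixel spacing {sorted(set(d))}")
        return float(d[0])

    sx, sy = _spacing(xs), _spacing(ys)
    if sx is not None and sy is not None and not np.isclose(sx, sy):
        raise FormatError(f"{path}: x step {sx} differs from y step {sy}")
    step = sx or sy or 1.0
    return RamanCube(axis, cube_arr, step=step, origin=(float(xs[0]), float(ys[0])))


def write_labeled_csv(spectra: LabeledSpectraSet, path: str | Path) -> None:
    """Write a labeled set as matrix CSV: wavenumber header + label column."""
    df = pd.DataFrame(spectra.matrix, columns=[repr(float(w)) for w in spectra.axis.wavenumbers])
    df["label"] = spectra.labels
    df.to_csv(path, index=False)


def read_labeled_csv(path: str | Path) -> LabeledSpectraSet:
    """Read a matrix CSV written by :func:`write_labeled_csv`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    if len(df) == 0:
        raise FormatError(f"{path}: empty spectra body")
    try:
        wn = np.array([float(c) for c in df.columns if c != "label"])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber in header") from exc
    if not np.all(np.diff(wn) > 0):
        raise FormatError(f"{path}: wavenumber header is not strictly increasing")
    body = df.drop(columns="label")
    for col in body.columns:
        if not np.issubdtype(body[col].dtype, np.number):
            bad = body.index[pd.to_numeric(body[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value at row {int(bad[0])}, "
                f"wavenumber {col}"
            )
    return LabeledSpectraSet(
        SpectralAxis(wn), body.to_numpy(float), df["label"].to_numpy(object)
    )


def cube_to_set(cube: RamanCube, mask: np.ndarray) -> LabeledSpectraSet:
    """Flatten a cube into a labeled set using a per-pixel label mask.

    Row order is row-major pixel order; labels are copied from the mask
    (any dtype convertible to str).
    """
    mask = np.asarray(mask)
    if mask.shape != (cube.rows, cube.cols):
        raise InvalidArgumentError(
            f"mask shape {mask.shape} does not match cube {cube.rows}x{cube.cols}"
        )
    labels = np.array([str(v) for v in mask.ravel()], dtype=object)
    return LabeledSpectraSet(cube.axis, cube.to_matrix(), labels)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as 8-bit grayscale PNG."""
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidArgumentError("mask labels must fit 8-bit PNG (0..255)")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit label mask written by :func:`write_mask_png`."""
    return np.asarray(iio.imread(Path(path))).astype(int)
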