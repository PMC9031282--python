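"""Core in-memory containers: spectral axis, hyperspectral cube, labeled spectra.

A hyperspectral Raman map is a 2-D pixel grid where every pixel holds a full
spectrum sampled on a shared wavenumber axis.  The containers here are thin
dataclasses around numpy arrays; all heavier processing lives in the
dedicated modules (:mod:`preprocess`, :mod:`denoise`, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AxisMismatchError, InvalidArgumentError

__all__ = ["SpectralAxis", "RamanCube", "LabeledSpectraSet", "BACKGROUND_LABEL"]

#: Label used for pixels/spectra that belong to the buffer background.
BACKGROUND_LABEL = "background"


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly increasing grid of Raman shifts in cm^-1."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise InvalidArgumentError("axis needs at least two wavenumbers")
        if not np.all(np.diff(wn) > 0):
            raise InvalidArgumentError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)

    @property
    def n_channels(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def index_of(self, wavenumber: float) -> int:
        """Channel index nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels inside the closed window [lo, hi]."""
        if lo >= hi:
            raise InvalidArgumentError(f"empty window [{lo}, {hi}]")
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def contains(self, wavenumber: float) -> bool:
        lo, hi = self.span
        return lo <= wavenumber <= hi

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpectralAxis) and np.array_equal(
            self.wavenumbers, other.wavenumbers
        )

    def __len__(self) -> int:
        return self.n_channels


def _require_same_axis(a: SpectralAxis, b: SpectralAxis, what: str) -> None:
    if a != b:
        raise AxisMismatchError(f"{what} do not share a spectral axis")


@dataclass
class RamanCube:
    """A rows x cols pixel grid of spectra with spatial metadata.

    ``intensities`` has shape (rows, cols, n_channels); ``step`` is the
    scanning step in micrometres; ``origin`` is the (x0, y0) position of the
    first pixel.  x increases with column index, y with row index.
    """

    axis: SpectralAxis
    intensities: np.ndarray
    step: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != self.axis.n_channels:
            raise InvalidArgumentError(
                f"intensities shape {arr.shape} inconsistent with "
                f"{self.axis.n_channels}-channel axis"
            )
        if self.step <= 0:
            raise InvalidArgumentError("step must be positive")
        self.intensities = arr

    @property
    def rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def to_matrix(self) -> np.ndarray:
        """Spectra as an (n_pixels, n_channels) matrix in row-major pixel order."""
        return self.intensities.reshape(self.n_pixels, self.axis.n_channels)

    def with_matrix(self, matrix: np.ndarray) -> "RamanCube":
        """A copy of this cube with spectra replaced from a pixel-major matrix."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_pixels, self.axis.n_channels):
            raise InvalidArgumentError("matrix shape does not match cube layout")
        return replace(
            self, intensities=matrix.reshape(self.rows, self.cols, self.axis.n_channels)
        )

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates in micrometres for every pixel, row-major."""
        x0, y0 = self.origin
        x = x0 + np.arange(self.cols) * self.step
        y = y0 + np.arange(self.rows) * self.step
        xx, yy = np.meshgrid(x, y)
        return xx.ravel(), yy.ravel()


@dataclass
class LabeledSpectraSet:
    """A spectra matrix with one class label per row."""

    axis: SpectralAxis
    matrix: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        mat = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        labels = np.asarray(self.labels, dtype=object)
        if mat.shape[1] != self.axis.n_channels:
            raise InvalidArgumentError(
                f"matrix has {mat.shape[1]} channels, axis has {self.axis.n_channels}"
            )
        if labels.shape != (mat.shape[0],):
            raise InvalidArgumentError(
                f"{labels.size} labels for {mat.shape[0]} spectra"
            )
        self.matrix = mat
        self.labels = labels

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def subset(self, label: str) -> np.ndarray:
        """Rows belonging to one class."""
        return self.matrix[self.labels == label]

    def without_background(self) -> "LabeledSpectraSet":
        keep = self.labels != BACKGROUND_LABEL
        return LabeledSpectraSet(self.axis, self.matrix[keep], self.labels[keep])

    def with_matrix(self, matrix: np.ndarray) -> "LabeledSpectraSet":
        return LabeledSpectraSet(self.axis, matrix, self.labels.copy())
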