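"""Spectral purification: despiking, baseline correction, normalization.

The purification chain mirrors the standard treatment of low-SNR cellular
Raman maps:

1. cosmic-ray spikes are repaired by a running-median detector;
2. the dominant fluorescence background is removed by iterative ("modified")
   polynomial fitting — a polynomial is fitted, the spectrum is clipped to
   ``min(spectrum, fit)`` and the fit repeated until it settles below the
   Raman bands (degree 9, relative tolerance 0.001, at most 100 iterations
   by default);
3. each spectrum is divided by the trapezoidal integral of the PBS buffer
   916 cm^-1 band over 910-920 cm^-1, removing pixel-to-pixel throughput
   differences.

All three operations accept a single spectrum or a (n, channels) matrix and
are vectorized over rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .containers import LabeledSpectraSet, RamanCube, SpectralAxis
from .errors import DegenerateNormalizationError, InvalidArgumentError

__all__ = [
    "SpikeConfig",
    "BaselineConfig",
    "NormalizationWindow",
    "remove_spikes",
    "fit_baseline",
    "normalize_band",
    "purify_matrix",
    "purify_set",
    "purify_cube",
    "PBS_WINDOW",
]


@dataclass(frozen=True)
class SpikeConfig:
    """Running-median spike detector settings.

    Defaults (window 7, z 8) never fire on noiseless spectra and repair
    one- and two-channel-wide cosmic rays.
    """

    window: int = 7
    z_threshold: float = 8.0
    max_width: int = 2  # cosmic rays span 1-2 channels; wider runs are bands

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidArgumentError("window must be odd and >= 3")
        if self.z_threshold <= 0:
            raise InvalidArgumentError("z_threshold must be > 0")
        if self.max_width < 1:
            raise InvalidArgumentError("max_width must be >= 1")


@dataclass(frozen=True)
class BaselineConfig:
    """Iterative polynomial baseline settings (degree 9, tol 0.001, 100 iters)."""

    degree: int = 9
    tol: float = 1e-3
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise InvalidArgumentError("degree must be >= 0")
        if self.tol <= 0:
            raise InvalidArgumentError("tol must be > 0")
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")


@dataclass(frozen=True)
class NormalizationWindow:
    """Closed wavenumber window whose band integral is the reference."""

    lo: float = 910.0
    hi: float = 920.0

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise InvalidArgumentError("window lo must be < hi")


#: The PBS buffer 916 cm^-1 normalization window.
PBS_WINDOW = NormalizationWindow(910.0, 920.0)


def _as_matrix(spectra: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise InvalidArgumentError("expected a spectrum or a spectra matrix")


def remove_spikes(spectra: np.ndarray, cfg: SpikeConfig = SpikeConfig()) -> np.ndarray:
    """Replace cosmic-ray channels by the local running median.

    A channel is flagged when its deviation from the running median exceeds
    ``z_threshold`` times the robust (MAD-based) scale of the deviations of
    its own spectrum; contiguous flagged runs wider than ``max_width``
    channels are genuine bands, not cosmic rays, and are left alone, as are
    the half-window edge channels where the running median is biased.  Only
    flagged channels are modified.
    """
    mat, single = _as_matrix(spectra)
    if not np.all(np.isfinite(mat)):
        raise InvalidArgumentError("spectra must be finite")
    med = median_filter(mat, size=(1, cfg.window), mode="reflect")
    resid = mat - med
    scale = 1.4826 * np.median(np.abs(resid), axis=1, keepdims=True)
    floor = 1e-12 * np.maximum(np.abs(mat).max(axis=1, keepdims=True), 1.0)
    scale = np.maximum(scale, floor)
    flagged = np.abs(resid) > cfg.z_threshold * scale
    half = cfg.window // 2
    flagged[:, :half] = False
    flagged[:, mat.shape[1] - half:] = False
    # drop runs wider than max_width
    padded = np.pad(flagged, ((0, 0), (1, 1)))
    starts = padded[:, 1:-1] & ~padded[:, :-2]
    for i, j in zip(*np.nonzero(starts)):
        width = 1
        while j + width < mat.shape[1] and flagged[i, j + width]:
            width += 1
        if width > cfg.max_width:
            flagged[i, j:j + width] = False
    out = np.where(flagged, med, mat)
    return out[0] if single else out


def fit_baseline(
    spectra: np.ndarray, cfg: BaselineConfig = BaselineConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively fit a polynomial below each spectrum and subtract it.

    Returns ``(baseline, corrected)``.  Each iteration fits a degree-``degree``
    polynomial (on the channel grid affinely mapped to [-1, 1] for
    conditioning), clips the fit target to ``min(target, fit)`` and refits;
    iteration stops when the maximum absolute change between successive fits,
    relative to the spectrum's maximum magnitude, drops below ``tol``, or
    after ``max_iter`` iterations.  Negative residuals are kept — clipping
    them would bias band integrals.
    """
    mat, single = _as_matrix(spectra)
    n, p = mat.shape
    if p <= cfg.degree:
        raise InvalidArgumentError(
            f"need more than degree+1={cfg.degree + 1} channels, got {p}"
        )
    t = np.linspace(-1.0, 1.0, p)
    V = np.polynomial.polynomial.polyvander(t, cfg.degree)  # p x (d+1)
    pinv = np.linalg.pinv(V)  # (d+1) x p
    scale = np.maximum(np.abs(mat).max(axis=1), 1e-300)  # per spectrum
    target = mat.T.copy()  # p x n
    prev = None
    for _ in range(cfg.max_iter):
        fit = V @ (pinv @ target)
        if prev is not None:
            change = np.abs(fit - prev).max(axis=0) / scale
            if np.all(change < cfg.tol):
                break
        prev = fit
        target = np.minimum(target, fit)
    baseline = fit.T
    corrected = mat - baseline
    if single:
        return baseline[0], corrected[0]
    return baseline, corrected


def normalize_band(
    spectra: np.ndarray,
    axis: SpectralAxis,
    window: NormalizationWindow = PBS_WINDOW,
) -> np.ndarray:
    """Divide each spectrum by its trapezoidal band integral over the window.

    Scale-invariant and idempotent: a spectrum whose window integral is one
    is returned unchanged.  A non-positive integral raises
    :class:`DegenerateNormalizationError` (background-free or inverted
    spectrum).
    """
    mat, single = _as_matrix(spectra)
    if not (axis.contains(window.lo) and axis.contains(window.hi)):
        raise InvalidArgumentError("normalization window outside axis span")
    mask = axis.window_mask(window.lo, window.hi)
    if mask.sum() < 2:
        raise InvalidArgumentError("normalization window covers fewer than 2 channels")
    integrals = np.trapezoid(mat[:, mask], axis.wavenumbers[mask], axis=1)
    if np.any(integrals <= 0):
        bad = int(np.argmax(integrals <= 0))
        raise DegenerateNormalizationError(
            f"non-positive band integral ({integrals[bad]:.4g}) in spectrum {bad}"
        )
    out = mat / integrals[:, None]
    return out[0] if single else out


def purify_matrix(
    matrix: np.ndarray,
    axis: SpectralAxis,
    spike_cfg: SpikeConfig | None = SpikeConfig(),
    baseline_cfg: BaselineConfig | None = BaselineConfig(),
    window: NormalizationWindow | None = PBS_WINDOW,
) -> np.ndarray:
    """Full purification chain: despike -> baseline-correct -> normalize.

    Any stage can be skipped by passing ``None`` for its configuration.
    """
    out = np.asarray(matrix, dtype=float)
    if spike_cfg is not None:
        out = remove_spikes(out, spike_cfg)
    if baseline_cfg is not None:
        _, out = fit_baseline(out, baseline_cfg)
    if window is not None:
        out = normalize_band(out, axis, window)
    return out


def purify_set(
    spectra: LabeledSpectraSet,
    spike_cfg: SpikeConfig | None = SpikeConfig(),
    baseline_cfg: BaselineConfig | None = BaselineConfig(),
    window: NormalizationWindow | None = PBS_WINDOW,
) -> LabeledSpectraSet:
    return spectra.with_matrix(
        purify_matrix(spectra.matrix, spectra.axis, spike_cfg, baseline_cfg, window)
    )


def purify_cube(
    cube: RamanCube,
    spike_cfg: SpikeConfig | None = SpikeConfig(),
    baseline_cfg: BaselineConfig | None = BaselineConfig(),
    window: NormalizationWindow | None = PBS_WINDOW,
) -> RamanCube:
    return cube.with_matrix(
        purify_matrix(cube.to_matrix(), cube.axis, spike_cfg, baseline_cfg, window)
    )
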