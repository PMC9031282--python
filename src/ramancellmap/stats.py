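"""Group spectra summaries, difference spectra and band-level ANOVA.

Semi-quantification compares the intensity of a signature band (peak height
or integral within ``center +- 8`` cm^-1) between labeled groups of
normalized, denoised spectra.  Group differences are tested by one-way
fixed-effects ANOVA; for two groups the F statistic equals the squared
pooled-variance two-sample t statistic.  Significance tiers follow the
standard convention: ns > 0.05, * <= 0.05, ** <= 0.01, *** <= 0.001,
**** <= 0.0001.  No multiple-testing correction is applied across bands by
default (a Bonferroni option is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import BandDef
from .containers import LabeledSpectraSet
from .errors import AxisMismatchError, InvalidArgumentError
from .imaging import DEFAULT_BAND_HALFWIDTH

__all__ = [
    "GroupSpectrumSummary",
    "group_summaries",
    "difference_spectrum",
    "BandQuantResult",
    "band_intensities",
    "band_anova",
    "band_report",
    "significance_tier",
]


@dataclass
class GroupSpectrumSummary:
    """Channel-wise mean and standard deviation of one labeled group."""

    group: str
    mean: np.ndarray
    sd: np.ndarray
    n: int
    axis: object = None  # SpectralAxis, kept for axis checks


def group_summaries(spectra: LabeledSpectraSet) -> list[GroupSpectrumSummary]:
    """Mean and SD spectrum per label (sample SD; zero for singleton groups)."""
    out = []
    for group in spectra.classes:
        mat = spectra.subset(group)
        if mat.shape[0] == 0:
            raise InvalidArgumentError(f"group {group!r} is empty")
        sd = mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
        out.append(
            GroupSpectrumSummary(group, mat.mean(axis=0), sd, mat.shape[0], spectra.axis)
        )
    return out


def difference_spectrum(a: GroupSpectrumSummary, b: GroupSpectrumSummary) -> np.ndarray:
    """Channel-wise mean difference a - b (antisymmetric in its arguments)."""
    if a.axis is not None and b.axis is not None and a.axis != b.axis:
        raise AxisMismatchError("group summaries computed on different axes")
    if a.mean.shape != b.mean.shape:
        raise AxisMismatchError("group summaries have different channel counts")
    return a.mean - b.mean


def significance_tier(p: float) -> str:
    """ns / * / ** / *** / **** with **** meaning p <= 0.0001."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class BandQuantResult:
    """One band's per-group intensities and ANOVA outcome."""

    band: BandDef
    values: dict[str, np.ndarray]  # group -> per-spectrum intensities
    F: float
    p: float
    verdict: str

    @property
    def group_means(self) -> dict[str, float]:
        return {g: float(v.mean()) for g, v in self.values.items()}


def band_intensities(
    spectra: LabeledSpectraSet,
    band: BandDef,
    mode: str = "peak",
    halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> dict[str, np.ndarray]:
    """Per-spectrum band intensity (peak height or integral), split by group."""
    if mode not in ("peak", "integral"):
        raise InvalidArgumentError("mode must be 'peak' or 'integral'")
    axis = spectra.axis
    lo, hi = band.center - halfwidth, band.center + halfwidth
    if not (axis.contains(lo) and axis.contains(hi)):
        raise InvalidArgumentError(f"band window [{lo}, {hi}] outside the axis")
    mask = axis.window_mask(lo, hi)
    window = spectra.matrix[:, mask]
    if mode == "peak":
        intensities = window.max(axis=1)
    else:
        intensities = np.trapezoid(window, axis.wavenumbers[mask], axis=1)
    return {g: intensities[spectra.labels == g] for g in spectra.classes}


def band_anova(
    spectra: LabeledSpectraSet,
    band: BandDef,
    mode: str = "peak",
    halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> BandQuantResult:
    """One-way fixed-effects ANOVA of band intensities between groups.

    Requires at least two groups with n >= 2 each.  With zero within-group
    variance and equal group means the F statistic is undefined and the
    verdict is reported as ``"degenerate"``.
    """
    values = band_intensities(spectra, band, mode, halfwidth)
    if len(values) < 2:
        raise InvalidArgumentError("ANOVA needs at least two groups")
    if any(v.size < 2 for v in values.values()):
        raise InvalidArgumentError("every group needs at least two spectra")
    groups = list(values.values())
    grand = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ssw == 0:
        if np.isclose(ssb, 0):  # all values identical: F undefined
            return BandQuantResult(band, values, float("nan"), float("nan"), "degenerate")
        return BandQuantResult(band, values, float("inf"), 0.0, significance_tier(0.0))
    F, p = sps.f_oneway(*groups)
    return BandQuantResult(band, values, float(F), float(p), significance_tier(float(p)))


def band_report(
    spectra: LabeledSpectraSet,
    bands: list[BandDef] | tuple[BandDef, ...],
    mode: str = "peak",
    halfwidth: float = DEFAULT_BAND_HALFWIDTH,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Tabular semi-quantification report for a list of bands.

    With ``bonferroni=True`` p-values are multiplied by the number of bands
    (capped at 1) before the verdict is assigned.
    """
    rows = []
    m = len(bands)
    for band in bands:
        res = band_anova(spectra, band, mode, halfwidth)
        p = res.p
        if bonferroni and np.isfinite(p):
            p = min(1.0, p * m)
        row = {"band": band.center, "assignment": band.assignment,
               "F": res.F, "p": p,
               "verdict": significance_tier(p) if np.isfinite(p) else res.verdict}
        for g, mean in res.group_means.items():
            row[f"mean[{g}]"] = mean
        rows.append(row)
    return pd.DataFrame(rows)
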