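"""Raman band definitions and line shapes.

The band registry follows the conventional assignments for mammalian cells:
749 cm^-1 nucleic acids (Trp), 1003 cm^-1 phenylalanine / protein ring
breathing, 1451 cm^-1 lipid CH2 deformation, and so on.  Phosphate-buffered
saline (PBS) contributes its own signature bands at 634, 808 and 916 cm^-1;
the 910-920 cm^-1 integral of the 916 band is the standard normalization
reference when cells are imaged immersed in buffer.

Band shapes are Lorentzian, the usual condensed-phase Raman line shape, with
a default full width at half maximum of 12 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SpectralAxis
from .errors import InvalidArgumentError

__all__ = [
    "BandDef",
    "lorentzian",
    "DEFAULT_FWHM",
    "CELL_BAND_TABLE",
    "PBS_BANDS",
    "SIGNATURE_BANDS",
    "band_by_center",
]

#: Default full width at half maximum in cm^-1 for synthetic bands.
DEFAULT_FWHM = 12.0


@dataclass(frozen=True)
class BandDef:
    """A single Raman band: position, width, assignment and relative strength."""

    name: str
    center: float  # cm^-1
    width: float = DEFAULT_FWHM  # FWHM, cm^-1
    assignment: str = ""  # biomolecule class (component name)
    amplitude: float = 1.0  # relative peak height, dimensionless

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidArgumentError(f"band {self.name}: width must be > 0")


def lorentzian(
    axis: SpectralAxis | np.ndarray, center: float, fwhm: float = DEFAULT_FWHM
) -> np.ndarray:
    """Unit-height Lorentzian profile evaluated on the axis."""
    wn = axis.wavenumbers if isinstance(axis, SpectralAxis) else np.asarray(axis, float)
    half = fwhm / 2.0
    return 1.0 / (1.0 + ((wn - center) / half) ** 2)


# Component (biomolecule class) band table used by the synthetic generator.
# Amplitudes are relative within a component; positions follow the
# conventional mammalian-cell assignments.
CELL_BAND_TABLE: tuple[BandDef, ...] = (
    BandDef("nucleic-749", 749.0, 12.0, "nucleic-acid", 1.0),
    BandDef("nucleic-1091", 1091.0, 14.0, "nucleic-acid", 0.4),
    BandDef("nucleic-1580", 1580.0, 14.0, "nucleic-acid", 0.7),
    BandDef("protein-1003", 1003.0, 10.0, "protein", 1.0),
    BandDef("protein-1126", 1126.0, 12.0, "protein", 0.5),
    BandDef("protein-1340", 1340.0, 16.0, "protein", 0.6),
    BandDef("protein-1656", 1656.0, 18.0, "protein", 0.8),
    BandDef("lipid-719", 719.0, 12.0, "lipid", 0.3),
    BandDef("lipid-1064", 1064.0, 12.0, "lipid", 0.5),
    BandDef("lipid-1304", 1304.0, 14.0, "lipid", 0.6),
    BandDef("lipid-1451", 1451.0, 14.0, "lipid", 1.0),
)

#: Buffer bands; the 916 cm^-1 band anchors the 910-920 normalization window.
PBS_BANDS: tuple[BandDef, ...] = (
    BandDef("pbs-634", 634.0, 14.0, "pbs-buffer", 0.6),
    BandDef("pbs-808", 808.0, 12.0, "pbs-buffer", 0.5),
    BandDef("pbs-916", 916.0, 12.0, "pbs-buffer", 2.0),
)

#: The three bands used for univariate chemical imaging:
#: nucleic acids, proteins and lipids.
SIGNATURE_BANDS: tuple[BandDef, ...] = (
    CELL_BAND_TABLE[0],   # 749
    CELL_BAND_TABLE[3],   # 1003
    CELL_BAND_TABLE[10],  # 1451
)


def band_by_center(center: float, table: tuple[BandDef, ...] = CELL_BAND_TABLE + PBS_BANDS) -> BandDef:
    """Look up a band by its (exact) center wavenumber."""
    for band in table:
        if band.center == center:
            return band
    raise InvalidArgumentError(f"no band defined at {center} cm^-1")
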