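"""Seeded synthetic hyperspectral Raman data with known ground truth.

The generator emulates fast (1 s per pixel) confocal Raman maps of living
cells immersed in PBS buffer: per-pixel spectra are a linear mixture of
biomolecule component spectra (nucleic acids, proteins, lipids) and the
buffer spectrum, contaminated by a smooth spot-varying fluorescence
baseline, additive Gaussian read-out noise and sparse cosmic-ray spikes.
Two cell classes are produced by attenuating a fixed set of signature bands
in one class (the cancer-like class), mirroring the semi-quantification
pattern observed between melanoma and myoblast cell lines.

Everything is deterministic given a seed, and every generated object comes
with its clean ground truth, so each downstream stage (baseline correction,
PCA denoising, imaging, statistics, classification) can be tested against
exact truth without any measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bands import CELL_BAND_TABLE, PBS_BANDS, BandDef, lorentzian
from .containers import BACKGROUND_LABEL, LabeledSpectraSet, RamanCube, SpectralAxis
from .errors import AxisMismatchError, InvalidArgumentError, PlacementError

__all__ = [
    "ComponentSpectrum",
    "SyntheticScene",
    "NoiseModel",
    "EffectVector",
    "make_axis",
    "make_component_spectra",
    "make_scene",
    "render_cube",
    "make_labeled_classes",
    "default_axis",
    "melanoma_components",
    "melanoma_noise",
    "quiet_noise",
    "MELANOMA_EFFECT",
    "NULL_EFFECT",
    "CELL_COMPONENTS",
    "PBS_COMPONENT",
    "CLASS_A",
    "CLASS_B",
]

#: Component names carried by cell pixels.
CELL_COMPONENTS = ("nucleic-acid", "protein", "lipid")
#: Component present everywhere (cells are immersed in buffer).
PBS_COMPONENT = "pbs-buffer"

#: Class labels: cell-A is the cancer-like (band-attenuated) class.
CLASS_A = "cell-A"
CLASS_B = "cell-B"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSpectrum:
    """A biomolecule-class spectrum: sum of Lorentzian bands on an axis."""

    component: str
    bands: tuple[BandDef, ...]
    profile: np.ndarray
    axis: SpectralAxis

    def __post_init__(self) -> None:
        prof = np.asarray(self.profile, float)
        if prof.shape != (self.axis.n_channels,):
            raise InvalidArgumentError("profile length does not match axis")
        if np.any(prof < 0):
            raise InvalidArgumentError("component profile must be non-negative")
        object.__setattr__(self, "profile", prof)


@dataclass
class SyntheticScene:
    """Ground-truth spatial layout of cells on a pixel grid.

    ``masks`` holds a per-pixel cell id (0 = background); concentration maps
    give the per-component abundance at every pixel (zero outside cell masks
    for cell components, positive everywhere for the buffer component).
    """

    rows: int
    cols: int
    step: float
    masks: np.ndarray
    morphologies: dict[int, str]  # cell id -> "elongated" | "round"
    concentration_maps: dict[str, np.ndarray]
    class_of_cell: dict[int, str]

    @property
    def n_cells(self) -> int:
        return len(self.morphologies)

    def cell_mask(self, cell_id: int | None = None) -> np.ndarray:
        """Boolean foreground mask, optionally restricted to one cell."""
        if cell_id is None:
            return self.masks > 0
        return self.masks == cell_id


@dataclass(frozen=True)
class NoiseModel:
    """Contamination model: fluorescence baseline, white noise, cosmic spikes.

    The fluorescence background is a random positive-enforced polynomial of
    ``baseline_degree`` whose coefficients and overall amplitude are jittered
    from spectrum to spectrum by ``baseline_spot_variation`` (the shift
    varies from spot to spot).  ``spike_amplitude`` is the lower edge of the
    cosmic-ray amplitude range; amplitudes are drawn uniformly from
    [spike_amplitude, 5 x spike_amplitude], widths are 1-2 channels.
    All intensity scales are in the generator's unit-peak-height units.
    """

    baseline_degree: int = 5
    baseline_scale: float = 8.0
    baseline_spot_variation: float = 0.3
    noise_sd: float = 0.35
    spike_rate: float = 0.1  # expected spikes per spectrum
    spike_amplitude: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_scale", "baseline_spot_variation", "noise_sd",
                     "spike_rate", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.baseline_degree < 0:
            raise InvalidArgumentError("baseline_degree must be >= 0")

    def is_null(self) -> bool:
        return (
            self.baseline_scale == 0 and self.noise_sd == 0 and self.spike_rate == 0
        )


@dataclass(frozen=True)
class EffectVector:
    """Per-band multiplicative intensity ratios, class A relative to class B."""

    ratios: dict[float, float] = field(default_factory=dict)  # center -> ratio

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios.values()):
            raise InvalidArgumentError("effect ratios must be > 0")

    def ratio_for(self, band: BandDef) -> float:
        return self.ratios.get(band.center, 1.0)


#: Differential pattern of the cancer-like class: the nucleic-acid (749),
#: protein (1003, 1126, 1340) and lipid (1451) bands are attenuated, while
#: the adenine/guanine band at 1580 shows no class difference.
MELANOMA_EFFECT = EffectVector(
    {749.0: 0.55, 1003.0: 0.55, 1126.0: 0.55, 1340.0: 0.55, 1451.0: 0.55, 1580.0: 1.0}
)

#: No class difference at any band.
NULL_EFFECT = EffectVector({})


# ---------------------------------------------------------------------------
# axis and component construction
# ---------------------------------------------------------------------------


def make_axis(min_wn: float, max_wn: float, n_channels: int) -> SpectralAxis:
    """An evenly spaced wavenumber grid of ``n_channels`` spanning [min, max]."""
    if n_channels < 2:
        raise InvalidArgumentError("n_channels must be >= 2")
    if min_wn >= max_wn:
        raise InvalidArgumentError("min_wn must be < max_wn")
    return SpectralAxis(np.linspace(min_wn, max_wn, n_channels))


def default_axis() -> SpectralAxis:
    """The measurement grid emulated by default: 466-1667 cm^-1, 1022 shifts."""
    return make_axis(466.0, 1667.0, 1022)


def make_component_spectra(
    axis: SpectralAxis, band_table: list[BandDef] | tuple[BandDef, ...]
) -> list[ComponentSpectrum]:
    """Group a band table by assignment and build one spectrum per component."""
    lo, hi = axis.span
    by_component: dict[str, list[BandDef]] = {}
    for band in band_table:
        if not (lo <= band.center <= hi):
            raise InvalidArgumentError(
                f"band {band.name} at {band.center} cm^-1 outside axis span [{lo}, {hi}]"
            )
        by_component.setdefault(band.assignment or band.name, []).append(band)
    out = []
    for component, bands in by_component.items():
        profile = np.zeros(axis.n_channels)
        for band in bands:
            profile += band.amplitude * lorentzian(axis, band.center, band.width)
        out.append(ComponentSpectrum(component, tuple(bands), profile, axis))
    return out


def melanoma_components(
    axis: SpectralAxis | None = None, effect: EffectVector | None = None
) -> list[ComponentSpectrum]:
    """The default cell + buffer components, optionally band-attenuated.

    ``effect`` scales cell-component band amplitudes by their ratios; the
    buffer component is never affected.
    """
    axis = axis or default_axis()
    table = []
    for band in CELL_BAND_TABLE:
        r = effect.ratio_for(band) if effect is not None else 1.0
        table.append(replace(band, amplitude=band.amplitude * r))
    table.extend(PBS_BANDS)
    return make_component_spectra(axis, table)


def melanoma_noise(seed: int = 0) -> NoiseModel:
    """Default contamination level of the fast-acquisition regime."""
    return NoiseModel(seed=seed)


def quiet_noise(seed: int = 0) -> NoiseModel:
    """Low-noise mode emulating long-acquisition reference spectra."""
    return NoiseModel(
        baseline_scale=0.5, baseline_spot_variation=0.1, noise_sd=0.02,
        spike_rate=0.0, spike_amplitude=0.2, seed=seed,
    )


# ---------------------------------------------------------------------------
# scenes and cubes
# ---------------------------------------------------------------------------

_ELONGATED = "elongated"
_ROUND = "round"


def _draw_ellipse_mask(rows, cols, rng, morphology):
    """Random rotated ellipse as a boolean mask; None if it does not fit."""
    if morphology == _ELONGATED:
        a = rng.uniform(0.22, 0.30) * min(rows, cols)
        b = a / rng.uniform(3.0, 4.0)  # axis ratio >= 3
    else:
        a = rng.uniform(0.12, 0.18) * min(rows, cols)
        b = a / rng.uniform(1.0, 1.3)  # axis ratio <= 1.3
    theta = rng.uniform(0, math.pi)
    cr = rng.uniform(a, rows - 1 - a) if rows - 1 > 2 * a else None
    cc = rng.uniform(a, cols - 1 - a) if cols - 1 > 2 * a else None
    if cr is None or cc is None:
        return None
    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - cr, cc_grid - cc
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return None
    return mask


def make_scene(
    rows: int,
    cols: int,
    n_cells: int,
    seed: int,
    step: float = 2.0,
    cell_classes: str | list[str] = CLASS_A,
    abundance_cv: float = 0.15,
    pbs_cv: float = 0.05,
    max_attempts: int = 500,
) -> SyntheticScene:
    """Place non-overlapping elliptical cells on a grid by rejection sampling.

    Morphologies alternate elongated / round; ``cell_classes`` is either one
    label for all cells or a per-cell list.  Cell-component abundances are
    lognormal around a per-cell mean inside each mask and exactly zero
    outside; the buffer component is positive everywhere.
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("grid dims must be >= 1")
    if n_cells < 0:
        raise InvalidArgumentError("n_cells must be >= 0")
    if isinstance(cell_classes, str):
        cell_classes = [cell_classes] * n_cells
    if len(cell_classes) != n_cells:
        raise InvalidArgumentError("need one class per cell")

    rng = np.random.default_rng(seed)
    masks = np.zeros((rows, cols), dtype=int)
    morphologies: dict[int, str] = {}
    for cid in range(1, n_cells + 1):
        morph = _ELONGATED if cid % 2 == 1 else _ROUND
        for _ in range(max_attempts):
            ell = _draw_ellipse_mask(rows, cols, rng, morph)
            if ell is not None and not (ell & (masks > 0)).any():
                masks[ell] = cid
                morphologies[cid] = morph
                break
        else:
            raise PlacementError(
                f"could not place cell {cid} ({morph}) on a {rows}x{cols} grid "
                f"after {max_attempts} attempts"
            )

    conc: dict[str, np.ndarray] = {}
    for name in CELL_COMPONENTS:
        cmap = np.zeros((rows, cols))
        for cid in morphologies:
            cell_mean = rng.lognormal(0.0, abundance_cv)
            inside = masks == cid
            cmap[inside] = cell_mean * rng.lognormal(0.0, abundance_cv / 2, inside.sum())
        conc[name] = cmap
    conc[PBS_COMPONENT] = rng.lognormal(0.0, pbs_cv, (rows, cols))

    class_of_cell = {cid: cell_classes[cid - 1] for cid in morphologies}
    return SyntheticScene(rows, cols, step, masks, morphologies, conc, class_of_cell)


def _random_baselines(rng: np.random.Generator, n: int, axis: SpectralAxis,
                      noise: NoiseModel) -> np.ndarray:
    """Smooth positive fluorescence backgrounds, one per spectrum."""
    p = axis.n_channels
    if noise.baseline_scale == 0:
        return np.zeros((n, p))
    t = np.linspace(-1.0, 1.0, p)
    V = np.polynomial.polynomial.polyvander(t, noise.baseline_degree)  # p x (d+1)
    master = rng.normal(0.0, 1.0, noise.baseline_degree + 1)
    jitter = 1.0 + noise.baseline_spot_variation * rng.normal(0.0, 1.0, (n, master.size))
    coeffs = master[None, :] * jitter
    base = coeffs @ V.T  # n x p
    lo = base.min(axis=1, keepdims=True)
    rngspan = base.max(axis=1, keepdims=True) - lo
    base = base - lo + 0.2 * (rngspan + 1e-12)
    amp = noise.baseline_scale * rng.lognormal(0.0, noise.baseline_spot_variation, n)
    base *= (amp / base.mean(axis=1))[:, None]
    return base


def _add_spikes(rng: np.random.Generator, observed: np.ndarray, noise: NoiseModel) -> None:
    if noise.spike_rate == 0:
        return
    n, p = observed.shape
    counts = rng.poisson(noise.spike_rate, n)
    for i in np.nonzero(counts)[0]:
        for _ in range(counts[i]):
            ch = int(rng.integers(0, p))
            width = int(rng.integers(1, 3))  # 1-2 channels
            amp = rng.uniform(noise.spike_amplitude, 5.0 * noise.spike_amplitude)
            observed[i, ch:ch + width] += amp


def _contaminate(rng: np.random.Generator, clean: np.ndarray, axis: SpectralAxis,
                 noise: NoiseModel) -> np.ndarray:
    observed = clean + _random_baselines(rng, clean.shape[0], axis, noise)
    if noise.noise_sd > 0:
        observed += rng.normal(0.0, noise.noise_sd, clean.shape)
    _add_spikes(rng, observed, noise)
    return observed


def render_cube(
    scene: SyntheticScene,
    components: list[ComponentSpectrum],
    noise: NoiseModel,
) -> tuple[RamanCube, RamanCube]:
    """Render (observed, ground_truth) cubes from a scene.

    observed = clean mixture + spot-varying smooth baseline + white noise
    + cosmic spikes; ground_truth is the clean mixture only.  Deterministic
    given ``noise.seed``.
    """
    axis = components[0].axis
    for c in components[1:]:
        if c.axis != axis:
            raise AxisMismatchError("components were built on different axes")
    by_name = {c.component: c for c in components}
    missing = [n for n in scene.concentration_maps if n not in by_name]
    if missing:
        raise InvalidArgumentError(f"no component spectrum for: {missing}")

    clean = np.zeros((scene.rows, scene.cols, axis.n_channels))
    for name, cmap in scene.concentration_maps.items():
        clean += cmap[:, :, None] * by_name[name].profile[None, None, :]

    truth = RamanCube(axis, clean, step=scene.step)
    rng = np.random.default_rng(noise.seed)
    observed_mat = _contaminate(rng, truth.to_matrix(), axis, noise)
    observed = truth.with_matrix(observed_mat)
    return observed, truth


# ---------------------------------------------------------------------------
# labeled two-class spectra
# ---------------------------------------------------------------------------


def make_labeled_classes(
    n_a: int,
    n_b: int,
    effect: EffectVector,
    noise: NoiseModel,
    seed: int,
    axis: SpectralAxis | None = None,
    band_table: tuple[BandDef, ...] | None = None,
    abundance_cv: float = 0.15,
    pbs_cv: float = 0.05,
    n_background: int = 0,
    return_truth: bool = False,
) -> LabeledSpectraSet | tuple[LabeledSpectraSet, LabeledSpectraSet]:
    """Two classes of single-pixel spectra with a per-band class effect.

    Class A scales the affected bands by the effect ratios (the cancer-like,
    attenuated class); per-spectrum component abundances are lognormal with
    coefficient of variation ``abundance_cv`` (``pbs_cv`` for the buffer).
    Optionally ``n_background`` pure-buffer spectra are appended.  All
    randomness flows from ``seed``.
    """
    if n_a < 1 or n_b < 1:
        raise InvalidArgumentError("n_a and n_b must be >= 1")
    axis = axis or default_axis()
    table = band_table if band_table is not None else CELL_BAND_TABLE + PBS_BANDS

    def class_profiles(eff: EffectVector | None):
        tab = []
        for band in table:
            r = 1.0
            if eff is not None and band.assignment != PBS_COMPONENT:
                r = eff.ratio_for(band)
            tab.append(replace(band, amplitude=band.amplitude * r))
        comps = make_component_spectra(axis, tuple(tab))
        return {c.component: c.profile for c in comps}

    prof_a = class_profiles(effect)
    prof_b = class_profiles(None)
    rng = np.random.default_rng(seed)

    def draw(n: int, profiles: dict[str, np.ndarray], cells: bool) -> np.ndarray:
        clean = np.zeros((n, axis.n_channels))
        for name, profile in profiles.items():
            if name == PBS_COMPONENT:
                amounts = rng.lognormal(0.0, pbs_cv, n) if pbs_cv > 0 else np.ones(n)
            elif cells:
                amounts = rng.lognormal(0.0, abundance_cv, n) if abundance_cv > 0 else np.ones(n)
            else:
                continue
            clean += amounts[:, None] * profile[None, :]
        return clean

    clean_a = draw(n_a, prof_a, cells=True)
    clean_b = draw(n_b, prof_b, cells=True)
    blocks = [clean_a, clean_b]
    labels = [CLASS_A] * n_a + [CLASS_B] * n_b
    if n_background > 0:
        blocks.append(draw(n_background, {PBS_COMPONENT: prof_b[PBS_COMPONENT]}, cells=False))
        labels += [BACKGROUND_LABEL] * n_background

    clean = np.vstack(blocks)
    observed = _contaminate(rng, clean, axis, noise)
    labels_arr = np.array(labels, dtype=object)
    result = LabeledSpectraSet(axis, observed, labels_arr)
    if return_truth:
        return result, LabeledSpectraSet(axis, clean, labels_arr)
    return result
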