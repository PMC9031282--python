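"""End-to-end orchestration: simulate -> purify -> denoise -> image/stats/classify.

A :class:`PipelineConfig` (optionally loaded from YAML) enables stages and
carries every stage's parameters.  All randomness flows from one root seed
via a documented derivation (``stage_seed``), and a run manifest records
the package version, the resolved configuration, the derived seeds and a
SHA-256 hash of every artifact written — rerunning the same configuration
reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .bands import band_by_center
from .classify import (
    CVConfig,
    ReductionSpec,
    SplitSpec,
    evaluate,
    reduce_features,
    split_train_test,
    train_models,
)
from .containers import LabeledSpectraSet, RamanCube
from .denoise import fit_pca, reconstruct
from .errors import PipelineConfigError
from .imaging import band_intensity_map, merge_rgb, threshold_background
from .io_cube import write_labeled_csv, write_map_long, write_mask_png
from .preprocess import BaselineConfig, NormalizationWindow, SpikeConfig, purify_matrix
from .stats import band_report
from .synthdata import (
    MELANOMA_EFFECT,
    make_labeled_classes,
    make_scene,
    melanoma_components,
    melanoma_noise,
    quiet_noise,
    render_cube,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root_seed * 10007 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class SimulateConfig:
    kind: str = "classes"  # "classes" | "cube"
    preset: str = "melanoma"  # "melanoma" | "quiet"
    n_a: int = 200
    n_b: int = 200
    n_background: int = 0
    rows: int = 31
    cols: int = 43
    n_cells: int = 2


@dataclass
class PreprocessConfig:
    enabled: bool = True
    despike: bool = True
    baseline_degree: int = 9
    baseline_tol: float = 1e-3
    baseline_max_iter: int = 100
    norm_lo: float = 910.0
    norm_hi: float = 920.0
    normalize: bool = True


@dataclass
class DenoiseConfig:
    enabled: bool = True
    k: int | str = "auto"


@dataclass
class ImageConfig:
    enabled: bool = False
    bands: tuple[float, ...] = (749.0, 1003.0, 1451.0)
    mode: str = "peak"
    threshold: str = "otsu"


@dataclass
class StatsConfig:
    enabled: bool = False
    bands: tuple[float, ...] = (749.0, 1003.0, 1126.0, 1340.0, 1451.0, 1580.0)
    mode: str = "peak"


@dataclass
class ClassifyConfig:
    enabled: bool = False
    reduce: str = "pca:15"  # "pca:N" | "tsne:2"
    families: tuple[str, ...] | str = "all"
    train_fraction: float = 0.75
    folds: int = 10
    repeats: int = 5


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for one end-to-end run."""

    seed: int = 0
    out_dir: str = "pipeline-out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    image: ImageConfig = field(default_factory=ImageConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for name, value in raw.items():
            if not hasattr(cfg, name):
                raise PipelineConfigError(f"unknown config section {name!r}")
            attr = getattr(cfg, name)
            if dataclasses.is_dataclass(attr) and isinstance(value, dict):
                for k, v in value.items():
                    if not hasattr(attr, k):
                        raise PipelineConfigError(f"unknown option {name}.{k}")
                    setattr(attr, k, tuple(v) if isinstance(v, list) else v)
            else:
                setattr(cfg, name, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        if self.simulate.kind not in ("classes", "cube"):
            raise PipelineConfigError(f"unknown simulate.kind {self.simulate.kind!r}")
        if self.simulate.preset not in ("melanoma", "quiet"):
            raise PipelineConfigError(f"unknown preset {self.simulate.preset!r}")
        if self.classify.enabled and self.simulate.kind != "classes":
            raise PipelineConfigError(
                "classification requires labeled spectra (simulate.kind='classes')"
            )
        if self.stats.enabled and self.simulate.kind != "classes":
            raise PipelineConfigError(
                "statistics require labeled spectra (simulate.kind='classes')"
            )
        if self.image.enabled and self.simulate.kind != "cube":
            raise PipelineConfigError("imaging requires a cube (simulate.kind='cube')")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in workflow order and write a manifest.

    Returns the manifest dictionary (also written to ``out_dir/manifest.json``).
    Stage failures propagate with the stage recorded in the manifest written
    so far; partial outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seeds = {s: stage_seed(config.seed, s) for s in
             ("simulate", "split", "cv", "reduce")}

    def save(name: str, writer, *args) -> Path:
        path = out / name
        writer(*args, path)
        artifacts[name] = _sha256(path)
        return path

    noise_factory = melanoma_noise if config.simulate.preset == "melanoma" else quiet_noise
    noise = noise_factory(seed=seeds["simulate"])
    spike_cfg = SpikeConfig() if config.preprocess.despike else None
    baseline_cfg = BaselineConfig(
        config.preprocess.baseline_degree,
        config.preprocess.baseline_tol,
        config.preprocess.baseline_max_iter,
    )
    window = (NormalizationWindow(config.preprocess.norm_lo, config.preprocess.norm_hi)
              if config.preprocess.normalize else None)

    results: dict = {}
    if config.simulate.kind == "classes":
        spectra = make_labeled_classes(
            config.simulate.n_a, config.simulate.n_b, MELANOMA_EFFECT, noise,
            seed=seeds["simulate"], n_background=config.simulate.n_background,
        )
        save("spectra_raw.csv", write_labeled_csv, spectra)
        if config.preprocess.enabled:
            spectra = spectra.with_matrix(purify_matrix(
                spectra.matrix, spectra.axis, spike_cfg, baseline_cfg, window))
            save("spectra_purified.csv", write_labeled_csv, spectra)
        model = None
        if config.denoise.enabled:
            k = None if config.denoise.k == "auto" else int(config.denoise.k)
            model = fit_pca(spectra.matrix, k=k)
            denoised, _ = reconstruct(model)
            spectra = spectra.with_matrix(denoised)
            scree = out / "scree.csv"
            np.savetxt(scree, np.column_stack([
                np.arange(1, model.explained_var.size + 1), model.explained_var,
            ]), delimiter=",", header="pc,explained_variance_fraction", comments="")
            artifacts["scree.csv"] = _sha256(scree)
            results["k_selected"] = model.k_selected
            save("spectra_denoised.csv", write_labeled_csv, spectra)
        if config.stats.enabled:
            bands = [band_by_center(c) for c in config.stats.bands]
            report = band_report(spectra.without_background(), bands, config.stats.mode)
            rp = out / "band_anova.csv"
            report.to_csv(rp, index=False)
            artifacts["band_anova.csv"] = _sha256(rp)
            results["band_anova"] = report.to_dict(orient="records")
        if config.classify.enabled:
            method, _, ncomp = config.classify.reduce.partition(":")
            rspec = ReductionSpec(method=method, n_components=int(ncomp or 15),
                                  seed=seeds["reduce"])
            feats, labels = reduce_features(spectra.without_background(), rspec)
            (ftr, ytr), (fte, yte) = split_train_test(
                feats, labels,
                SplitSpec(config.classify.train_fraction, seed=seeds["split"]),
            )
            registry = train_models(
                ftr, ytr,
                CVConfig(config.classify.folds, config.classify.repeats, seeds["cv"]),
                families=config.classify.families,
            )
            report = evaluate(registry, fte, yte)
            rp = out / "classification.csv"
            report.to_frame().to_csv(rp, index=False)
            artifacts["classification.csv"] = _sha256(rp)
            results["classification"] = report.to_frame().to_dict(orient="records")
    else:  # cube
        scene = make_scene(config.simulate.rows, config.simulate.cols,
                           config.simulate.n_cells, seed=seeds["simulate"])
        components = melanoma_components()
        observed, truth = render_cube(scene, components, noise)
        save("cube_observed.tsv", write_map_long, observed)
        save("cube_truth.tsv", write_map_long, truth)
        save("scene_mask.png", write_mask_png, scene.masks)
        cube = observed
        if config.preprocess.enabled:
            cube = cube.with_matrix(purify_matrix(
                cube.to_matrix(), cube.axis, spike_cfg, baseline_cfg, window))
        if config.denoise.enabled:
            k = None if config.denoise.k == "auto" else int(config.denoise.k)
            model = fit_pca(cube.to_matrix(), k=k)
            denoised, _ = reconstruct(model)
            cube = cube.with_matrix(denoised)
            results["k_selected"] = model.k_selected
            save("cube_denoised.tsv", write_map_long, cube)
        if config.image.enabled:
            maps = []
            for center in config.image.bands:
                bmap = band_intensity_map(cube, band_by_center(center),
                                          mode=config.image.mode)
                bmap.mask = threshold_background(bmap.values, rule=config.image.threshold)
                np.savetxt(out / f"map_{int(center)}.csv", bmap.values, delimiter=",")
                artifacts[f"map_{int(center)}.csv"] = _sha256(out / f"map_{int(center)}.csv")
                maps.append(bmap)
            if len(maps) == 3:
                rgb_path = out / "merged_rgb.png"
                iio.imwrite(rgb_path, merge_rgb(maps))
                artifacts["merged_rgb.png"] = _sha256(rgb_path)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "artifacts": artifacts,
        "results": {k: v for k, v in results.items() if k == "k_selected"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results
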