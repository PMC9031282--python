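"""Univariate chemical imaging of a synthetic two-cell map.

Renders a 31x43-pixel map (2 um step) containing one elongated and one
round cell, purifies and PCA-denoises it, builds band-intensity maps for
nucleic acids (749), proteins (1003) and lipids (1451 cm^-1), thresholds
the background and writes a merged RGB chemical image.
"""

import numpy as np

import ramancellmap as rm

scene = rm.make_scene(31, 43, 2, seed=3)
components = rm.melanoma_components()
observed, truth = rm.render_cube(scene, components, rm.melanoma_noise(seed=3))
print(f"scene: {scene.n_cells} cells, morphologies {scene.morphologies}, "
      f"{int(scene.cell_mask().sum())} cell pixels of {observed.n_pixels}")

purified = rm.purify_cube(observed)
denoised, _ = rm.denoise_matrix(purified.to_matrix(), k=4)
cube = purified.with_matrix(denoised)

maps = [rm.band_intensity_map(cube, rm.band_by_center(c))
        for c in (749.0, 1003.0, 1451.0)]
merged_values = sum(m.values for m in maps)
fg = rm.threshold_background(merged_values, rule="otsu", min_eta=0.6)
for m in maps:
    m.mask = fg

truth_mask = scene.cell_mask()
iou = (fg & truth_mask).sum() / (fg | truth_mask).sum()
print(f"foreground pixels {int(fg.sum())}, IoU vs true cell masks {iou:.2f}")
# IoU near 1 means the denoised band maps reproduce the cell outlines

rgb = rm.merge_rgb(maps)  # R=nucleic acids, G=proteins, B=lipids
import imageio.v3 as iio

iio.imwrite("chemical_image.png", rgb)
print("wrote chemical_image.png (merged R/G/B = nucleic/protein/lipid)")
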