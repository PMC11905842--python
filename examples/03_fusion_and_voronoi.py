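"""Tissue-constrained fusion of deformed pseudo-atlases + Voronoi tessellation.

Warps the phantom's true parcellation through 20 smooth random deformations
(1 mm RMS, mimicking registration error), cleans each against the tissue
map, fuses them, and tessellates the cerebrum white matter by nearest
grey-matter region.  Prints the per-label Dice improvement of fusion over
the individual warped atlases.
"""

import numpy as np

from pmmorph.fusion import clean_warped_parcellation, fuse_parcellations, voronoi_tessellate_wm
from pmmorph.phantom import PhantomSpec, make_atlas_set, make_phantom

sample = make_phantom(PhantomSpec(seed=0))
truth = sample.truth_parcellation.labels
atlases = make_atlas_set(sample, 20, deformation_amplitude_mm=1.0, seed=7)


def mean_label_dice(pred):
    vals = []
    for lab in np.unique(truth[truth > 0]):
        a, b = pred == lab, truth == lab
        vals.append(2 * np.count_nonzero(a & b) / (a.sum() + b.sum()))
    return float(np.mean(vals))


cleaned = [clean_warped_parcellation(a, sample.truth_tissue, sample.label_table)
           for a, _ in atlases]
result = fuse_parcellations(cleaned, sample.truth_tissue, sample.label_table)
individual = np.mean([mean_label_dice(a.labels) for a, _ in atlases])
print(f"mean per-label Dice, individual warped atlases: {individual:.4f}")
print(f"mean per-label Dice, fused parcellation:        "
      f"{mean_label_dice(result.parcellation.labels):.4f}")

tessellated, table = voronoi_tessellate_wm(result.parcellation, sample.label_table)
new_regions = sorted(set(tessellated.labels.ravel()) - set(truth.ravel()) - {0})
print(f"Voronoi WM sub-regions created: {len(new_regions)}")
# Fusion beats every individual atlas because registration errors are
# independent; the Voronoi split lets WMH volumes be localized inside WM.
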