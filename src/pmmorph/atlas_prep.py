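"""Derivation of postmortem-ready restricted atlases.

A whole-brain atlas cannot be registered to a formalin-fixed left
hemisphere as-is: ventricles collapse postmortem, the right hemisphere is
absent, and the cerebellum detaches from the forebrain and floats in the
fixative.  ``restrict_atlas`` removes ventricle labels and right-hemisphere
content and cuts bilateral regions at the midline plane;
``erode_cerebellum`` erases cerebellar labels within a small Chebyshev
distance of cortical labels, opening a gap that deformable registration
can inflate to follow the detached cerebellum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelTable, LabelVolume, ScalarVolume

__all__ = ["RestrictedAtlas", "restrict_atlas", "erode_cerebellum"]


@dataclass
class RestrictedAtlas:
    parcellation: LabelVolume
    template: ScalarVolume
    table: LabelTable
    midline_index: int
    keep_side: str
    erosion_distance: int | None = None

    def validate(self) -> None:
        """Assert the restricted-atlas invariants; raises on violation."""
        labels = self.parcellation.labels
        present = self.parcellation.present_labels()
        discard = "right" if self.keep_side == "left" else "left"
        bad = np.intersect1d(present, self.table.ventricle_labels())
        if bad.size:
            raise AssertionError(f"ventricle labels remain: {bad.tolist()}")
        bad = np.intersect1d(present, self.table.hemisphere_labels(discard))
        if bad.size:
            raise AssertionError(f"{discard}-hemisphere labels remain: {bad.tolist()}")
        axis0 = np.arange(labels.shape[0])[:, None, None]
        discarded_side = axis0 > self.midline_index if self.keep_side == "left" \
            else axis0 < self.midline_index
        if np.any((labels > 0) & discarded_side):
            raise AssertionError("labeled voxels remain on the discarded side of the midline")
        if self.erosion_distance is not None:
            cereb = np.isin(labels, np.concatenate([
                self.table.wm_labels(cerebellum=True), self.table.gm_labels(cerebellum=True)]))
            cortical = np.isin(labels, self.table.cortical_labels())
            if cortical.any() and cereb.any():
                near = ndimage.binary_dilation(
                    cortical, structure=np.ones((3, 3, 3), bool),
                    iterations=self.erosion_distance)
                if np.any(cereb & near):
                    raise AssertionError("cerebellar labels within erosion distance of cortex")


def restrict_atlas(parcellation: LabelVolume, template: ScalarVolume,
                   table: LabelTable, midline_index: int = 90,
                   keep_side: str = "left") -> RestrictedAtlas:
    """Remove ventricles and the discarded hemisphere; cut at the midline.

    Ventricle/CSF labels and labels of the discarded hemisphere are zeroed
    everywhere.  For bilateral regions (and any stray labeled voxel), both
    the labels and the template intensity are zeroed at voxels on the
    discarded side of the midline plane (first voxel axis, 0-based index
    ``midline_index``); the kept side is untouched.
    """
    parcellation.grid.require_compatible(template.grid)
    table.require_covers(parcellation)
    if keep_side not in ("left", "right"):
        raise ValueError("keep_side must be 'left' or 'right'")
    if not 0 <= midline_index < parcellation.grid.dims[0]:
        raise ValueError(f"midline index {midline_index} outside grid "
                         f"dims {parcellation.grid.dims}")
    discard = "right" if keep_side == "left" else "left"

    labels = parcellation.labels.copy()
    tmpl = template.values.copy()
    drop = np.concatenate([table.ventricle_labels(), table.hemisphere_labels(discard)])
    labels[np.isin(labels, drop)] = 0

    axis0 = np.arange(labels.shape[0])[:, None, None]
    discarded_side = axis0 > midline_index if keep_side == "left" \
        else axis0 < midline_index
    cut = np.broadcast_to(discarded_side, labels.shape)
    labels = np.where(cut, 0, labels)
    tmpl = np.where(cut, 0.0, tmpl)

    atlas = RestrictedAtlas(
        parcellation=parcellation.with_labels(labels),
        template=ScalarVolume(template.grid, tmpl),
        table=table, midline_index=midline_index, keep_side=keep_side,
    )
    atlas.validate()
    return atlas


def erode_cerebellum(atlas: RestrictedAtlas, distance_voxels: int = 2) -> RestrictedAtlas:
    """Zero cerebellar labels within ``distance_voxels`` (Chebyshev) of cortex.

    Implemented as ``distance_voxels`` dilations of the cortical-label mask
    with a 3x3x3 structuring element.  Idempotent; with no cortical labels
    present the atlas is returned unchanged.
    """
    if distance_voxels < 1:
        raise ValueError("distance must be >= 1")
    labels = atlas.parcellation.labels
    cortical = np.isin(labels, atlas.table.cortical_labels())
    if not cortical.any():
        return RestrictedAtlas(atlas.parcellation, atlas.template, atlas.table,
                               atlas.midline_index, atlas.keep_side,
                               erosion_distance=distance_voxels)
    cereb_ids = np.concatenate([atlas.table.wm_labels(cerebellum=True),
                                atlas.table.gm_labels(cerebellum=True)])
    near = ndimage.binary_dilation(cortical, structure=np.ones((3, 3, 3), bool),
                                   iterations=distance_voxels)
    out = labels.copy()
    out[near & np.isin(labels, cereb_ids)] = 0
    result = RestrictedAtlas(atlas.parcellation.with_labels(out), atlas.template,
                             atlas.table, atlas.midline_index, atlas.keep_side,
                             erosion_distance=distance_voxels)
    result.validate()
    return result
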