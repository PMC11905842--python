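"""Tissue-constrained fusion rules and the L1 Voronoi tessellation oracle."""

import numpy as np
import pytest

from pmmorph.core import GREY, WHITE, LabelTable, LabelVolume, TissueMap, VoxelGrid
from pmmorph.fusion import (
    VORONOI_OFFSET,
    clean_warped_parcellation,
    fuse_parcellations,
    voronoi_tessellate_wm,
)


def _table():
    return LabelTable.from_rows([
        dict(label=2, name="cerebrum-wm", tissue_class="WM", hemisphere="left",
             is_cerebellum=False, is_cortical=False),
        dict(label=7, name="cb-wm", tissue_class="WM", hemisphere="left",
             is_cerebellum=True, is_cortical=False),
        dict(label=8, name="cb-gm", tissue_class="GM", hemisphere="left",
             is_cerebellum=True, is_cortical=False),
        dict(label=10, name="thalamus", tissue_class="GM", hemisphere="left",
             is_cerebellum=False, is_cortical=False),
        dict(label=1001, name="cortexA", tissue_class="GM", hemisphere="left",
             is_cerebellum=False, is_cortical=True),
        dict(label=1002, name="cortexB", tissue_class="GM", hemisphere="left",
             is_cerebellum=False, is_cortical=True),
        dict(label=4, name="ventricle", tissue_class="ventricle_CSF",
             hemisphere="both", is_cerebellum=False, is_cortical=False),
    ])


def _grid(d=12):
    return VoxelGrid((d, d, d), (1, 1, 1))


class TestCleanWarpedParcellation:
    def test_tissue_inconsistent_labels_removed(self):
        grid = _grid(8)
        tis = np.full(grid.dims, WHITE, dtype=np.int32)
        tis[0] = GREY
        lab = np.zeros(grid.dims, np.int32)
        lab[0, 0, 0] = 1001   # GM label on GREY tissue: kept
        lab[0, 1, 1] = 2      # WM label on GREY tissue: removed
        lab[4, 4, 4] = 1001   # GM label on WHITE tissue: removed
        lab[4, 5, 5] = 2      # WM label on WHITE tissue: kept
        out = clean_warped_parcellation(LabelVolume(grid, lab), TissueMap(grid, tis),
                                        _table())
        assert out.labels[0, 0, 0] == 1001
        assert out.labels[0, 1, 1] == 0
        assert out.labels[4, 4, 4] == 0
        assert out.labels[4, 5, 5] == 2

    def test_cerebellar_swap(self):
        grid = _grid(8)
        tis = np.full(grid.dims, WHITE, dtype=np.int32)
        tis[0] = GREY
        lab = np.zeros(grid.dims, np.int32)
        lab[4, 4, 4] = 8   # cerebellar GM label on WM tissue -> becomes 7
        lab[0, 2, 2] = 7   # cerebellar WM label on GM tissue -> becomes 8
        out = clean_warped_parcellation(LabelVolume(grid, lab), TissueMap(grid, tis),
                                        _table())
        assert out.labels[4, 4, 4] == 7
        assert out.labels[0, 2, 2] == 8

    def test_labels_never_on_background_or_csf(self):
        grid = _grid(8)
        tis = np.zeros(grid.dims, np.int32)  # all background
        tis[0, 0, 0] = 1  # CSF
        lab = np.full(grid.dims, 1001, np.int32)
        out = clean_warped_parcellation(LabelVolume(grid, lab), TissueMap(grid, tis),
                                        _table())
        assert out.labels.sum() == 0

    def test_cerebellar_gm_completion_threshold_strict(self):
        # an unlabeled GM voxel adopts cerebellar GM iff > 5 cb-WM in its 7x7x7
        grid = _grid(11)
        tis = np.full(grid.dims, GREY, dtype=np.int32)
        for n_wm, expected in [(6, 8), (5, 0)]:
            lab = np.zeros(grid.dims, np.int32)
            for i in range(n_wm):
                tis[3 + i, 3, 3] = WHITE
                lab[3 + i, 3, 3] = 7
            out = clean_warped_parcellation(LabelVolume(grid, lab),
                                            TissueMap(grid, tis), _table())
            assert out.labels[5, 5, 5] == expected, n_wm
            tis[:] = GREY

    def test_cerebellar_wm_region_growing_reaches_connected_wm(self):
        grid = _grid(10)
        tis = np.full(grid.dims, 0, dtype=np.int32)
        tis[2:8, 5, 5] = WHITE   # a WM filament
        lab = np.zeros(grid.dims, np.int32)
        lab[2, 5, 5] = 7         # seed at one end
        out = clean_warped_parcellation(LabelVolume(grid, lab), TissueMap(grid, tis),
                                        _table())
        assert np.all(out.labels[2:8, 5, 5] == 7)


def _consistent_parcellation(sample):
    return sample.truth_parcellation, sample.truth_tissue


class TestFuseParcellations:
    def test_unanimity_fixed_point(self, phantom_sample):
        parc, tissue = _consistent_parcellation(phantom_sample)
        table = phantom_sample.label_table
        for n in (1, 3):
            result = fuse_parcellations([parc] * n, tissue, table)
            np.testing.assert_array_equal(result.parcellation.labels, parc.labels)

    def test_wm_majority(self):
        grid = _grid(8)
        tis = np.full(grid.dims, WHITE, dtype=np.int32)
        a = np.full(grid.dims, 2, np.int32)
        b = np.full(grid.dims, 7, np.int32)
        parcs = [LabelVolume(grid, a)] * 11 + [LabelVolume(grid, b)] * 9
        result = fuse_parcellations(parcs, TissueMap(grid, tis), _table())
        assert np.all(result.parcellation.labels == 2)

    def test_cerebellar_gm_override_quarter_rule(self):
        grid = _grid(8)
        tis = np.full(grid.dims, GREY, dtype=np.int32)
        cb = LabelVolume(grid, np.full(grid.dims, 8, np.int32))
        other = LabelVolume(grid, np.full(grid.dims, 1001, np.int32))
        # 6 of 20 cerebellar votes: 6 > 5 -> override
        result = fuse_parcellations([cb] * 6 + [other] * 14,
                                    TissueMap(grid, tis), _table())
        assert np.all(result.parcellation.labels == 8)
        # 5 of 20: no override; smoothing vote won by the majority label
        result = fuse_parcellations([cb] * 5 + [other] * 15,
                                    TissueMap(grid, tis), _table())
        assert np.all(result.parcellation.labels == 1001)

    def test_csf_and_background_stay_unlabeled(self, phantom_sample):
        parc, tissue = _consistent_parcellation(phantom_sample)
        result = fuse_parcellations([parc], tissue, phantom_sample.label_table)
        outside = tissue.labels == 0
        assert np.all(result.parcellation.labels[outside] == 0)

    def test_empty_input_rejected(self, phantom_sample):
        with pytest.raises(ValueError):
            fuse_parcellations([], phantom_sample.truth_tissue,
                               phantom_sample.label_table)

    def test_tissue_consistency_and_improvement_over_individual_atlases(
            self, phantom_sample):
        """Fusing deformed pseudo-atlases beats the average individual atlas."""
        from pmmorph.phantom import make_atlas_set

        sample = phantom_sample
        table = sample.label_table
        tissue = sample.truth_tissue
        truth = sample.truth_parcellation.labels
        atlases = make_atlas_set(sample, 10, 1.0, seed=42)
        cleaned = [clean_warped_parcellation(a, tissue, table) for a, _ in atlases]
        result = fuse_parcellations(cleaned, tissue, table)
        fused = result.parcellation.labels

        wm_ids = set(table.wm_labels().tolist())
        gm_ids = set(table.gm_labels().tolist())
        reassigned = result.reassigned_to_gm
        for lab in np.unique(fused[fused > 0]):
            where = (fused == lab) & ~reassigned
            if lab in wm_ids:
                assert np.all(tissue.labels[where] == WHITE), lab
            elif lab in gm_ids:
                assert np.all(tissue.labels[where] == GREY), lab

        def mean_dice(pred):
            vals = []
            for lab in np.unique(truth[truth > 0]):
                a, b = pred == lab, truth == lab
                vals.append(2 * np.count_nonzero(a & b) / (a.sum() + b.sum()))
            return float(np.mean(vals))

        fused_dice = mean_dice(fused)
        individual = np.mean([mean_dice(a.labels) for a, _ in atlases])
        assert fused_dice > individual


class TestVoronoi:
    def _brute_force(self, lab, table, offset):
        gm_ids = np.sort(table.gm_labels())
        gm_points = {g: np.argwhere(lab == g) for g in gm_ids if (lab == g).any()}
        wm_mask = np.isin(lab, table.wm_labels(cerebellum=False))
        out = lab.copy()
        for p in np.argwhere(wm_mask):
            best_d, best_g = None, None
            for g, pts in gm_points.items():
                d = np.abs(pts - p).sum(axis=1).min()
                if best_d is None or d < best_d or (d == best_d and g < best_g):
                    best_d, best_g = d, g
            out[tuple(p)] = offset + best_g
        return out

    def test_matches_brute_force_on_random_parcellations(self, rng):
        table = _table()
        grid = _grid(12)
        for trial in range(20):
            lab = rng.choice([0, 2, 2, 2, 8, 10, 1001, 1002],
                             size=grid.dims).astype(np.int32)
            parc = LabelVolume(grid, lab)
            out, _ = voronoi_tessellate_wm(parc, table)
            expected = self._brute_force(lab, table, VORONOI_OFFSET)
            np.testing.assert_array_equal(out.labels, expected, err_msg=f"trial {trial}")

    def test_single_gm_region_takes_all_wm(self):
        grid = _grid(6)
        lab = np.full(grid.dims, 2, np.int32)
        lab[0, 0, 0] = 1001
        out, table2 = voronoi_tessellate_wm(LabelVolume(grid, lab), _table())
        wm = lab == 2
        assert np.all(out.labels[wm] == VORONOI_OFFSET + 1001)
        assert (VORONOI_OFFSET + 1001) in table2

    def test_nearer_region_wins(self):
        grid = _grid(8)
        lab = np.zeros(grid.dims, np.int32)
        lab[1, 1, 1] = 1001
        lab[7, 7, 7] = 1002
        lab[2, 2, 2] = 2  # L1 3 from A, 15 from B
        out, _ = voronoi_tessellate_wm(LabelVolume(grid, lab), _table())
        assert out.labels[2, 2, 2] == VORONOI_OFFSET + 1001

    def test_cerebellar_labels_untouched(self, phantom_sample):
        parc = phantom_sample.truth_parcellation
        out, _ = voronoi_tessellate_wm(parc, phantom_sample.label_table)
        cb = np.isin(parc.labels, [7, 8])
        np.testing.assert_array_equal(out.labels[cb], parc.labels[cb])

    def test_no_gm_rejected(self):
        grid = _grid(4)
        lab = np.full(grid.dims, 2, np.int32)
        with pytest.raises(ValueError, match="grey-matter"):
            voronoi_tessellate_wm(LabelVolume(grid, lab), _table())
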