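"""WMH fractions, corrective/imputed swaps, conservation properties."""

import numpy as np
import pandas as pd
import pytest

from pmmorph.core import BinaryMask, LabelVolume, VoxelGrid
from pmmorph.fusion import VORONOI_OFFSET
from pmmorph.wmh import (
    corrective_swap,
    imputed_swap,
    regional_wmh_fractions,
    replicate_to_invivo,
    sex_imbalance_tests,
    swap_deltas,
    wmh_age_correlation,
)


def _region_table(rows):
    return pd.DataFrame(rows, columns=["region", "name", "tissue_class",
                                       "volume_mm3", "wmh_mm3", "fraction",
                                       "voronoi_partner"])


def _basic_table(g_vol=100.0, g_wmh=10.0, v_vol=50.0, v_wmh=5.0):
    return _region_table([
        dict(region=1001, name="g", tissue_class="GM", volume_mm3=g_vol,
             wmh_mm3=g_wmh, fraction=g_wmh / g_vol, voronoi_partner=VORONOI_OFFSET + 1001),
        dict(region=VORONOI_OFFSET + 1001, name="Vg", tissue_class="WM",
             volume_mm3=v_vol, wmh_mm3=v_wmh, fraction=v_wmh / v_vol,
             voronoi_partner=np.nan),
    ])


class TestRegionalFractions:
    def test_half_covered_region(self, phantom_sample):
        grid = VoxelGrid((8, 8, 8), (0.5, 0.5, 0.5))
        lab = np.zeros(grid.dims, np.int32)
        lab[:4] = 1001
        wmh = np.zeros(grid.dims, np.int32)
        wmh[:2] = 1
        df = regional_wmh_fractions(BinaryMask(grid, wmh), LabelVolume(grid, lab),
                                    phantom_sample.label_table)
        row = df[df["region"] == 1001].iloc[0]
        assert row["fraction"] == pytest.approx(0.5)

    def test_empty_wmh_mask(self, phantom_sample):
        grid = phantom_sample.truth_parcellation.grid
        empty = BinaryMask(grid, np.zeros(grid.dims, np.int32))
        df = regional_wmh_fractions(empty, phantom_sample.truth_parcellation,
                                    phantom_sample.label_table)
        assert (df["fraction"] == 0).all()

    def test_100_voxel_blob_at_half_mm(self, phantom_sample):
        grid = VoxelGrid((10, 10, 10), (0.5, 0.5, 0.5))
        lab = np.full(grid.dims, 2, np.int32)
        wmh = np.zeros(grid.dims, np.int32)
        wmh.ravel()[:100] = 1
        df = regional_wmh_fractions(BinaryMask(grid, wmh), LabelVolume(grid, lab),
                                    phantom_sample.label_table)
        assert df.iloc[0]["wmh_mm3"] == pytest.approx(12.5)  # 100 x 0.125


class TestCorrectiveSwap:
    def test_bookkeeping_example(self):
        out, amounts = corrective_swap(_basic_table())
        out = out.set_index("region")
        assert out.at[1001, "volume_mm3"] == 90.0
        assert out.at[1001, "wmh_mm3"] == 0.0
        assert out.at[VORONOI_OFFSET + 1001, "volume_mm3"] == 60.0
        assert out.at[VORONOI_OFFSET + 1001, "wmh_mm3"] == 15.0
        assert amounts.at[1001] == 10.0

    def test_zero_wmh_is_identity(self):
        table = _basic_table(g_wmh=0.0, v_wmh=0.0)
        out, _ = corrective_swap(table)
        pd.testing.assert_frame_equal(out, table)

    def test_conservation_on_random_tables(self, rng):
        for _ in range(100):
            n = rng.integers(2, 10)
            rows = []
            for i in range(n):
                vol = float(rng.uniform(10, 1000))
                wmh = float(rng.uniform(0, vol))
                rows.append(dict(region=1000 + i, name=f"g{i}", tissue_class="GM",
                                 volume_mm3=vol, wmh_mm3=wmh, fraction=wmh / vol,
                                 voronoi_partner=VORONOI_OFFSET + 1000 + i))
                vol2 = float(rng.uniform(10, 1000))
                wmh2 = float(rng.uniform(0, vol2))
                rows.append(dict(region=VORONOI_OFFSET + 1000 + i, name=f"V{i}",
                                 tissue_class="WM", volume_mm3=vol2, wmh_mm3=wmh2,
                                 fraction=wmh2 / vol2, voronoi_partner=np.nan))
            table = _region_table(rows)
            out, _ = corrective_swap(table)
            assert out["volume_mm3"].sum() == pytest.approx(
                table["volume_mm3"].sum(), rel=1e-9)
            assert out["wmh_mm3"].sum() == pytest.approx(
                table["wmh_mm3"].sum(), rel=1e-9)
            assert (out["volume_mm3"] >= 0).all()

    def test_idempotent(self):
        once, _ = corrective_swap(_basic_table())
        twice, amounts = corrective_swap(once)
        pd.testing.assert_frame_equal(once, twice)
        assert amounts.sum() == 0.0

    def test_missing_partner_flagged_and_unchanged(self):
        table = _basic_table()
        table.loc[table["region"] == 1001, "voronoi_partner"] = np.nan
        with pytest.warns(UserWarning, match="no Voronoi partner"):
            out, _ = corrective_swap(table)
        assert out.set_index("region").at[1001, "volume_mm3"] == 100.0


class TestImputedSwap:
    def test_mean_of_references(self):
        refs = [(_basic_table(g_wmh=4.0), "F"), (_basic_table(g_wmh=8.0), "F"),
                (_basic_table(g_wmh=100.0), "M")]
        target = _basic_table(g_wmh=0.0, v_wmh=0.0)
        out = imputed_swap(refs, (target, "F"))
        out = out.set_index("region")
        assert out.at[1001, "volume_mm3"] == pytest.approx(94.0)  # swapped mean(4,8)=6
        assert out.at[VORONOI_OFFSET + 1001, "volume_mm3"] == pytest.approx(56.0)

    def test_zero_references_identity(self):
        refs = [(_basic_table(g_wmh=0.0), "M")]
        target = _basic_table(g_wmh=0.0, v_wmh=0.0)
        out = imputed_swap(refs, (target, "M"))
        pd.testing.assert_frame_equal(out, target)

    def test_no_same_sex_reference_rejected(self):
        with pytest.raises(ValueError, match="no reference"):
            imputed_swap([(_basic_table(), "M")], (_basic_table(), "F"))

    def test_clipping_at_available_volume(self):
        refs = [(_basic_table(g_vol=1000.0, g_wmh=500.0), "F")]
        target = _basic_table(g_vol=100.0, g_wmh=0.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = imputed_swap(refs, (target, "F"))
        out = out.set_index("region")
        assert out.at[1001, "volume_mm3"] == 0.0
        assert out.at[VORONOI_OFFSET + 1001, "volume_mm3"] == 150.0


class TestReplicateToInvivo:
    def test_zero_deltas_identity(self):
        table = _basic_table()
        out = replicate_to_invivo(pd.Series(0.0, index=[1001]), table)
        pd.testing.assert_frame_equal(out, table)

    def test_swap_deltas_replicated(self):
        before = _basic_table()
        after, _ = corrective_swap(before)
        deltas = swap_deltas(before, after)
        invivo = _basic_table(g_vol=200.0, g_wmh=0.0, v_vol=80.0, v_wmh=0.0)
        out = replicate_to_invivo(deltas, invivo).set_index("region")
        assert out.at[1001, "volume_mm3"] == 190.0
        assert out.at[VORONOI_OFFSET + 1001, "volume_mm3"] == 90.0

    def test_zero_sum_deltas_conserve_total(self, rng):
        for _ in range(20):
            table = _basic_table()
            d = float(rng.uniform(-5, 5))
            deltas = pd.Series([d, -d], index=[1001, VORONOI_OFFSET + 1001])
            out = replicate_to_invivo(deltas, table)
            assert out["volume_mm3"].sum() == pytest.approx(
                table["volume_mm3"].sum(), rel=1e-12)

    def test_missing_region_flagged(self):
        with pytest.warns(UserWarning, match="absent"):
            replicate_to_invivo(pd.Series([1.0], index=[9999]), _basic_table())


class TestStatWrappers:
    def test_wilcoxon_bonferroni(self, rng):
        data = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        sexes = pd.Series(["M"] * 15 + ["F"] * 15)
        out = sex_imbalance_tests(data, sexes)
        assert len(out) == 4
        assert (out["p_bonferroni"] >= out["p_value"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_spearman_increasing(self):
        x = pd.Series(np.arange(20, dtype=float))
        res = wmh_age_correlation(x, x ** 3)
        assert res["rho"] == pytest.approx(1.0)
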