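"""Regional white-matter-hyperintensity accounting.

WMH voxels look grey on T2, so intensity-driven tissue maps misplace them
into grey-matter regions during parcellation.  The accounting here
measures WMH volume per region, then *swaps* each grey-matter region's
WMH volume into its L1-nearest Voronoi white-matter sub-region — a
table-level volume bookkeeping, not a voxel relabeling, so the same
operation applies to donors whose swap amounts are imputed from same-sex
donors with masks.  Total tissue volume and total WMH volume are conserved
by every operation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, LabelTable, LabelVolume
from .fusion import VORONOI_OFFSET

__all__ = [
    "regional_wmh_fractions",
    "corrective_swap",
    "imputed_swap",
    "replicate_to_invivo",
    "sex_imbalance_tests",
    "wmh_age_correlation",
]

REGION_COLUMNS = ["region", "name", "tissue_class", "volume_mm3", "wmh_mm3",
                  "fraction", "voronoi_partner"]


def regional_wmh_fractions(wmh_mask: BinaryMask, parcellation: LabelVolume,
                           table: LabelTable) -> pd.DataFrame:
    """Per-region volume, WMH volume and WMH fraction.

    ``table`` should be the Voronoi-extended label table so that each
    grey-matter region can be paired with its ``voronoi_partner``
    (``VORONOI_OFFSET + label``) when that sub-region exists.
    """
    wmh_mask.grid.require_compatible(parcellation.grid)
    lab = parcellation.labels
    if not (lab > 0).any():
        raise ValueError("empty parcellation")
    vox = parcellation.grid.voxel_volume_mm3
    ids = parcellation.present_labels()
    counts = np.bincount(lab.ravel(), minlength=lab.max() + 1)
    overlap = np.bincount(lab.ravel(), weights=wmh_mask.labels.ravel().astype(float),
                          minlength=lab.max() + 1)
    rows = []
    present = set(ids.tolist())
    for rid in ids:
        meta = table.df.loc[int(rid)] if int(rid) in table else None
        volume = counts[rid] * vox
        wmh = overlap[rid] * vox
        partner = np.nan
        tclass = meta["tissue_class"] if meta is not None else ""
        if meta is not None and tclass == "GM" and (VORONOI_OFFSET + rid) in present:
            partner = VORONOI_OFFSET + int(rid)
        rows.append(dict(region=int(rid),
                         name=meta["name"] if meta is not None else f"label-{rid}",
                         tissue_class=tclass, volume_mm3=float(volume),
                         wmh_mm3=float(wmh), fraction=float(wmh / volume),
                         voronoi_partner=partner))
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def _indexed(df: pd.DataFrame) -> pd.DataFrame:
    return df.set_index("region", drop=False)


def corrective_swap(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Move each GM region's WMH volume into its Voronoi WM partner.

    For a GM region ``g`` with WMH volume ``w``: ``volume[g] -= w``,
    ``volume[V(g)] += w``, ``wmh[g] = 0``, ``wmh[V(g)] += w``.  GM regions
    with WMH but no partner are flagged and left unchanged.  Returns the
    swapped table and the per-GM-region swap amounts (mm^3).
    """
    out = _indexed(table.copy())
    amounts = pd.Series(0.0, index=out.index[out["tissue_class"] == "GM"], name="swap_mm3")
    for rid, row in out[out["tissue_class"] == "GM"].iterrows():
        w = row["wmh_mm3"]
        if w <= 0:
            continue
        partner = row["voronoi_partner"]
        if pd.isna(partner) or int(partner) not in out.index:
            warnings.warn(f"GM region {rid} has WMH but no Voronoi partner; left unchanged",
                          stacklevel=2)
            continue
        partner = int(partner)
        out.at[rid, "volume_mm3"] -= w
        out.at[rid, "wmh_mm3"] = 0.0
        out.at[partner, "volume_mm3"] += w
        out.at[partner, "wmh_mm3"] += w
        amounts.at[rid] = w
    _refresh_fraction(out)
    return out.reset_index(drop=True), amounts


def _refresh_fraction(df: pd.DataFrame) -> None:
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(df["volume_mm3"] > 0, df["wmh_mm3"] / df["volume_mm3"], 0.0)
    df["fraction"] = frac


def imputed_swap(tables_with_sex: list[tuple[pd.DataFrame, str]],
                 target: tuple[pd.DataFrame, str]) -> pd.DataFrame:
    """Apply sex-averaged swap amounts to a donor without a WMH mask.

    The amount swapped for each GM region is the mean, over same-sex
    reference donors, of the amount :func:`corrective_swap` moved for that
    region.  Amounts are clipped at the target region's available volume
    (clip events reported via warning).
    """
    target_df, target_sex = target
    refs = [df for df, sex in tables_with_sex if sex == target_sex]
    if not refs:
        raise ValueError(f"no reference donors of sex {target_sex!r}")
    amount_series = [corrective_swap(df)[1] for df in refs]
    mean_amounts = pd.concat(amount_series, axis=1).fillna(0.0).mean(axis=1)

    out = _indexed(target_df.copy())
    for rid, w in mean_amounts.items():
        if w <= 0 or rid not in out.index:
            continue
        partner = out.at[rid, "voronoi_partner"]
        if pd.isna(partner) or int(partner) not in out.index:
            continue
        avail = out.at[rid, "volume_mm3"]
        if w > avail:
            warnings.warn(f"swap for region {rid} clipped from {w:.1f} to {avail:.1f} mm3",
                          stacklevel=2)
            w = avail
        partner = int(partner)
        out.at[rid, "volume_mm3"] -= w
        out.at[partner, "volume_mm3"] += w
        out.at[partner, "wmh_mm3"] += min(w, out.at[rid, "wmh_mm3"]) \
            if out.at[rid, "wmh_mm3"] > 0 else 0.0
        out.at[rid, "wmh_mm3"] = max(0.0, out.at[rid, "wmh_mm3"] - w)
    _refresh_fraction(out)
    return out.reset_index(drop=True)


def replicate_to_invivo(postmortem_delta: pd.Series,
                        invivo_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the postmortem per-region volume deltas to an in vivo table."""
    out = _indexed(invivo_table.copy())
    missing = [rid for rid in postmortem_delta.index if rid not in out.index]
    if missing:
        warnings.warn(f"regions {missing} absent from the in vivo table; their deltas "
                      "were skipped", stacklevel=2)
    for rid, d in postmortem_delta.items():
        if rid in out.index:
            out.at[rid, "volume_mm3"] += d
    _refresh_fraction(out)
    return out.reset_index(drop=True)


def swap_deltas(before: pd.DataFrame, after: pd.DataFrame) -> pd.Series:
    """Per-region volume change between two region tables (after - before)."""
    b = _indexed(before)["volume_mm3"]
    a = _indexed(after)["volume_mm3"]
    return (a - b).rename("delta_mm3")


# ---------------------------------------------------------------------------
# Thin statistical wrappers


def sex_imbalance_tests(wmh_by_region: pd.DataFrame, sexes: pd.Series,
                        n_tests: int | None = None) -> pd.DataFrame:
    """Wilcoxon rank-sum of WMH volume (men vs women) per Voronoi region.

    ``wmh_by_region``: donors x regions matrix of WMH volumes.  Bonferroni
    correction is applied over ``n_tests`` (default: the number of region
    columns, following the convention of correcting over the Voronoi
    region family).
    """
    n_tests = n_tests or wmh_by_region.shape[1]
    men = sexes == "M"
    rows = []
    for region in wmh_by_region.columns:
        x = wmh_by_region.loc[men, region]
        y = wmh_by_region.loc[~men, region]
        stat, p = stats.ranksums(x, y)
        rows.append(dict(region=region, statistic=stat, p_value=p,
                         p_bonferroni=min(1.0, p * n_tests)))
    return pd.DataFrame(rows)


def wmh_age_correlation(wmh_volumes: pd.Series, ages: pd.Series) -> dict:
    """Spearman rank correlation of WMH volume with age at death."""
    rho, p = stats.spearmanr(wmh_volumes, ages)
    return {"rho": float(rho), "p_value": float(p), "n": int(len(wmh_volumes))}
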