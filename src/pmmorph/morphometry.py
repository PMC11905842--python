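"""Regional volume aggregation and robust morphometry models.

Volumes are modeled with robust linear regression (Huber norm, tuning
constant 1.345, asymptotic normal inference) rather than ordinary least
squares: postmortem parcellations contain occasional gross failures, and
down-weighting outliers keeps coefficient estimates stable at desk-size
cohorts.  The main model expresses a regional volume as

    volume ~ intercept + sex(F) + age + invivo + AD + FTD + OD + VD + M

where ``sex(F)`` is 1 for women, ``invivo`` flags volumes measured in
antemortem clinical scans, and the five binary diagnosis indicators are
not mutually exclusive (comorbidity allowed; ``M`` marks a missing
diagnosis, in which case the other four are zero).  The age/neuropathology
relation is modeled the other way around — age as a quadratic in the sum
of scores s = Thal + Braak + CERAD — with a second robust quadratic fit of
the absolute prediction error providing an uncertainty band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import LabelTable, LabelVolume

__all__ = [
    "DEEP_GM_LABELS",
    "CEREBELLUM_LABELS",
    "HIPPOCAMPUS_LABEL",
    "aggregate_volumes",
    "RobustFit",
    "fit_robust_linear",
    "fit_morphometry_model",
    "AgeScoreFit",
    "fit_age_score_band",
    "cohort_tests",
    "MORPHOMETRY_PREDICTORS",
]

#: deep grey matter = thalamus, caudate, putamen, pallidum, hippocampus,
#: amygdala, accumbens
DEEP_GM_LABELS = (10, 11, 12, 13, 17, 18, 26)
CEREBELLUM_LABELS = (7, 8)
HIPPOCAMPUS_LABEL = 17

MORPHOMETRY_PREDICTORS = ["sexF", "age", "invivo", "AD", "FTD", "OD", "VD", "M"]


def aggregate_volumes(parcellation: LabelVolume, table: LabelTable,
                      ) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Per-label volumes (mm^3) plus the named aggregates.

    Aggregates: ``total_brain`` (all labeled voxels), ``cerebrum_wm``
    (non-cerebellar WM labels), ``deep_gm`` (sum over the seven deep
    nuclei), ``hippocampus``, ``cerebellum`` (cerebellar WM + GM).  An
    aggregate whose required labels are absent is reported as ``None``
    rather than zero.
    """
    lab = parcellation.labels
    vox = parcellation.grid.voxel_volume_mm3
    counts = np.bincount(lab.ravel())
    ids = np.flatnonzero(counts)
    ids = ids[ids > 0]
    per_label = pd.DataFrame({
        "region": ids,
        "name": [table.name_of(i) if int(i) in table else f"label-{i}" for i in ids],
        "volume_mm3": counts[ids] * vox,
    })

    def vol_of(labels) -> float | None:
        labels = [l for l in labels]
        if any(counts[l] == 0 if l < len(counts) else True for l in labels):
            return None
        return float(sum(counts[l] for l in labels) * vox)

    cerebrum_wm_ids = [int(i) for i in table.wm_labels(cerebellum=False)
                       if i < len(counts) and counts[i] > 0]
    aggregates: dict[str, float | None] = {
        "total_brain": float(counts[ids].sum() * vox),
        "cerebrum_wm": float(sum(counts[i] for i in cerebrum_wm_ids) * vox)
        if cerebrum_wm_ids else None,
        "deep_gm": vol_of(DEEP_GM_LABELS),
        "hippocampus": vol_of([HIPPOCAMPUS_LABEL]),
        "cerebellum": vol_of(CEREBELLUM_LABELS),
    }
    return per_label, aggregates


def average_aggregates(per_scan: list[dict[str, float | None]]) -> dict[str, float | None]:
    """Arithmetic mean of aggregates over a donor's scans (None propagates)."""
    out = {}
    for key in per_scan[0]:
        vals = [d[key] for d in per_scan]
        out[key] = None if any(v is None for v in vals) else float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# Robust regression


@dataclass
class RobustFit:
    """Coefficient table of a Huber-norm robust linear fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    huber_t: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "p_value": self.pvalues})

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(X[[c for c in self.params.index if c != "const"]],
                            has_constant="add")
        return X.to_numpy() @ self.params.reindex(X.columns).to_numpy()


def fit_robust_linear(data: pd.DataFrame, response: str, predictors: list[str],
                      huber_t: float = 1.345) -> RobustFit:
    """Huber-loss iteratively reweighted least squares with normal inference."""
    data = data.dropna(subset=[response, *predictors])
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError(f"n={n} too small for {len(predictors)} predictors")
    X = sm.add_constant(data[predictors].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("singular design matrix")
    res = sm.RLM(data[response].astype(float), X,
                 M=sm.robust.norms.HuberT(t=huber_t)).fit()
    return RobustFit(params=res.params, bse=res.bse, pvalues=res.pvalues,
                     nobs=int(res.nobs), huber_t=huber_t)


def fit_morphometry_model(volumes: pd.DataFrame, records: pd.DataFrame,
                          region: str, huber_t: float = 1.345) -> RobustFit:
    """Fit the regional-volume model on a merged volumes/records table.

    ``volumes`` must carry columns donor/invivo/age_scan/<region>;
    ``records`` carries sex and the diagnosis indicators.  In vivo
    observations inherit their donor's postmortem diagnosis.
    """
    merged = volumes.merge(
        records[["donor", "sex", "AD", "FTD", "OD", "VD", "M"]], on="donor")
    merged["sexF"] = (merged["sex"] == "F").astype(float)
    merged = merged.rename(columns={"age_scan": "age"})
    return fit_robust_linear(merged, region, MORPHOMETRY_PREDICTORS, huber_t)


# ---------------------------------------------------------------------------
# Age vs neuropathology-score quadratic with absolute-error band


@dataclass
class AgeScoreFit:
    age_fit: RobustFit     # age ~ s + s^2
    error_fit: RobustFit   # |age - predicted| ~ s + s^2
    negative_error_floored: int = 0

    def predicted(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        a = self.age_fit.params
        return a["const"] + a["s"] * s + a["s2"] * s ** 2

    def band(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper): prediction minus/plus the fitted absolute error.

        Negative error predictions are floored at zero (and counted in
        ``negative_error_floored``), so the band always contains the
        point prediction.
        """
        s = np.asarray(s, dtype=float)
        e = self.error_fit.params
        err = e["const"] + e["s"] * s + e["s2"] * s ** 2
        err = np.maximum(err, 0.0)
        mid = self.predicted(s)
        return mid - err, mid + err


def fit_age_score_band(records: pd.DataFrame, huber_t: float = 1.345) -> AgeScoreFit:
    """Two-step robust quadratic fit of age on the sum of scores."""
    df = records.dropna(subset=["age_death", "sum_scores"]).copy()
    if len(df) < 4:
        raise ValueError("need at least 4 donors with scores and ages")
    if df["sum_scores"].nunique() < 3:
        raise ValueError("sum of scores nearly constant: quadratic design singular")
    df["s"] = df["sum_scores"].astype(float)
    df["s2"] = df["s"] ** 2
    age_fit = fit_robust_linear(df, "age_death", ["s", "s2"], huber_t)
    a = age_fit.params
    pred = a["const"] + a["s"] * df["s"] + a["s2"] * df["s2"]
    df["abs_err"] = np.abs(df["age_death"] - pred)
    error_fit = fit_robust_linear(df, "abs_err", ["s", "s2"], huber_t)
    e = error_fit.params
    err_vals = e["const"] + e["s"] * df["s"] + e["s2"] * df["s2"]
    return AgeScoreFit(age_fit=age_fit, error_fit=error_fit,
                       negative_error_floored=int((err_vals < 0).sum()))


# ---------------------------------------------------------------------------
# Cohort descriptive tests


def cohort_tests(records: pd.DataFrame,
                 welch_columns: tuple[str, ...] = ("age_death", "sum_scores",
                                                   "thal", "braak", "cerad"),
                 n_tests: int | None = None) -> pd.DataFrame:
    """Welch t-tests (men vs women) and Fisher exact subgroup tests.

    Returns one row per test with the statistic, p-value and the
    Bonferroni-corrected p over the declared family size (default: the
    number of tests actually run).
    """
    men = records["sex"] == "M"
    rows = []
    for col in welch_columns:
        x, y = records.loc[men, col].dropna(), records.loc[~men, col].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append(dict(test=f"welch:{col}", statistic=np.nan, p_value=np.nan,
                             note="degenerate group"))
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(dict(test=f"welch:{col}", statistic=float(t), p_value=float(p),
                         note=""))
    n_all = len(records)
    n_men = int(men.sum())
    for flag in ("AD", "FTD", "OD", "VD", "M", "invivo_available"):
        if flag not in records:
            continue
        sub = records[records[flag] == 1]
        tab = [[int((sub["sex"] == "M").sum()), int((sub["sex"] == "F").sum())],
               [n_men, n_all - n_men]]
        odds, p = stats.fisher_exact(tab)
        rows.append(dict(test=f"fisher:{flag}", statistic=float(odds),
                         p_value=float(p), note=""))
    out = pd.DataFrame(rows)
    family = n_tests or len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * family)
    return out


def spearman(x: pd.Series, y: pd.Series) -> dict:
    rho, p = stats.spearmanr(x, y, nan_policy="omit")
    return {"rho": float(rho), "p_value": float(p)}
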