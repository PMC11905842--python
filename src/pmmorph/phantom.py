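"""Synthetic brain-in-formalin phantoms with complete ground truth.

The generator emulates the properties the postmortem pipeline actually
exploits, not anatomy: a dark air shell around a formalin bath that is
bright in T2 and darker than tissue in T1; voxel-scale tissue texture
against centimeter-scale formalin artifacts; a hemisphere-like forebrain
(grey-matter shell over a white-matter core with deep grey nuclei) and a
cerebellum detached from it by a formalin-filled gap; white-matter
hyperintensity blobs whose T2 intensity mimics grey matter, reproducing
the tissue-misclassification failure mode of intensity-driven tissue
segmentation.  A cohort simulator draws donor demographics, neuropathology
scores, and regional volumes from the same linear/quadratic generative
models that the morphometry stage fits, so parameter recovery can be
tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    GREY,
    WHITE,
    BinaryMask,
    LabelTable,
    LabelVolume,
    ScalarVolume,
    TissueMap,
    VoxelGrid,
)

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "CohortSpec",
    "make_phantom",
    "make_atlas_set",
    "make_cohort",
    "CEREBRUM_WM_LABEL",
    "CEREBELLUM_WM_LABEL",
    "CEREBELLUM_GM_LABEL",
    "DEEP_GM_LABELS",
]

# label ids follow the whole-brain atlas convention the morphometry stage
# expects: 2 = cerebrum WM, 7/8 = cerebellar WM/GM, deep grey nuclei
# 10,11,12,13,17,18,26, cortical parcels from 1001.
CEREBRUM_WM_LABEL = 2
CEREBELLUM_WM_LABEL = 7
CEREBELLUM_GM_LABEL = 8
DEEP_GM_LABELS = {
    10: "thalamus",
    11: "caudate",
    12: "putamen",
    13: "pallidum",
    17: "hippocampus",
    18: "amygdala",
    26: "accumbens",
}
CORTICAL_LABELS = {1001: "cortex-anterior-superior", 1002: "cortex-posterior-superior",
                   1003: "cortex-anterior-inferior", 1004: "cortex-posterior-inferior"}

_COMPARTMENTS = ("air", "formalin", "gm", "wm", "cereb_gm", "cereb_wm", "wmh")

# (T1 mean, T2 mean, texture sd) per compartment.  Formalin is bright in
# T2 and darker than white matter in T1; WMH shares the grey-matter T2
# range so it confuses intensity-based tissue classification.
_DEFAULT_INTENSITIES: dict[str, tuple[float, float, float]] = {
    "air": (0.02, 0.02, 0.01),
    "formalin": (0.20, 1.00, 0.01),
    "gm": (0.50, 0.60, 0.05),
    "wm": (0.72, 0.38, 0.05),
    "cereb_gm": (0.52, 0.62, 0.05),
    "cereb_wm": (0.70, 0.40, 0.05),
    "wmh": (0.62, 0.60, 0.05),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic two-modality sample."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    intensities: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_INTENSITIES)
    )
    formalin_artifact_amplitude: float = 0.08
    formalin_artifact_scale_voxels: float = 12.0
    cerebellum_gap_voxels: int = 3
    wmh_count: int = 3
    wmh_radius_voxels: tuple[float, float] = (1.5, 3.0)
    bias_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        inten = dict(self.intensities)
        missing = set(_COMPARTMENTS) - set(inten)
        if missing:
            raise ValueError(f"intensities missing compartments {sorted(missing)}")
        t1 = {c: inten[c][0] for c in _COMPARTMENTS}
        t2 = {c: inten[c][1] for c in _COMPARTMENTS}
        if not (t2["formalin"] > t2["gm"] and t2["formalin"] > t2["wm"]):
            raise ValueError("T2 formalin mean must exceed T2 grey- and white-matter means")
        if not t1["formalin"] < t1["wm"]:
            raise ValueError("T1 formalin mean must be below the T1 white-matter mean")
        if self.formalin_artifact_scale_voxels < 10:
            raise ValueError("formalin artifact scale must be >= 10 voxels (centimeter-wide)")
        if self.cerebellum_gap_voxels < 1:
            raise ValueError("cerebellum gap must be >= 1 voxel")
        if self.wmh_radius_voxels[0] > self.wmh_radius_voxels[1]:
            raise ValueError("wmh radius range inverted")
        object.__setattr__(self, "intensities", inten)


@dataclass
class PhantomSample:
    """A phantom scan pair plus every ground-truth volume the pipeline needs.

    ``degraded_tissue`` is the tissue map an intensity-driven classifier
    would produce: identical to ``truth_tissue`` except that WMH voxels
    are marked grey matter.
    """

    t1: ScalarVolume
    t2: ScalarVolume
    truth_mask: BinaryMask
    truth_tissue: TissueMap
    truth_parcellation: LabelVolume
    label_table: LabelTable
    wmh_mask: BinaryMask
    degraded_tissue: TissueMap


def _ellipsoid(grid_shape, center, semi_axes) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    acc = np.zeros(grid_shape)
    for ax in range(3):
        acc += ((coords[ax] - center[ax]) / semi_axes[ax]) ** 2
    return acc <= 1.0


def default_label_table(include_wmh_subregions: bool = False) -> LabelTable:
    rows = [
        dict(label=CEREBRUM_WM_LABEL, name="cerebrum-white-matter", tissue_class="WM",
             hemisphere="left", is_cerebellum=False, is_cortical=False),
        dict(label=CEREBELLUM_WM_LABEL, name="cerebellum-white-matter", tissue_class="WM",
             hemisphere="left", is_cerebellum=True, is_cortical=False),
        dict(label=CEREBELLUM_GM_LABEL, name="cerebellum-cortex", tissue_class="GM",
             hemisphere="left", is_cerebellum=True, is_cortical=False),
    ]
    for lab, name in DEEP_GM_LABELS.items():
        rows.append(dict(label=lab, name=name, tissue_class="GM", hemisphere="left",
                         is_cerebellum=False, is_cortical=False))
    for lab, name in CORTICAL_LABELS.items():
        rows.append(dict(label=lab, name=name, tissue_class="GM", hemisphere="left",
                         is_cerebellum=False, is_cortical=True))
    return LabelTable.from_rows(rows)


def make_phantom(spec: PhantomSpec | None = None) -> PhantomSample:
    """Generate one deterministic two-modality phantom per ``spec``."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    dims = spec.dims
    grid = VoxelGrid(dims, spec.spacing)
    scale = min(dims) / 64.0

    center = np.array(dims) / 2.0 - 0.5
    # formalin bag
    bag = _ellipsoid(dims, center, np.array(dims) * 0.44)

    # forebrain: GM shell over WM core, shifted superior (axis 2), cut to a
    # hemisphere-like flat medial face on axis 0
    fb_center = center + np.array([0.0, 0.0, 6.0 * scale])
    fb_semi = np.array([20.0, 18.0, 16.0]) * scale
    forebrain = _ellipsoid(dims, fb_center, fb_semi)
    forebrain &= np.indices(dims)[0] <= int(center[0] + 12 * scale)
    wm_core = _ellipsoid(dims, fb_center, fb_semi * 0.65)
    wm_core &= forebrain
    gm_shell = forebrain & ~wm_core

    # cerebellum detached below the forebrain by >= gap voxels of formalin
    fb_zmin = int(np.flatnonzero(forebrain.any(axis=(0, 1)))[0])
    cb_radius = 8.0 * scale
    cb_cz = fb_zmin - spec.cerebellum_gap_voxels - cb_radius - 1
    if cb_cz - cb_radius < 1:
        raise ValueError("cerebellum gap too large for these dims")
    cb_center = np.array([center[0], center[1], cb_cz])
    cerebellum = _ellipsoid(dims, cb_center, np.array([cb_radius] * 3))
    cerebellum &= bag
    cb_wm = _ellipsoid(dims, cb_center, np.array([4.0, 4.0, 5.0]) * scale) & cerebellum
    cb_gm = cerebellum & ~cb_wm

    # deep grey nuclei inside the WM core
    offsets = {
        10: (0.0, 0.0, 0.0), 11: (-4.5, 3.5, 2.0), 12: (-4.5, -3.5, 2.0),
        13: (4.0, 4.0, -2.0), 17: (4.0, -4.0, -2.0), 18: (0.0, 5.5, -3.5),
        26: (0.0, -5.5, -3.5),
    }
    parcellation = np.zeros(dims, dtype=np.int32)
    parcellation[wm_core] = CEREBRUM_WM_LABEL
    for lab, off in offsets.items():
        nucleus = _ellipsoid(dims, fb_center + np.array(off) * scale,
                             np.array([2.2, 2.2, 2.2]) * scale)
        nucleus &= wm_core
        parcellation[nucleus] = lab

    # cortical parcels: GM shell split by quadrant around the forebrain center
    idx = np.indices(dims)
    ant = idx[1] >= fb_center[1]
    sup = idx[2] >= fb_center[2]
    parcellation[gm_shell & ant & sup] = 1001
    parcellation[gm_shell & ~ant & sup] = 1002
    parcellation[gm_shell & ant & ~sup] = 1003
    parcellation[gm_shell & ~ant & ~sup] = 1004
    parcellation[cb_wm] = CEREBELLUM_WM_LABEL
    parcellation[cb_gm] = CEREBELLUM_GM_LABEL

    brain = forebrain | cerebellum
    deep_gm_mask = np.isin(parcellation, list(DEEP_GM_LABELS))
    gm_tissue = gm_shell | cb_gm | deep_gm_mask
    wm_tissue = brain & ~gm_tissue

    # WMH blobs: spheres fully inside cerebrum WM, away from nuclei
    cerebrum_wm = parcellation == CEREBRUM_WM_LABEL
    depth = ndimage.distance_transform_edt(cerebrum_wm)
    wmh = np.zeros(dims, dtype=bool)
    for _ in range(spec.wmh_count):
        r = rng.uniform(*spec.wmh_radius_voxels)
        candidates = np.argwhere(depth > r + 0.5)
        if candidates.size == 0:
            raise ValueError("wmh radius exceeds the white-matter extent")
        c = candidates[rng.integers(len(candidates))]
        wmh |= _ellipsoid(dims, c.astype(float), np.array([r] * 3))
    wmh &= cerebrum_wm

    # compartment index map drives intensity synthesis
    comp = np.zeros(dims, dtype=np.int8)  # 0 air
    comp[bag] = 1
    comp[gm_shell | deep_gm_mask] = 2
    comp[wm_tissue & forebrain] = 3
    comp[cb_gm] = 4
    comp[cb_wm] = 5
    comp[wmh] = 6
    comp_names = ("air", "formalin", "gm", "wm", "cereb_gm", "cereb_wm", "wmh")

    vols = []
    for mod in (0, 1):  # T1, T2
        img = np.zeros(dims, dtype=float)
        for ci, name in enumerate(comp_names):
            mean, sd = spec.intensities[name][mod], spec.intensities[name][2]
            region = comp == ci
            img[region] = mean + sd * rng.standard_normal(int(region.sum()))
        # centimeter-scale formalin artifact
        art = ndimage.gaussian_filter(rng.standard_normal(dims),
                                      spec.formalin_artifact_scale_voxels)
        rms = np.sqrt((art ** 2).mean())
        if rms > 0:
            art *= spec.formalin_artifact_amplitude / rms
        img[comp == 1] += art[comp == 1]
        if spec.bias_amplitude > 0:
            gain = ndimage.gaussian_filter(rng.standard_normal(dims), 16.0)
            gain = 1.0 + spec.bias_amplitude * gain / np.sqrt((gain ** 2).mean())
            img *= gain
        vols.append(ScalarVolume(grid, np.clip(img, 0.0, None)))

    tissue = np.zeros(dims, dtype=np.int32)
    tissue[gm_tissue] = GREY
    tissue[wm_tissue] = WHITE
    degraded = tissue.copy()
    degraded[wmh] = GREY

    return PhantomSample(
        t1=vols[0],
        t2=vols[1],
        truth_mask=BinaryMask(grid, brain.astype(np.int32)),
        truth_tissue=TissueMap(grid, tissue),
        truth_parcellation=LabelVolume(grid, parcellation),
        label_table=default_label_table(),
        wmh_mask=BinaryMask(grid, wmh.astype(np.int32)),
        degraded_tissue=TissueMap(grid, degraded),
    )


# ---------------------------------------------------------------------------
# Pseudo-atlases with controlled registration error


def make_atlas_set(
    sample: PhantomSample,
    n_atlases: int,
    deformation_amplitude_mm: float,
    seed: int = 0,
    field_scale_voxels: float = 6.0,
) -> list[tuple[LabelVolume, ScalarVolume]]:
    """Warp the truth parcellation through smooth random displacement fields.

    Each atlas applies an independent Gaussian-filtered random displacement
    field whose root-mean-square magnitude equals ``deformation_amplitude_mm``;
    labels are pulled back by nearest neighbor, emulating the small
    registration errors of deformable atlas warping.  Amplitude 0
    reproduces the truth exactly.
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    if deformation_amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    truth = sample.truth_parcellation
    dims = truth.grid.dims
    spacing = np.asarray(truth.grid.spacing)
    base = np.indices(dims, dtype=float)
    truth_ids = set(truth.present_labels().tolist())

    out = []
    for _ in range(n_atlases):
        disp_mm = np.stack([
            ndimage.gaussian_filter(rng.standard_normal(dims), field_scale_voxels)
            for _ in range(3)
        ])
        rms = np.sqrt((disp_mm ** 2).sum(axis=0).mean())
        if rms > 0 and deformation_amplitude_mm > 0:
            disp_mm *= deformation_amplitude_mm / rms
        else:
            disp_mm[:] = 0.0
        src = base + disp_mm / spacing[:, None, None, None]
        src = np.rint(src).astype(int)
        for ax in range(3):
            np.clip(src[ax], 0, dims[ax] - 1, out=src[ax])
        warped = truth.labels[src[0], src[1], src[2]]
        lost = truth_ids - set(np.unique(warped).tolist())
        if lost:
            raise ValueError(f"deformation amplitude erased labels {sorted(lost)}")
        template = sample.t1.values[src[0], src[1], src[2]]
        out.append((LabelVolume(truth.grid, warped),
                    ScalarVolume(truth.grid, template)))
    return out


# ---------------------------------------------------------------------------
# Cohort simulator


#: Eq.-style generator coefficients per aggregate region, patterned on the
#: study's fitted morphometry models (mm^3; zero where no effect was seen).
DEFAULT_REGION_MODELS: dict[str, dict[str, float]] = {
    "brain": dict(intercept=5.85e5, age=0.0, sexF=-7.52e4, invivo=6.96e4,
                  AD=0.0, FTD=0.0, OD=0.0, VD=0.0, M=0.0, noise_sd=3.0e4),
    "cerebrum_wm": dict(intercept=2.53e5, age=0.0, sexF=-4.16e4, invivo=0.0,
                        AD=0.0, FTD=0.0, OD=0.0, VD=0.0, M=0.0, noise_sd=2.0e4),
    "deep_gm": dict(intercept=2.66e4, age=-1.05e2, sexF=-1.90e3, invivo=-2.12e3,
                    AD=0.0, FTD=-3.02e3, OD=0.0, VD=0.0, M=0.0, noise_sd=2.5e3),
    "hippocampus": dict(intercept=4.87e3, age=-1.65e1, sexF=-3.88e2, invivo=1.39e3,
                        AD=-4.25e2, FTD=-1.10e3, OD=0.0, VD=0.0, M=0.0, noise_sd=5.0e2),
    "cerebellum": dict(intercept=7.07e4, age=-1.91e2, sexF=-7.65e3, invivo=-3.67e3,
                       AD=0.0, FTD=0.0, OD=0.0, VD=0.0, M=0.0, noise_sd=7.0e3),
}

#: age = a + b*s + c*s^2 + noise, s = Thal + Braak + CERAD in [0, 14]
DEFAULT_AGE_SCORE_MODEL = dict(intercept=60.0, s=3.2, s2=-0.13, noise_sd=8.0)


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a simulated donor cohort."""

    n_donors: int = 92
    female_fraction: float = 47 / 92
    missing_diagnosis_fraction: float = 15 / 92
    diagnosis_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"AD": 51 / 77, "FTD": 7 / 77, "OD": 21 / 77, "VD": 10 / 77}
    )
    invivo_fraction: float = 31 / 92
    invivo_age_gap_years: float = 3.83
    region_models: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_MODELS.items()}
    )
    age_score_model: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SCORE_MODEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        for frac in (self.female_fraction, self.missing_diagnosis_fraction,
                     self.invivo_fraction, *self.diagnosis_prevalence.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        for name, model in self.region_models.items():
            if model.get("noise_sd", 0.0) < 0:
                raise ValueError(f"negative noise sd for region {name}")
        if self.age_score_model.get("noise_sd", 0.0) < 0:
            raise ValueError("negative age noise sd")


def _draw_scores(rng: np.random.Generator, n: int) -> pd.DataFrame:
    thal = np.clip(np.rint(rng.normal(3.8, 1.5, n)), 0, 5).astype(int)
    braak = np.clip(np.rint(rng.normal(4.6, 1.5, n)), 0, 6).astype(int)
    cerad = np.clip(np.rint(rng.normal(1.9, 1.0, n)), 0, 3).astype(int)
    return pd.DataFrame({"thal": thal, "braak": braak, "cerad": cerad})


def make_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate donor records and per-observation regional volumes.

    Returns ``(records, volumes)``: one record row per donor, and one
    volumes row per observation (each donor has a postmortem observation;
    a subset gains an in vivo observation at an earlier scan age).  Ages
    follow the quadratic age-versus-score model; volumes follow the linear
    morphometry generator per region.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_donors

    sexF = (rng.random(n) < spec.female_fraction).astype(int)
    if len(np.unique(sexF)) < 2 and any(
        m.get("sexF", 0.0) != 0.0 for m in spec.region_models.values()
    ):
        raise ValueError("degenerate cohort: a sex effect is requested but all "
                         "donors drew the same sex")
    scores = _draw_scores(rng, n)
    s = scores.sum(axis=1).to_numpy()
    asm = spec.age_score_model
    age_death = (asm["intercept"] + asm["s"] * s + asm["s2"] * s ** 2
                 + asm["noise_sd"] * rng.standard_normal(n))
    age_death = np.clip(age_death, 40.0, 105.0)

    missing = rng.random(n) < spec.missing_diagnosis_fraction
    diag = {d: np.zeros(n, dtype=int) for d in ("AD", "FTD", "OD", "VD")}
    for i in range(n):
        if missing[i]:
            continue
        flags = {d: rng.random() < p for d, p in spec.diagnosis_prevalence.items()}
        if not any(flags.values()):
            flags["AD"] = True  # every non-missing donor carries >= 1 dementia
        for d in diag:
            diag[d][i] = int(flags.get(d, False))

    invivo = rng.random(n) < spec.invivo_fraction
    age_scan_invivo = age_death - np.abs(
        rng.normal(spec.invivo_age_gap_years, 1.0, n)
    )

    records = pd.DataFrame({
        "donor": [f"D{i:03d}" for i in range(n)],
        "sex": np.where(sexF == 1, "F", "M"),
        "age_death": age_death,
        "invivo_available": invivo.astype(int),
        "age_scan_invivo": np.where(invivo, age_scan_invivo, np.nan),
        "AD": diag["AD"], "FTD": diag["FTD"], "OD": diag["OD"], "VD": diag["VD"],
        "M": missing.astype(int),
        "thal": scores["thal"], "braak": scores["braak"], "cerad": scores["cerad"],
        "sum_scores": s,
    })

    rows = []
    for i in range(n):
        obs = [(0, age_death[i])]
        if invivo[i]:
            obs.append((1, age_scan_invivo[i]))
        for is_invivo, age in obs:
            row = {"donor": records.at[i, "donor"], "invivo": is_invivo, "age_scan": age}
            for region, m in spec.region_models.items():
                mean = (m["intercept"] + m.get("age", 0.0) * age
                        + m.get("sexF", 0.0) * sexF[i]
                        + m.get("invivo", 0.0) * is_invivo
                        + sum(m.get(d, 0.0) * diag[d][i] for d in diag)
                        + m.get("M", 0.0) * int(missing[i]))
                row[region] = mean + m.get("noise_sd", 0.0) * rng.standard_normal()
            rows.append(row)
    volumes = pd.DataFrame(rows)
    return records, volumes
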