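"""Synthetic mTBI cohort generator.

Emulates the statistical structure a skeletonized-FA lesion-load analysis
assumes, so every downstream stage (normative z-mapping, cluster-extent
inference, prognostic SVM) can be exercised without any clinical data:

* control FA on a white-matter-skeleton grid with linear age / sex /
  education effects and spatially smooth Gaussian noise of known FWHM;
* patient FA additionally perturbed in contiguous clusters of raised or
  lowered FA inside named tracts ("lesions"), carried by the patients
  designated to have a poor information-processing-speed (IPS) outcome;
* acutely elevated serum cytokines (IL-1beta, IL-6, CCL2) in patients,
  with a further shift in the poor-outcome subgroup;
* follow-up Trail-Making-Test-A (TMT-A, seconds) and backward digit span
  (BDS) scores driven by each subject's total injected lesion burden plus
  noise, from which the recovered / not-recovered class label is derived
  against an age- and education-banded norms table.

The grid is partitioned into rectangular tract blocks; the skeleton is a
thin slab through each block, which keeps tracts contiguous under
26-connectivity the way a real tract skeleton is.
"""

from __future__ import annotations

import importlib.resources
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import SkeletonGeometry, SkeletonImage, TractAtlas

__all__ = [
    "LesionSpec",
    "SimulationConfig",
    "CohortBundle",
    "generate_cohort",
    "label_recovery",
    "load_norms_table",
    "smooth_noise",
]

#: analyte order used throughout
CYTOKINES = ("il1b", "il6", "ccl2")

# control-population cytokine levels (pg/mL): mean, SD
_CYTOKINE_CONTROL = {"il1b": (2.2, 0.85), "il6": (0.9, 0.3), "ccl2": (212.0, 51.0)}


@dataclass(frozen=True)
class LesionSpec:
    """One injected abnormality: a contiguous cluster of shifted FA.

    effect_size is in units of the between-subject noise SD (reference SD);
    prevalence is the probability that a designated non-recovered patient
    carries this lesion.
    """

    tract: int
    direction: str  # "high" | "low"
    effect_size: float = 4.0
    extent: int = 120
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValueError(f"direction must be 'high' or 'low', got {self.direction!r}")
        if self.extent < 1:
            raise ValueError("lesion extent must be >= 1 voxel")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")


def default_lesion_specs() -> list[LesionSpec]:
    """Four strong lesions in four tracts, both directions represented."""
    return [
        LesionSpec(tract=2, direction="low"),
        LesionSpec(tract=5, direction="high"),
        LesionSpec(tract=8, direction="low"),
        LesionSpec(tract=11, direction="low"),
    ]


@dataclass
class SimulationConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults mirror the original-sample design: 60 patients / 40 controls,
    a third of patients with a poor long-term IPS outcome, and lesions
    strong enough (4 reference-SD, 120 voxels) to survive frequency
    pooling at one-third outcome prevalence.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: float = 2.0  # mm, isotropic
    skeleton_fraction: float = 0.10
    n_tracts: int = 12
    n_controls: int = 40
    n_patients: int = 60
    # FA units per covariate unit: age (per year), sex (0/1 offset), education (per year)
    covariate_effects: tuple[float, float, float] = (-0.001, 0.010, 0.0005)
    noise_sd: float = 0.03  # FA units, after smoothing
    smoothing_fwhm: float = 4.0  # mm
    lesion_specs: list[LesionSpec] = field(default_factory=default_lesion_specs)
    nonrecovery_fraction: float = 0.33
    # per-analyte mean elevation in all patients (pg/mL)
    cytokine_shift: tuple[float, float, float] = (0.4, 0.4, 47.0)
    # further elevation in designated non-recovered patients (outcome signal)
    cytokine_outcome_shift: tuple[float, float, float] = (0.3, 0.15, 25.0)
    # follow-up TMT-A = intercept + slope * burden + N(0, sd); burden in SD*voxels
    tmt_intercept: float = 24.0
    tmt_burden_slope: float = 0.02
    tmt_noise_sd: float = 3.0
    # follow-up BDS = intercept + slope * burden + N(0, sd)
    bds_intercept: float = 5.0
    bds_burden_slope: float = -0.0012
    bds_noise_sd: float = 0.8
    burden_jitter: tuple[float, float] = (0.8, 1.2)  # per-lesion multiplier range
    # recovered patients carry the same lesion sites at reduced effect and
    # prevalence: injury is graded, not all-or-none
    recovered_effect_scale: float = 0.3
    recovered_prevalence: float = 0.5
    norms_table: pd.DataFrame | None = None  # default: packaged synthetic norms
    seed: int = 0
    cohort: str = "original"

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_tracts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.skeleton_fraction < 1.0:
            raise ValueError("skeleton_fraction must lie in (0, 1)")
        if self.smoothing_fwhm < self.voxel_size:
            raise ValueError("smoothing FWHM must be at least one voxel size")
        if not 0.0 <= self.nonrecovery_fraction <= 1.0:
            raise ValueError("nonrecovery_fraction must lie in [0, 1]")
        self.lesion_specs = [
            ls if isinstance(ls, LesionSpec) else LesionSpec(**ls) for ls in self.lesion_specs
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("norms_table")
        return d

    def replicate(self, seed: int) -> "SimulationConfig":
        """Same study conditions, fresh sampling seed, tagged 'replicate'."""
        import copy

        cfg = copy.copy(self)
        cfg.lesion_specs = list(self.lesion_specs)
        cfg.seed = seed
        cfg.cohort = "replicate"
        return cfg


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces.

    ``truth`` records injected lesion voxel sets and per-subject burden for
    recovery tests only; analysis modules never read it.
    """

    config: SimulationConfig
    geometry: SkeletonGeometry
    atlas: TractAtlas
    images: list[SkeletonImage]
    covariates: pd.DataFrame  # subject_id, age, sex, education, group, cohort
    cytokines: pd.DataFrame  # subject_id + analyte columns (pg/mL)
    outcomes: pd.DataFrame  # subject_id, tmt_a/bds at baseline & follow-up
    truth: dict

    @property
    def control_ids(self) -> list[str]:
        m = self.covariates["group"] == "control"
        return list(self.covariates.loc[m, "subject_id"])

    @property
    def patient_ids(self) -> list[str]:
        m = self.covariates["group"] == "patient"
        return list(self.covariates.loc[m, "subject_id"])

    def image_matrix(self, subject_ids: list[str]) -> np.ndarray:
        by_id = {im.subject_id: im for im in self.images}
        return np.vstack([by_id[s].data for s in subject_ids])


# ---------------------------------------------------------------------------
# grid / atlas construction (deterministic given the config, seed-free)
# ---------------------------------------------------------------------------


def _block_layout(n_tracts: int) -> tuple[int, int]:
    bx = int(np.ceil(np.sqrt(n_tracts)))
    by = int(np.ceil(n_tracts / bx))
    return bx, by


def build_geometry(config: SimulationConfig) -> tuple[SkeletonGeometry, TractAtlas]:
    """Tract blocks with a thin skeleton slab through each.

    Deterministic and seed-free so the original and replicate cohorts share
    one common space, as registered real cohorts would.
    """
    nx, ny, nz = config.grid_shape
    bx, by = _block_layout(config.n_tracts)
    xs = np.array_split(np.arange(nx), bx)
    ys = np.array_split(np.arange(ny), by)
    mask = np.zeros(config.grid_shape, dtype=bool)
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for t in range(config.n_tracts):
        xblk = xs[t % bx]
        yblk = ys[t // bx]
        thick = max(1, int(round(config.skeleton_fraction * len(yblk))))
        y0 = yblk[0] + (len(yblk) - thick) // 2
        sl = (slice(xblk[0], xblk[-1] + 1), slice(y0, y0 + thick), slice(0, nz))
        mask[sl] = True
        labels[sl] = t + 1
    geom = SkeletonGeometry(mask=mask, voxel_size=(config.voxel_size,) * 3)
    table = pd.DataFrame(
        {"label": np.arange(1, config.n_tracts + 1), "name": [f"tract_{t:02d}" for t in range(1, config.n_tracts + 1)]}
    )
    return geom, TractAtlas(labels=labels, table=table)


def grow_lesion_mask(
    geometry: SkeletonGeometry, atlas: TractAtlas, spec: LesionSpec
) -> np.ndarray:
    """Deterministic contiguous voxel set of ``spec.extent`` inside the tract.

    Breadth-first growth (26-connectivity) from the tract voxel closest to
    the tract centroid; deterministic so lesion sites coincide across
    cohorts drawn from the same configuration.
    """
    tract_mask = (atlas.labels == spec.tract) & geometry.mask
    n_avail = int(tract_mask.sum())
    if n_avail == 0:
        raise ValueError(f"lesion tract id {spec.tract} absent from atlas")
    if spec.extent > n_avail:
        raise ValueError(
            f"lesion extent {spec.extent} exceeds tract {spec.tract} skeleton size {n_avail}"
        )
    coords = np.array(np.nonzero(tract_mask)).T
    centroid = coords.mean(axis=0)
    start = tuple(coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])
    shape = geometry.shape
    chosen: list[tuple[int, int, int]] = []
    seen = {start}
    queue = deque([start])
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while queue and len(chosen) < spec.extent:
        vox = queue.popleft()
        chosen.append(vox)
        neighbours = []
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                continue
            if nb in seen or not tract_mask[nb]:
                continue
            neighbours.append(nb)
        # expand nearest-to-centroid first: compact, roughly convex blobs
        neighbours.sort(key=lambda v: (((np.array(v) - centroid) ** 2).sum(), v))
        for nb in neighbours:
            seen.add(nb)
            queue.append(nb)
    if len(chosen) < spec.extent:  # tract large enough but disconnected
        raise ValueError(
            f"could not grow contiguous lesion of {spec.extent} voxels in tract {spec.tract}"
        )
    lesion = np.zeros(shape, dtype=bool)
    lesion[tuple(np.array(chosen).T)] = True
    return lesion


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def _smoothing_sigma_vox(fwhm_mm: float, voxel_size: float) -> float:
    return fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * voxel_size)


def smooth_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fwhm_mm: float, voxel_size: float
) -> np.ndarray:
    """Unit-variance Gaussian field of the requested smoothness.

    White noise convolved with a Gaussian kernel on a torus (wrap mode), so
    the field is stationary and the variance renormalization, computed from
    the kernel's sum of squares, is exact at every voxel.
    """
    sigma = _smoothing_sigma_vox(fwhm_mm, voxel_size)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    impulse = np.zeros(shape)
    impulse[(0,) * len(shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma, mode="wrap")
    return field_ / np.sqrt((kernel**2).sum())


# ---------------------------------------------------------------------------
# norms table and recovery labels
# ---------------------------------------------------------------------------


def load_norms_table() -> pd.DataFrame:
    """Packaged TMT-A cut-off table by (age band, education band).

    Published age/education-adjusted TMT-A norms are licensed tables and
    not redistributable, so this file is a synthetic stand-in: cut-offs
    rise with age and fall with education, on a realistic seconds scale.
    """
    ref = importlib.resources.files("lesionload.data") / "tmt_a_norms_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def label_recovery(outcomes: pd.DataFrame, norms_table: pd.DataFrame) -> pd.Series:
    """Binary recovery labels: +1 improved-to-normal, -1 not.

    A subject is labelled +1 iff their follow-up TMT-A is less than or
    equal to the cut-off for their (age, education) band; the cut-off is
    inclusive.  ``outcomes`` needs columns ``subject_id``, ``age``,
    ``education`` and ``tmt_a_followup``.
    """
    required = {"subject_id", "age", "education", "tmt_a_followup"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcomes table missing columns: {sorted(missing)}")
    labels = np.empty(len(outcomes), dtype=int)
    unmatched: list[str] = []
    for i, row in enumerate(outcomes.itertuples(index=False)):
        band = norms_table[
            (norms_table["age_min"] <= row.age)
            & (row.age <= norms_table["age_max"])
            & (norms_table["edu_min"] <= row.education)
            & (row.education <= norms_table["edu_max"])
        ]
        if band.empty:
            unmatched.append(str(row.subject_id))
            continue
        cutoff = float(band["tmt_a_cutoff"].iloc[0])
        labels[i] = 1 if row.tmt_a_followup <= cutoff else -1
    if unmatched:
        raise ValueError(f"subjects outside all norm bands: {unmatched}")
    return pd.Series(labels, index=outcomes["subject_id"].values, name="recovery")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _baseline_map(geometry: SkeletonGeometry, atlas: TractAtlas) -> np.ndarray:
    """Deterministic per-tract baseline FA in [0.40, 0.55]."""
    labels = atlas.labels_on_skeleton(geometry)
    return 0.40 + 0.15 * ((labels - 1) % 5) / 4.0


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one full cohort (controls + patients) from the configuration.

    Deterministic given ``config.seed``.  See the module docstring for the
    generative model.
    """
    rng = np.random.default_rng(config.seed)
    geometry, atlas = build_geometry(config)
    baseline = _baseline_map(geometry, atlas)
    lesion_masks = [
        geometry.extract(grow_lesion_mask(geometry, atlas, spec)).astype(bool)
        for spec in config.lesion_specs
    ]

    n_total = config.n_controls + config.n_patients
    groups = ["control"] * config.n_controls + ["patient"] * config.n_patients
    subject_ids = [
        f"{config.cohort[:4]}-{g[:3]}-{i:03d}" for i, g in enumerate(groups)
    ]
    # integer years, as clinical tables record them (and as the banded
    # norms table expects)
    age = rng.integers(18, 60, n_total).astype(float)
    sex = (rng.random(n_total) < 0.6).astype(int)
    education = rng.integers(5, 17, n_total).astype(float)
    a_age, a_sex, a_edu = config.covariate_effects

    # outcome designation: which patients carry the injury driving poor IPS
    n_nonrec = int(round(config.nonrecovery_fraction * config.n_patients))
    patient_idx = np.arange(config.n_controls, n_total)
    nonrec_idx = set(rng.choice(patient_idx, size=n_nonrec, replace=False).tolist())

    images: list[SkeletonImage] = []
    burden = np.zeros(n_total)
    lesion_carrier = np.zeros((n_total, len(lesion_masks)), dtype=bool)
    for i, sid in enumerate(subject_ids):
        fa = (
            baseline
            + a_age * (age[i] - 40.0)
            + a_sex * sex[i]
            + a_edu * (education[i] - 11.0)
            + config.noise_sd
            * smooth_noise(rng, geometry.shape, config.smoothing_fwhm, config.voxel_size)[
                geometry.mask
            ]
        )
        if groups[i] == "patient":
            nonrec = i in nonrec_idx
            scale = 1.0 if nonrec else config.recovered_effect_scale
            for j, (spec, mask) in enumerate(zip(config.lesion_specs, lesion_masks)):
                prevalence = spec.prevalence if nonrec else config.recovered_prevalence
                if scale == 0.0 or rng.random() > prevalence:
                    continue
                mult = scale * rng.uniform(*config.burden_jitter)
                sign = 1.0 if spec.direction == "high" else -1.0
                fa[mask] += sign * spec.effect_size * config.noise_sd * mult
                burden[i] += spec.effect_size * spec.extent * mult
                lesion_carrier[i, j] = True
        images.append(SkeletonImage(sid, np.clip(fa, 0.0, 1.0), geometry))

    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "education": education,
            "group": groups,
            "cohort": config.cohort,
        }
    )

    cyt = {"subject_id": subject_ids}
    is_patient = np.array([g == "patient" for g in groups])
    is_nonrec = np.array([i in nonrec_idx for i in range(n_total)])
    for k, analyte in enumerate(CYTOKINES):
        mean, sd = _CYTOKINE_CONTROL[analyte]
        vals = rng.normal(mean, sd, n_total)
        vals[is_patient] += config.cytokine_shift[k]
        vals[is_nonrec] += config.cytokine_outcome_shift[k]
        cyt[analyte] = np.clip(vals, 0.05, None)
    cytokines = pd.DataFrame(cyt)

    tmt_fu = (
        config.tmt_intercept
        + config.tmt_burden_slope * burden
        + rng.normal(0.0, config.tmt_noise_sd, n_total)
    )
    tmt_base = tmt_fu + np.abs(rng.normal(6.0, 5.0, n_total))
    bds_fu = (
        config.bds_intercept
        + config.bds_burden_slope * burden
        + rng.normal(0.0, config.bds_noise_sd, n_total)
    )
    bds_base = bds_fu - np.abs(rng.normal(0.4, 0.4, n_total))
    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "tmt_a_baseline": np.clip(tmt_base, 10.0, None),
            "tmt_a_followup": np.clip(tmt_fu, 10.0, None),
            "bds_baseline": np.clip(bds_base, 0.0, None),
            "bds_followup": np.clip(bds_fu, 0.0, None),
            "age": age,
            "education": education,
            "group": groups,
        }
    )

    truth = {
        "lesions": [
            {
                "tract": spec.tract,
                "direction": spec.direction,
                "effect_size": spec.effect_size,
                "extent": spec.extent,
                "voxels": np.flatnonzero(mask),  # on-skeleton indices
            }
            for spec, mask in zip(config.lesion_specs, lesion_masks)
        ],
        "burden": pd.DataFrame(
            {
                "subject_id": subject_ids,
                "burden": burden,
                "designated_nonrecovered": is_nonrec,
            }
        ),
        "lesion_carrier": lesion_carrier,
    }
    return CohortBundle(
        config=config,
        geometry=geometry,
        atlas=atlas,
        images=images,
        covariates=covariates,
        cytokines=cytokines,
        outcomes=outcomes,
        truth=truth,
    )
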