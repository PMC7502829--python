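"""Abnormality clusters, GRF extent correction and lesion-load features.

EZ deviation maps are thresholded at |EZ| > u separately for abnormally
high and low FA, masked to atlas tracts, and reduced to contiguous
clusters whose extent survives a family-wise 5% Gaussian-random-field
(GRF) correction.  Patients' abnormality maps are pooled by frequency
into one fixed cluster catalogue, and each subject's mean adjusted FA per
catalogue cluster becomes a prognostic feature.

The GRF extent threshold uses the classical expected-cluster-count times
extent-tail approximation for a smooth stationary Gaussian field; because
a tract skeleton is quasi-2D this is approximate, and a Monte-Carlo null
(``mc_extent_threshold``) is provided as an alternative mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

from .geometry import SkeletonGeometry, TractAtlas

__all__ = [
    "Cluster",
    "ClusterSet",
    "estimate_smoothness",
    "grf_extent_threshold",
    "mc_extent_threshold",
    "detect_clusters",
    "lesion_load",
    "optimize_thresholds",
    "build_cluster_catalogue",
    "extract_features",
    "LesionFeatureExtractor",
]

logger = logging.getLogger(__name__)

_LN2_4 = 4.0 * np.log(2.0)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=int)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class Cluster:
    """A contiguous set of same-direction abnormal voxels in one tract."""

    id: str
    tract_label: int
    tract_name: str
    direction: str  # "high" | "low"
    voxels: np.ndarray  # indices into the on-skeleton vector

    @property
    def extent(self) -> int:
        return int(self.voxels.size)


@dataclass
class ClusterSet:
    """Fixed catalogue of abnormal clusters plus the provenance that cut it."""

    clusters: list[Cluster]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.clusters]
        if len(ids) != len(set(ids)):
            raise ValueError("cluster ids must be unique")
        for direction in ("high", "low"):
            seen: set[int] = set()
            for c in self.clusters:
                if c.direction != direction:
                    continue
                vox = set(c.voxels.tolist())
                if seen & vox:
                    raise ValueError(f"voxel in two {direction} clusters")
                seen |= vox

    def __len__(self) -> int:
        return len(self.clusters)

    def feature_ids(self) -> list[str]:
        """Deterministic column order: (tract label, direction, cluster id)."""
        order = sorted(
            self.clusters, key=lambda c: (c.tract_label, c.direction, c.id)
        )
        return [c.id for c in order]

    def label_volume(self, geometry: SkeletonGeometry) -> np.ndarray:
        """Integer volume of 1-based cluster indices in feature order."""
        vol = np.zeros(geometry.n_voxels, dtype=np.int32)
        by_id = {c.id: c for c in self.clusters}
        for i, fid in enumerate(self.feature_ids(), start=1):
            vol[by_id[fid].voxels] = i
        return geometry.embed(vol)


# ---------------------------------------------------------------------------
# smoothness
# ---------------------------------------------------------------------------


def estimate_smoothness(
    residuals: np.ndarray, geometry: SkeletonGeometry
) -> np.ndarray:
    """Per-axis FWHM (mm) of the noise field, from standardized residuals.

    For a unit-variance Gaussian field with Gaussian autocorrelation, the
    variance v of first differences at lag one voxel gives the lag-1
    autocorrelation rho = 1 - v/2 and hence the kernel width:
    FWHM = sqrt(8 ln 2) * delta / (2 sqrt(-ln rho)).  Differences are taken
    between adjacent on-skeleton voxel pairs only, averaged over maps, and
    the estimate is clipped below at one voxel size.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    sd = residuals.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all residual maps are constant")
    z = residuals[sd > 0] / sd[sd > 0, None]
    vols = np.stack([geometry.embed(row, fill=np.nan) for row in z])
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(vols, axis=ax + 1)
        d = d[np.isfinite(d)]  # both voxels on skeleton
        if d.size < 10:
            fwhm[ax] = geometry.voxel_size[ax]
            continue
        v = float(np.var(d))
        rho = np.clip(1.0 - v / 2.0, 1e-6, 1.0 - 1e-12)
        sigma_vox = 1.0 / (2.0 * np.sqrt(-np.log(rho)))
        fwhm[ax] = np.sqrt(8.0 * np.log(2.0)) * sigma_vox * geometry.voxel_size[ax]
    return np.maximum(fwhm, np.asarray(geometry.voxel_size, dtype=float))


# ---------------------------------------------------------------------------
# extent thresholds
# ---------------------------------------------------------------------------


def _as_fwhm_vox(fwhm, voxel_size) -> np.ndarray:
    fwhm = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return np.maximum(fwhm / vs, 1.0)


def grf_extent_threshold(
    u: float,
    fwhm,
    n_voxels: int,
    alpha: float = 0.05,
    voxel_size=1.0,
) -> int:
    """Minimum cluster extent k (voxels) controlling family-wise error.

    Smallest k such that the probability of observing at least one
    suprathreshold (one-sided, field > u) cluster of >= k voxels in a
    stationary Gaussian field of the given smoothness over ``n_voxels``
    is <= ``alpha``:

        E[clusters]   Em = S prod(1/f_i) (4 ln 2)^{3/2} (2 pi)^{-2} (u^2-1) e^{-u^2/2}
        E[voxels]     EN = S Phi(-u)
        P(extent>=k)  exp(-beta k^{2/3}),  beta = (Gamma(5/2) Em / EN)^{2/3}
        FWE           1 - exp(-Em P(extent >= k)) <= alpha

    ``fwhm`` and ``voxel_size`` may be scalars or per-axis triples in the
    same units.
    """
    if not (np.isfinite(u) and np.isfinite(alpha) and np.all(np.isfinite(fwhm))):
        raise ValueError("non-finite inputs to grf_extent_threshold")
    if u <= 1.0:
        raise ValueError("voxel threshold u must exceed 1 for the GRF cluster form")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    f_vox = _as_fwhm_vox(fwhm, voxel_size)
    D = 3
    Em = (
        n_voxels
        * float(np.prod(1.0 / f_vox))
        * _LN2_4 ** (D / 2)
        * (2.0 * np.pi) ** (-(D + 1) / 2)
        * (u * u - 1.0)
        * np.exp(-u * u / 2.0)
    )
    target = -np.log1p(-alpha)
    if Em <= target:
        return 1
    EN = n_voxels * stats.norm.sf(u)
    nbar = EN / Em
    beta = (gamma_fn(D / 2 + 1) / nbar) ** (2.0 / D)
    k = np.ceil(((np.log(Em) - np.log(target)) / beta) ** (D / 2.0))
    return max(int(k), 1)


def mc_extent_threshold(
    u: float,
    fwhm,
    n_voxels: int,
    alpha: float = 0.05,
    voxel_size=1.0,
    n_sim: int = 5000,
    seed: int = 0,
    connectivity: int = 26,
) -> int:
    """Monte-Carlo extent threshold from simulated smooth null fields.

    Simulates ``n_sim`` unit-variance Gaussian fields of the requested
    smoothness on a toroidal grid of about ``n_voxels`` voxels and returns
    the smallest k whose exceedance frequency (max suprathreshold cluster
    extent >= k) is <= ``alpha``.
    """
    f_vox = _as_fwhm_vox(fwhm, voxel_size)
    sigma_vox = f_vox / np.sqrt(8.0 * np.log(2.0))
    side = max(8, int(round(n_voxels ** (1.0 / 3.0))))
    shape = (side,) * 3
    impulse = np.zeros(shape)
    impulse[0, 0, 0] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma_vox, mode="wrap")
    scale = np.sqrt((kernel**2).sum())
    struct = _structure(connectivity)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_sim, dtype=int)
    for i in range(n_sim):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="wrap") / scale
        lab, nl = ndimage.label(f > u, structure=struct)
        maxima[i] = np.bincount(lab.ravel())[1:].max() if nl else 0
    # smallest k with P(max extent >= k) <= alpha
    ks = np.arange(1, maxima.max() + 2)
    exceed = (maxima[None, :] >= ks[:, None]).mean(axis=1)
    return int(ks[np.argmax(exceed <= alpha)])


# ---------------------------------------------------------------------------
# cluster detection and features
# ---------------------------------------------------------------------------


def _components_in_tracts(
    above: np.ndarray,
    geometry: SkeletonGeometry,
    atlas: TractAtlas,
    k: int,
    direction: str,
    connectivity: int,
) -> list[Cluster]:
    """Connected components of a boolean on-skeleton mask, per tract."""
    if atlas.labels.shape != geometry.shape:
        raise ValueError(
            f"atlas shape {atlas.labels.shape} != skeleton grid {geometry.shape}"
        )
    struct = _structure(connectivity)
    vol = geometry.embed(above.astype(np.int8)).astype(bool)
    skel_labels = atlas.labels_on_skeleton(geometry)
    inv = np.full(geometry.mask.size, -1, dtype=np.int64)
    inv[geometry.flat_index] = np.arange(geometry.n_voxels)
    clusters: list[Cluster] = []
    for tract in sorted(set(np.unique(skel_labels[above])) - {0}):
        tract_vol = vol & (atlas.labels == tract)
        lab, nl = ndimage.label(tract_vol, structure=struct)
        if nl == 0:
            continue
        sizes = np.bincount(lab.ravel())
        idx = 0
        for comp in range(1, nl + 1):
            if sizes[comp] < k:
                continue
            flat = np.flatnonzero(lab.ravel() == comp)
            vox = np.sort(inv[flat])
            clusters.append(
                Cluster(
                    id=f"{atlas.name_of(int(tract))}_{direction}_{idx}",
                    tract_label=int(tract),
                    tract_name=atlas.name_of(int(tract)),
                    direction=direction,
                    voxels=vox,
                )
            )
            idx += 1
    return clusters


def detect_clusters(
    ez: np.ndarray,
    u: float,
    k: int,
    geometry: SkeletonGeometry,
    atlas: TractAtlas,
    direction: str,
    connectivity: int = 26,
) -> list[Cluster]:
    """Suprathreshold clusters of one EZ map, masked per tract.

    Voxels with EZ > u (high) or EZ < -u (low) are intersected with each
    tract mask; connected components are computed within each tract
    separately and components smaller than k voxels discarded.  The
    boundary |EZ| = u is excluded (strict inequality).
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    ez = np.asarray(ez, dtype=float)
    above = ez > u if direction == "high" else ez < -u
    if not above.any():
        return []
    return _components_in_tracts(above, geometry, atlas, k, direction, connectivity)


def lesion_load(
    ez: np.ndarray,
    u: float,
    k: int,
    geometry: SkeletonGeometry,
    atlas: TractAtlas,
    connectivity: int = 26,
) -> int:
    """Total abnormal-voxel count across surviving clusters, both directions."""
    return sum(
        c.extent
        for direction in ("high", "low")
        for c in detect_clusters(ez, u, k, geometry, atlas, direction, connectivity)
    )


def optimize_thresholds(
    patient_ez: np.ndarray,
    control_ez: np.ndarray,
    geometry: SkeletonGeometry,
    atlas: TractAtlas,
    fwhm,
    u_grid=(1.64, 1.96, 2.33, 2.58),
    alpha_grid=(0.01, 0.05),
    connectivity: int = 26,
) -> tuple[float, int, float, pd.DataFrame]:
    """ROC sweep of (voxel threshold u, extent threshold k).

    For each candidate pair, the per-subject lesion load separates
    patients from normal controls; the pair maximizing ROC AUC wins, ties
    broken toward larger u then larger k.  Returns (u*, k*, AUC*, sweep
    table).
    """
    patient_ez = np.atleast_2d(patient_ez)
    control_ez = np.atleast_2d(control_ez)
    if patient_ez.shape[0] == 0 or control_ez.shape[0] == 0:
        raise ValueError("both patient and control EZ stacks must be non-empty")
    if not len(u_grid) or not len(alpha_grid):
        raise ValueError("threshold grids must be non-empty")
    y = np.r_[np.ones(patient_ez.shape[0]), np.zeros(control_ez.shape[0])]
    rows = []
    for u in sorted(u_grid):
        for alpha in sorted(alpha_grid):
            k = grf_extent_threshold(
                u, fwhm, geometry.n_voxels, alpha, voxel_size=geometry.voxel_size
            )
            loads = [
                lesion_load(ez, u, k, geometry, atlas, connectivity)
                for ez in np.vstack([patient_ez, control_ez])
            ]
            if len(set(loads)) == 1:
                auc = np.nan  # undefined: no separation information at all
            else:
                auc = roc_auc_score(y, loads)
            rows.append({"u": u, "alpha": alpha, "k": k, "auc": auc})
    sweep = pd.DataFrame(rows)
    if sweep["auc"].isna().all():
        raise ValueError("ROC undefined for every candidate threshold pair")
    best = sweep.sort_values(
        ["auc", "u", "k"], ascending=[False, False, False], kind="stable"
    ).iloc[0]
    return float(best["u"]), int(best["k"]), float(best["auc"]), sweep


def build_cluster_catalogue(
    patient_ez: np.ndarray,
    u: float,
    k: int,
    geometry: SkeletonGeometry,
    atlas: TractAtlas,
    frequency_fraction: float = 0.25,
    connectivity: int = 26,
    provenance: dict | None = None,
) -> ClusterSet:
    """Pool patients' abnormality maps into the fixed feature catalogue.

    Per direction, a voxel enters the group mask when abnormal in at least
    ``frequency_fraction`` of patients; clusters are then cut from that
    mask (per tract, extent >= k).  The catalogue is shared by every
    subject downstream.
    """
    if not 0.0 < frequency_fraction <= 1.0:
        raise ValueError("frequency_fraction must lie in (0, 1]")
    patient_ez = np.atleast_2d(np.asarray(patient_ez, dtype=float))
    if patient_ez.shape[0] < 1:
        raise ValueError("need at least one patient EZ map")
    clusters: list[Cluster] = []
    for direction, sign in (("high", 1.0), ("low", -1.0)):
        freq = (sign * patient_ez > u).mean(axis=0)
        mask = freq >= frequency_fraction
        if mask.any():
            clusters.extend(
                _components_in_tracts(mask, geometry, atlas, k, direction, connectivity)
            )
    prov = {
        "ez_threshold": float(u),
        "extent_threshold": int(k),
        "connectivity": connectivity,
        "frequency_fraction": float(frequency_fraction),
        "n_patients": int(patient_ez.shape[0]),
    }
    if provenance:
        prov.update(provenance)
    if not clusters:
        warnings.warn(
            "empty cluster catalogue: no voxel abnormal at the required frequency; "
            "downstream models will use non-imaging features only",
            stacklevel=2,
        )
        logger.warning("empty cluster catalogue (u=%.3g, k=%d)", u, k)
    return ClusterSet(clusters=clusters, provenance=prov)


def extract_features(
    fa: np.ndarray,
    catalogue: ClusterSet,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject mean (covariate-adjusted) FA over each catalogue cluster.

    Rows follow the input order; columns follow the catalogue's
    deterministic (tract, direction, index) order.  Column metadata lives
    in ``df.attrs['clusters']``.
    """
    fa = np.atleast_2d(np.asarray(fa, dtype=float))
    if np.isnan(fa).any():
        raise ValueError("subject FA contains missing values under the skeleton")
    by_id = {c.id: c for c in catalogue.clusters}
    cols = catalogue.feature_ids()
    for cid in cols:
        if by_id[cid].voxels.max(initial=-1) >= fa.shape[1]:
            raise ValueError(f"subjects are missing voxels under cluster {cid}")
    data = {cid: fa[:, by_id[cid].voxels].mean(axis=1) for cid in cols}
    index = subject_ids if subject_ids is not None else range(fa.shape[0])
    df = pd.DataFrame(data, index=index, columns=cols)
    df.attrs["clusters"] = {
        cid: {
            "tract_label": by_id[cid].tract_label,
            "tract_name": by_id[cid].tract_name,
            "direction": by_id[cid].direction,
            "extent": by_id[cid].extent,
        }
        for cid in cols
    }
    df.attrs["domain"] = {cid: "fa" for cid in cols}
    return df


class LesionFeatureExtractor(BaseEstimator, TransformerMixin):
    """Fit the cluster catalogue on patient EZ maps; transform adjusted FA
    stacks into lesion-load feature matrices.

    Parameters
    ----------
    geometry, atlas : cohort grid and tract labels.
    u : EZ voxel threshold (default 1.96).
    alpha : family-wise cluster-extent level (default .05).
    frequency_fraction : patient fraction required for the group mask.
    null_mode : 'grf' (analytic) or 'mc' (Monte-Carlo extent null).
    fwhm : smoothness override (mm); estimated from residuals when None.
    """

    def __init__(
        self,
        geometry: SkeletonGeometry,
        atlas: TractAtlas,
        u: float = 1.96,
        alpha: float = 0.05,
        frequency_fraction: float = 0.25,
        connectivity: int = 26,
        null_mode: str = "grf",
        mc_sims: int = 2000,
        fwhm=None,
        seed: int = 0,
    ):
        self.geometry = geometry
        self.atlas = atlas
        self.u = u
        self.alpha = alpha
        self.frequency_fraction = frequency_fraction
        self.connectivity = connectivity
        self.null_mode = null_mode
        self.mc_sims = mc_sims
        self.fwhm = fwhm
        self.seed = seed

    def fit(self, patient_ez: np.ndarray, residuals: np.ndarray | None = None):
        if self.fwhm is not None:
            self.fwhm_ = np.broadcast_to(np.asarray(self.fwhm, float), (3,)).copy()
        elif residuals is not None:
            self.fwhm_ = estimate_smoothness(residuals, self.geometry)
        else:
            raise ValueError("either fwhm or residual maps are required")
        thresh = {"grf": grf_extent_threshold, "mc": mc_extent_threshold}
        if self.null_mode not in thresh:
            raise ValueError("null_mode must be 'grf' or 'mc'")
        kwargs = {"voxel_size": self.geometry.voxel_size}
        if self.null_mode == "mc":
            kwargs.update(n_sim=self.mc_sims, seed=self.seed, connectivity=self.connectivity)
        self.k_ = thresh[self.null_mode](
            self.u, self.fwhm_, self.geometry.n_voxels, self.alpha, **kwargs
        )
        self.catalogue_ = build_cluster_catalogue(
            patient_ez,
            self.u,
            self.k_,
            self.geometry,
            self.atlas,
            frequency_fraction=self.frequency_fraction,
            connectivity=self.connectivity,
            provenance={
                "smoothness_fwhm_mm": [float(f) for f in self.fwhm_],
                "null_mode": self.null_mode,
            },
        )
        return self

    def transform(self, fa: np.ndarray, subject_ids: list[str] | None = None) -> pd.DataFrame:
        if not hasattr(self, "catalogue_"):
            raise ValueError("LesionFeatureExtractor is not fitted")
        return extract_features(fa, self.catalogue_, subject_ids)
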