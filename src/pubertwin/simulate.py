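"""Synthetic longitudinal twin cohorts with voxel-wise grey-matter maps.

The generator draws latent A/C/E factors per twin pair exactly as the path
model prescribes — additive-genetic factors correlate 1.0 across MZ and 0.5
across DZ co-twins, common-environment factors are shared within a pair,
unique-environment factors are individual — and composes phenotypes as
``mean + a*A + c*C + e*E``.

Grey-matter density is produced over a 3-D voxel grid: A and C contributions
are constant within the signal cluster and (with an independent set of
factors) constant outside it, so only voxels inside the cluster carry the
hormone-density coupling; the E contribution is a per-voxel random field,
Gaussian-smoothed for spatial realism and rescaled so each voxel's marginal
variance matches the path model.

Hormone levels are generated on the log scale (so the observed raw scale is
log-normal and left-skewed, as urinary gonadotropin levels are), split into
two assay days with independent measurement noise, multiplied by a per-day
creatinine excretion level, and censored at the assay detection limit.
Occasion-2 measurements are dropped completely at random to emulate
longitudinal attrition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .changes import change_variance
from .paths import GENETIC_CROSS_TWIN_CORR, PathModel

__all__ = [
    "SimulationConfig",
    "Cohort",
    "TwinPairRecord",
    "default_path_model",
    "bivariate_age12_truth",
    "plant_coupling",
    "simulate_cohort",
    "draw_pair_phenotypes",
    "write_cohort",
    "read_cohort",
]

TABLE_COLUMNS = [
    "family_id",
    "twin_id",
    "zygosity",
    "sex",
    "occasion",
    "age",
    "hormone_day1",
    "hormone_day2",
    "creatinine_day1",
    "creatinine_day2",
    "below_limit_day1",
    "below_limit_day2",
    "voxel_map_path",
]

# phenotype indices: hormone at the two occasions, density at the two occasions
_H9, _GM9, _H12, _GM12 = 0, 1, 2, 3
_HORMONE_IDX = (_H9, _H12)
_GM_IDX = (_GM9, _GM12)


def default_path_model(variant: str = "fsh") -> PathModel:
    """Ground-truth longitudinal model without hormone-density coupling.

    ``"fsh"`` (default): hormone (log U/mmol creatinine) half genetic with a
    sizeable unique-environment share, total variance 0.30, means matching
    observed creatinine-corrected FSH levels at ages 9 and 12; grey-matter
    density heritable, variance 0.01 around means 0.60 (age 9) and 0.55
    (age 12; density declines).  ``"c_heavy"``: a common-environment-
    dominated variant (larger C shares, weaker C tracking across age) that
    can carry a planted shared-environment coupling.  All hormone-density
    cross correlations are zero; see :func:`plant_coupling`.
    """
    if variant == "fsh":
        frac_h, frac_g = np.array([0.5, 0.1, 0.4]), np.array([0.5, 0.15, 0.35])
        rc = (0.5, 0.5)
    elif variant == "c_heavy":
        frac_h, frac_g = np.array([0.25, 0.45, 0.3]), np.array([0.3, 0.45, 0.25])
        rc = (0.2, 0.2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    var = np.array([0.30, 0.01, 0.30, 0.01])
    fracs = np.stack([frac_h, frac_g, frac_h, frac_g])
    paths = np.sqrt(fracs * var[:, None])

    def corr(r_h, r_g):
        R = np.eye(4)
        R[_H9, _H12] = R[_H12, _H9] = r_h
        R[_GM9, _GM12] = R[_GM12, _GM9] = r_g
        return R

    return PathModel(
        a=paths[:, 0],
        c=paths[:, 1],
        e=paths[:, 2],
        R_g=corr(0.6, 0.8),
        R_c=corr(*rc),
        R_e=corr(0.15, 0.15),
        means=np.array([np.log(0.47), 0.60, np.log(0.92), 0.55]),
    ).validate()


def bivariate_age12_truth(
    r_cross: float = -0.47, component: str = "c", variances: tuple[float, float] = (0.5, 0.01)
) -> PathModel:
    """Estradiol-like 2-phenotype ground truth for the second occasion only.

    Phenotype 0 is the log hormone level (shared-environment dominated, as
    urinary estradiol in pre-menarche girls is), phenotype 1 the
    grey-matter density; the cross-trait correlation ``r_cross`` is carried
    entirely by the chosen component.
    """
    frac_h = np.array([0.2, 0.6, 0.2])
    frac_g = np.array([0.3, 0.5, 0.2])
    fracs = np.stack([frac_h, frac_g])
    paths = np.sqrt(fracs * np.array(variances)[:, None])
    share = {"a": 0, "c": 1, "e": 2}[component]
    rho = r_cross / np.sqrt(fracs[0, share] * fracs[1, share])
    if abs(rho) > 0.95:
        raise ValueError(f"r_cross {r_cross} infeasible for component {component!r}")
    mats = [np.eye(2) for _ in range(3)]
    mats[share] = np.array([[1.0, rho], [rho, 1.0]])
    return PathModel(
        a=paths[:, 0],
        c=paths[:, 1],
        e=paths[:, 2],
        R_g=mats[0],
        R_c=mats[1],
        R_e=mats[2],
        means=np.array([np.log(344.2), 0.55]),
        labels=("hormone_age12", "density_age12"),
    ).validate()


def plant_coupling(
    model: PathModel,
    component: str = "e",
    r_target: float = 0.5,
    target: str = "change",
) -> PathModel:
    """Set hormone-density cross correlations of one component so the
    change correlation (or age-12 cross-trait correlation) equals ``r_target``.

    For the change target the same-occasion correlations r_X(0,1) and
    r_X(2,3) are set to a common value (cross-occasion cross-trait
    correlations stay zero); for the age-12 target only r_X(2,3) is set.
    Solved in closed form — cross-trait correlations do not enter the
    change variances, so the equation is linear in the planted value.
    """
    x = {"a": model.a, "c": model.c, "e": model.e}[component]
    if target == "change":
        v = change_variance(model, _GM_IDX) * change_variance(model, _HORMONE_IDX)
        denom = x[_H9] * x[_GM9] + x[_H12] * x[_GM12]
        pairs = [(_H9, _GM9), (_H12, _GM12)]
    elif target == "age12_cross_trait":
        v = (model.a[_H12] ** 2 + model.c[_H12] ** 2 + model.e[_H12] ** 2) * (
            model.a[_GM12] ** 2 + model.c[_GM12] ** 2 + model.e[_GM12] ** 2
        )
        denom = x[_H12] * x[_GM12]
        pairs = [(_H12, _GM12)]
    else:
        raise ValueError(f"unknown target {target!r}")
    if abs(denom) < 1e-12:
        raise ValueError(f"component {component!r} has no paths to carry the coupling")
    rho = r_target * np.sqrt(v) / denom
    if abs(rho) > 1.0:
        raise ValueError(
            f"requested correlation {r_target} needs factor correlation {rho:.3f} > 1"
        )
    key = {"a": "R_g", "c": "R_c", "e": "R_e"}[component]
    R = getattr(model, key).copy()
    for i, j in pairs:
        R[i, j] = R[j, i] = rho
    out = replace(model, **{key: R})
    out.validate()
    return out


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror a single-sex stratum of a two-occasion twin MRI study:
    21 MZ + 16 DZ complete same-sex pairs plus 19 incomplete-pair singletons
    at baseline, with roughly a third of individuals lost to follow-up.
    """

    rng_seed: int
    n_mz_pairs: int = 21
    n_dz_pairs: int = 16
    n_singletons: int = 19
    path_model: PathModel = field(default_factory=default_path_model)
    grid_shape: tuple[int, int, int] = (10, 10, 10)
    signal_cluster: np.ndarray | Sequence | None = None  # boolean mask or index tuples
    cluster_model: PathModel | None = None  # model active inside the cluster
    smoothing_fwhm_voxels: float = 2.0
    dropout_rate_occasion2: float = 0.34
    hormone: str = "fsh"
    detection_limit: float = 0.11
    assay_log_sd: float = 0.10
    creatinine_log_mean: float = 0.0
    creatinine_log_sd: float = 0.30
    occasion_ages: tuple[float, float] = (9.2, 12.1)
    occasion_age_sd: tuple[float, float] = (0.11, 0.24)
    sex: str = "F"

    def cluster_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        if self.signal_cluster is None:
            return mask
        sc = np.asarray(self.signal_cluster)
        if sc.dtype == bool:
            if sc.shape != tuple(self.grid_shape):
                raise ValueError("boolean signal_cluster must match grid_shape")
            return sc.copy()
        for idx in self.signal_cluster:
            idx = tuple(int(i) for i in idx)
            if any(i < 0 or i >= s for i, s in zip(idx, self.grid_shape)):
                raise ValueError(f"cluster voxel {idx} outside grid {self.grid_shape}")
            mask[idx] = True
        return mask

    def validate(self) -> "SimulationConfig":
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ValueError("pair/singleton counts must be non-negative")
        if not 0.0 <= self.dropout_rate_occasion2 <= 1.0:
            raise ValueError("dropout rate must be in [0, 1]")
        if self.smoothing_fwhm_voxels < 0:
            raise ValueError("smoothing FWHM must be non-negative")
        self.path_model.validate()
        if self.cluster_model is not None:
            self.cluster_model.validate()
        self.cluster_mask()
        return self


@dataclass
class TwinPairRecord:
    """Observed phenotype rows of one family (1 or 2 members)."""

    family_id: str
    zygosity: str
    rows: pd.DataFrame  # individual-occasion rows of this family


@dataclass
class Cohort:
    """A simulated (or loaded) twin cohort.

    ``table`` has one row per individual-occasion; ``voxel_data`` is aligned
    row-wise with ``table`` and holds that individual-occasion's grey-matter
    density map.
    """

    table: pd.DataFrame
    voxel_data: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    hormone: str = "fsh"
    detection_limit: float = 0.11
    occasion_labels: tuple[str, str] = ("age9", "age12")
    truth: PathModel | None = None
    cluster_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.voxel_data is not None and len(self.voxel_data) != len(self.table):
            raise ValueError("voxel_data must align row-wise with the table")

    @property
    def n_individuals(self) -> int:
        return self.table["twin_id"].nunique()

    def pairs(self) -> list[TwinPairRecord]:
        return [
            TwinPairRecord(family_id=fid, zygosity=g["zygosity"].iloc[0], rows=g)
            for fid, g in self.table.groupby("family_id", sort=True)
        ]

    def gm_at_voxel(self, voxel: tuple[int, int, int]) -> np.ndarray:
        """Grey-matter density at one voxel, aligned with ``table`` rows."""
        if self.voxel_data is None:
            raise ValueError("cohort has no voxel data")
        return self.voxel_data[(slice(None),) + tuple(voxel)]

    def voxel_matrix(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(n_rows x n_voxels) density matrix and the flat indices it covers."""
        if self.voxel_data is None:
            raise ValueError("cohort has no voxel data")
        flat = self.voxel_data.reshape(len(self.table), -1)
        if mask is None:
            idx = np.arange(flat.shape[1])
        else:
            mask = np.asarray(mask).reshape(-1)
            if mask.size != flat.shape[1]:
                raise ValueError(
                    f"mask covers {mask.size} voxels but the grid has {flat.shape[1]}"
                )
            idx = np.flatnonzero(mask)
        return flat[:, idx], idx


def _twin_block_cov(R: np.ndarray, rz: float) -> np.ndarray:
    return np.block([[R, rz * R], [rz * R, R]])


def _chol(M: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(M + 1e-12 * np.eye(M.shape[0]))


def _draw_A(R: np.ndarray, zygosity: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2, p) additive-genetic factor draws with the zygosity cross-twin corr."""
    p = R.shape[0]
    rz = GENETIC_CROSS_TWIN_CORR[zygosity]
    if rz == 1.0:
        one = rng.standard_normal((n, p)) @ _chol(R).T
        return np.stack([one, one], axis=1)
    L = _chol(_twin_block_cov(R, rz))
    z = rng.standard_normal((n, 2 * p)) @ L.T
    return z.reshape(n, 2, p)


def _draw_C(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2, p) common-environment draws, bit-identical within a pair."""
    one = rng.standard_normal((n, R.shape[0])) @ _chol(R).T
    return np.stack([one, one], axis=1)


def _draw_E(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2, p) unique-environment draws, independent across twins."""
    p = R.shape[0]
    z = rng.standard_normal((n, 2, p))
    return z @ _chol(R).T


def draw_pair_phenotypes(
    model: PathModel, zygosity: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample (n, 2p) phenotype vectors for n twin pairs from the factor model.

    Built from explicit latent factors, not from the model-implied
    covariance matrix, so it doubles as an independent sampling oracle for
    :func:`pubertwin.paths.expected_cov`.
    """
    model.validate()
    p = model.n_phenotypes
    A = _draw_A(model.R_g, zygosity, n, rng)
    C = _draw_C(model.R_c, n, rng)
    E = _draw_E(model.R_e, n, rng)
    x = model.means + model.a * A + model.c * C + model.e * E
    return x.reshape(n, 2 * p)


def _smooth_standardize(fields: np.ndarray, fwhm: float) -> np.ndarray:
    """Gaussian-smooth the trailing 3 axes and restore unit marginal variance."""
    if fwhm <= 0:
        return fields
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    lead = fields.ndim - 3
    out = gaussian_filter(fields, sigma=(0,) * lead + (sigma,) * 3, mode="nearest")
    sd = out.std()
    if sd > 0:
        out = out / sd
    return out


def _conditional_gm_given_h(R_e: np.ndarray):
    """B, chol(S) of (E_gm | E_h) under the 4-variate E correlation matrix."""
    gm = list(_GM_IDX)
    h = list(_HORMONE_IDX)
    S_hh = R_e[np.ix_(h, h)]
    S_gh = R_e[np.ix_(gm, h)]
    S_gg = R_e[np.ix_(gm, gm)]
    B = S_gh @ np.linalg.inv(S_hh)
    S = S_gg - B @ S_gh.T
    return B, _chol(S)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort from the configured ground truth.

    The model inside the signal cluster is ``config.cluster_model`` (falls
    back to ``path_model``); voxels outside the cluster follow
    ``path_model`` with all hormone-density cross correlations forced to
    zero, so the cluster is the only locus of true coupling.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    model_out = config.path_model.with_zeroed_cross(
        [(i, j) for i in _HORMONE_IDX for j in _GM_IDX]
    )
    model_out.validate()
    model_in = config.cluster_model if config.cluster_model is not None else config.path_model
    model_in.validate()
    mask = config.cluster_mask()

    groups = []
    if config.n_mz_pairs:
        groups.append(("MZ", config.n_mz_pairs, 2))
    if config.n_dz_pairs:
        groups.append(("DZ", config.n_dz_pairs, 2))
    if config.n_singletons:
        groups.append(("DZ", config.n_singletons, 1))

    rows: list[dict] = []
    maps: list[np.ndarray] = []
    fam_counter = 0
    nvox = int(np.prod(config.grid_shape))
    flat_mask = mask.reshape(-1)

    for zygosity, n_pairs, keep_members in groups:
        # latent factors: hormone components shared by both regional models;
        # grey-matter components drawn twice (coupled for the cluster region,
        # uncoupled for the rest) conditionally on the hormone factors.
        A_in = _draw_A(model_in.R_g, zygosity, n_pairs, rng)
        C_in = _draw_C(model_in.R_c, n_pairs, rng)
        E_in = _draw_E(model_in.R_e, n_pairs, rng)
        # out-of-cluster GM A/C factors: independent of the hormone factors
        A_gm_out = _draw_A(model_out.R_g[np.ix_(_GM_IDX, _GM_IDX)], zygosity, n_pairs, rng)
        C_gm_out = _draw_C(model_out.R_c[np.ix_(_GM_IDX, _GM_IDX)], n_pairs, rng)

        # per-voxel E fields for grey matter, spatially smoothed
        field_shape = (n_pairs, 2, 2) + tuple(config.grid_shape)  # pair, twin, component
        xi_in = _smooth_standardize(rng.standard_normal(field_shape), config.smoothing_fwhm_voxels)
        xi_out = _smooth_standardize(rng.standard_normal(field_shape), config.smoothing_fwhm_voxels)
        B_in, L_in = _conditional_gm_given_h(model_in.R_e)
        L_out = _chol(model_out.R_e[np.ix_(_GM_IDX, _GM_IDX)])
        E_h = E_in[:, :, list(_HORMONE_IDX)]  # (n, 2, 2)

        xi_in_f = xi_in.reshape(n_pairs, 2, 2, nvox)
        xi_out_f = xi_out.reshape(n_pairs, 2, 2, nvox)
        # E factor of GM per voxel: conditional mean + correlated residual
        cond_mean = np.einsum("kc,ntc->ntk", B_in, E_h)  # (n, 2, 2)
        E_gm_in = cond_mean[..., None] + np.einsum("kc,ntcv->ntkv", L_in, xi_in_f)
        E_gm_out = np.einsum("kc,ntcv->ntkv", L_out, xi_out_f)

        # compose grey-matter phenotype per voxel for both regions
        def gm_values(model, A_gm, C_gm, E_gm):
            a = model.a[list(_GM_IDX)][None, None, :, None]
            c = model.c[list(_GM_IDX)][None, None, :, None]
            e = model.e[list(_GM_IDX)][None, None, :, None]
            mu = model.means[list(_GM_IDX)][None, None, :, None]
            return mu + a * A_gm[..., None] + c * C_gm[..., None] + e * E_gm

        gm_in = gm_values(model_in, A_in[:, :, list(_GM_IDX)], C_in[:, :, list(_GM_IDX)], E_gm_in)
        gm_out = gm_values(model_out, A_gm_out, C_gm_out, E_gm_out)
        gm = np.where(flat_mask[None, None, None, :], gm_in, gm_out)  # (n, 2, 2, nvox)

        # hormone latent log levels per twin and occasion
        h_lat = (
            model_in.means[list(_HORMONE_IDX)]
            + model_in.a[list(_HORMONE_IDX)] * A_in[:, :, list(_HORMONE_IDX)]
            + model_in.c[list(_HORMONE_IDX)] * C_in[:, :, list(_HORMONE_IDX)]
            + model_in.e[list(_HORMONE_IDX)] * E_in[:, :, list(_HORMONE_IDX)]
        )  # (n, 2, 2) pair, twin, occasion

        ages = np.stack(
            [
                rng.normal(config.occasion_ages[k], config.occasion_age_sd[k], size=n_pairs)
                for k in range(2)
            ],
            axis=1,
        )  # (n, 2) pair, occasion — co-twins share assessment dates

        assay = rng.normal(0.0, config.assay_log_sd, size=(n_pairs, 2, 2, 2))
        creat = np.exp(
            rng.normal(config.creatinine_log_mean, config.creatinine_log_sd, size=(n_pairs, 2, 2, 2))
        )
        drop = rng.random((n_pairs, 2)) < config.dropout_rate_occasion2

        urine = config.hormone in {"lh", "fsh", "estradiol"}
        for i in range(n_pairs):
            fam_counter += 1
            fid = f"fam{fam_counter:04d}"
            for t in range(keep_members):
                tid = f"{fid}_t{t + 1}"
                for occ in range(2):
                    if occ == 1 and drop[i, t]:
                        continue
                    # day-level raw concentrations on the assay scale
                    day_log = h_lat[i, t, occ] + assay[i, t, occ]
                    corrected = np.exp(day_log)  # per-day level per mmol creatinine
                    raw = corrected * creat[i, t, occ] if urine else corrected
                    below = raw < config.detection_limit
                    rows.append(
                        {
                            "family_id": fid,
                            "twin_id": tid,
                            "zygosity": zygosity,
                            "sex": config.sex,
                            "occasion": occ + 1,
                            "age": ages[i, occ],
                            "hormone_day1": np.nan if below[0] else raw[0],
                            "hormone_day2": np.nan if below[1] else raw[1],
                            "creatinine_day1": creat[i, t, occ, 0] if urine else np.nan,
                            "creatinine_day2": creat[i, t, occ, 1] if urine else np.nan,
                            "below_limit_day1": bool(below[0]),
                            "below_limit_day2": bool(below[1]),
                            "voxel_map_path": "",
                        }
                    )
                    maps.append(gm[i, t, occ].reshape(config.grid_shape))

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    voxel_data = np.stack(maps) if maps else np.empty((0,) + tuple(config.grid_shape))
    return Cohort(
        table=table,
        voxel_data=voxel_data,
        grid_shape=tuple(config.grid_shape),
        hormone=config.hormone,
        detection_limit=config.detection_limit,
        truth=model_in,
        cluster_mask=mask,
    )


# -- persistence --------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str) -> str:
    """Write the cohort table (CSV) and one NIfTI map per individual-occasion.

    Returns the path of the table.  Maps go to ``<out_dir>/maps/`` and the
    table's ``voxel_map_path`` column points at them (relative paths).
    """
    os.makedirs(out_dir, exist_ok=True)
    table = cohort.table.copy()
    if cohort.voxel_data is not None:
        maps_dir = os.path.join(out_dir, "maps")
        os.makedirs(maps_dir, exist_ok=True)
        paths = []
        for k, (_, row) in enumerate(table.iterrows()):
            rel = os.path.join("maps", f"{row.twin_id}_occ{row.occasion}.nii")
            img = nib.Nifti1Image(
                np.asarray(cohort.voxel_data[k], dtype=np.float64), affine=np.eye(4)
            )
            nib.save(img, os.path.join(out_dir, rel))
            paths.append(rel)
        table["voxel_map_path"] = paths
    csv_path = os.path.join(out_dir, "cohort.csv")
    table.to_csv(csv_path, index=False)
    meta = {
        "hormone": cohort.hormone,
        "detection_limit": cohort.detection_limit,
        "grid_shape": list(cohort.grid_shape) if cohort.grid_shape else None,
    }
    with open(os.path.join(out_dir, "cohort.json"), "w") as fh:
        import json

        json.dump(meta, fh, indent=2)
    return csv_path


def read_cohort(csv_path: str, load_maps: bool = True) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (lossless round-trip)."""
    table = pd.read_csv(
        csv_path,
        dtype={"family_id": str, "twin_id": str},
        keep_default_na=True,
    )
    table["voxel_map_path"] = table["voxel_map_path"].fillna("")
    base = os.path.dirname(os.path.abspath(csv_path))
    meta_path = os.path.join(base, "cohort.json")
    hormone, limit, grid = "fsh", 0.11, None
    if os.path.exists(meta_path):
        import json

        with open(meta_path) as fh:
            meta = json.load(fh)
        hormone = meta.get("hormone", hormone)
        limit = meta.get("detection_limit", limit)
        grid = tuple(meta["grid_shape"]) if meta.get("grid_shape") else None
    voxel_data = None
    if load_maps and (table["voxel_map_path"] != "").any():
        vols = []
        for rel in table["voxel_map_path"]:
            img = nib.load(os.path.join(base, rel))
            vols.append(np.asarray(img.dataobj, dtype=np.float64))
        voxel_data = np.stack(vols)
        grid = voxel_data.shape[1:]
    return Cohort(
        table=table,
        voxel_data=voxel_data,
        grid_shape=grid,
        hormone=hormone,
        detection_limit=limit,
    )
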