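"""Mass-univariate voxel scanning with FDR control.

Fits the longitudinal twin model independently in every in-mask voxel,
tests one of the two association hypotheses by likelihood ratio —

* ``change_corr``: the correlation between latent hormone change and latent
  grey-matter-density change is zero;
* ``age12_cross_trait``: the hormone-density covariance at the second
  occasion is zero —

and controls the expected false-discovery proportion over voxels with the
Benjamini-Hochberg step-up rule.  Within the significant set, per-voxel
component-zeroing tests (is the genetic / common-environment /
unique-environment part of the covariance zero?) get their own FDR pass to
attribute each association to the component driving it.

Voxels are independent work units: every voxel's restart seed derives from
the master seed and the voxel's flat index, so results are bit-identical
regardless of processing order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .hormones import prepare_hormone_table
from .model import FamilyData, TwinACEModel, lrt
from .simulate import Cohort

__all__ = [
    "VoxelResultMap",
    "FDRResult",
    "ScanSummary",
    "scan",
    "fdr_threshold",
    "summarize_significant",
    "write_maps",
]


@dataclass
class FDRResult:
    """Outcome of the step-up false-discovery-rate procedure."""

    alpha: float
    critical_p: float | None
    critical_chi2: float | None
    n_rejected: int
    mask: np.ndarray  # boolean over the supplied p-values
    method: str = "bh"

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "critical_p": self.critical_p,
            "critical_chi2": self.critical_chi2,
            "n_rejected": int(self.n_rejected),
            "n_tests": int(self.mask.size),
            "method": self.method,
        }


def fdr_threshold(p_values: np.ndarray, alpha: float = 0.05, method: str = "bh") -> FDRResult:
    """Benjamini-Hochberg step-up FDR control (``method="by"`` for the
    conservative c(V)=sum 1/i variant).

    Sorts the m p-values, finds the largest k with p(k) <= k*alpha/(c(V)*m)
    and rejects the k smallest.  ``critical_p`` is the largest rejected
    p-value and ``critical_chi2`` the 1-df chi-square deviate it maps to.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject = multipletests(p, alpha=alpha, method=sm_method)[0]
    n_rej = int(reject.sum())
    crit_p = float(p[reject].max()) if n_rej else None
    crit_chi2 = float(stats.chi2.isf(crit_p, 1)) if crit_p is not None and crit_p > 0 else (
        float("inf") if n_rej else None
    )
    return FDRResult(
        alpha=alpha,
        critical_p=crit_p,
        critical_chi2=crit_chi2,
        n_rejected=n_rej,
        mask=reject,
        method=method,
    )


@dataclass
class VoxelResultMap:
    """Per-voxel fitted statistics of one hypothesis scan."""

    grid_shape: tuple[int, int, int]
    voxel_indices: np.ndarray  # flat indices of analysed voxels
    r: np.ndarray  # fitted correlation (r_ch or age-12 cross-trait r)
    chi2: np.ndarray
    p: np.ndarray
    rph_a: np.ndarray
    rph_c: np.ndarray
    rph_e: np.ndarray
    converged: np.ndarray
    hypothesis: str = "change_corr"
    hormone: str = "fsh"
    failed_voxels: list = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def usable(self) -> np.ndarray:
        """Voxels whose fits converged (the p-value pool for FDR)."""
        return self.converged & np.isfinite(self.p)

    def to_volume(self, name: str, fill: float = np.nan) -> np.ndarray:
        vol = np.full(int(np.prod(self.grid_shape)), fill)
        vol[self.voxel_indices] = getattr(self, name)
        return vol.reshape(self.grid_shape)


_HYPOTHESIS_CONSTRAINT = {
    "change_corr": "change_corr_zero",
    "age12_cross_trait": "cross_trait_age12_zero",
}
_HYPOTHESIS_TARGET = {
    "change_corr": "change",
    "age12_cross_trait": "age12_cross_trait",
}


def _voxel_seed(master_seed: int, flat_index: int) -> int:
    return int((np.uint64(master_seed) * np.uint64(1000003) + np.uint64(flat_index)) % (2**31))


def _assembly_index(table: pd.DataFrame, occasions: tuple[int, ...]):
    """Map each table row to (family row, density position) in the pair vector."""
    table = table.reset_index(drop=True)
    p = 2 * len(occasions)
    fam_ids = sorted(table["family_id"].unique())
    fam_row = {f: i for i, f in enumerate(fam_ids)}
    twin_rank = {
        (f, t): r
        for f, g in table.groupby("family_id")
        for r, t in enumerate(sorted(g["twin_id"].unique())[:2])
    }
    occ_pos = {occ: 2 * k for k, occ in enumerate(occasions)}
    rows, fams, positions = [], [], []
    for ridx, r in table.iterrows():
        rank = twin_rank.get((r["family_id"], r["twin_id"]))
        if rank is None or r["occasion"] not in occ_pos:
            continue
        rows.append(ridx)
        fams.append(fam_row[r["family_id"]])
        positions.append(rank * p + occ_pos[r["occasion"]] + 1)  # +1: density slot
    zyg = np.empty(len(fam_ids), dtype=object)
    ages = np.zeros((len(fam_ids), 2 * p))
    base_y = np.full((len(fam_ids), 2 * p), np.nan)
    for ridx, r in table.iterrows():
        rank = twin_rank.get((r["family_id"], r["twin_id"]))
        if rank is None or r["occasion"] not in occ_pos:
            continue
        f = fam_row[r["family_id"]]
        zyg[f] = r["zygosity"]
        pos = rank * p + occ_pos[r["occasion"]]
        base_y[f, pos] = r.get("hormone", np.nan)
        ages[f, pos] = ages[f, pos + 1] = r["age"]
    for f, g in table.groupby("family_id"):
        zyg[fam_row[f]] = g["zygosity"].iloc[0]
    return (
        np.array(rows),
        np.array(fams),
        np.array(positions),
        base_y,
        zyg,
        ages,
        fam_ids,
        p,
    )


def scan(
    cohort: Cohort,
    hypothesis: str = "change_corr",
    mask: np.ndarray | None = None,
    seed: int = 0,
    n_starts: int = 2,
    age_effects: bool = False,
    prepare: bool = True,
    impute_below_limit: bool = False,
) -> VoxelResultMap:
    """Fit full and constrained models in every in-mask voxel.

    Returns per-voxel correlation, -2 Δ log L, its 1-df p-value and the
    rph decomposition of the full fit.  Voxels whose fits fail to converge
    are flagged (and later excluded from the FDR pool), never dropped
    silently.
    """
    if hypothesis not in _HYPOTHESIS_CONSTRAINT:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    if cohort.voxel_data is None:
        raise ValueError("cohort has no voxel data")
    table = cohort.table
    if prepare and "hormone" not in table.columns:
        table = prepare_hormone_table(
            table,
            hormone=cohort.hormone,
            detection_limit=cohort.detection_limit,
            impute_below_limit=impute_below_limit,
        )
    voxmat, flat_idx = cohort.voxel_matrix(mask)
    occasions = (1, 2)
    (rows, fams, positions, base_y, zyg, ages, fam_ids, p) = _assembly_index(table, occasions)
    constraint_name = _HYPOTHESIS_CONSTRAINT[hypothesis]
    target = _HYPOTHESIS_TARGET[hypothesis]

    n_vox = len(flat_idx)
    out = {
        k: np.full(n_vox, np.nan)
        for k in ("r", "chi2", "p", "rph_a", "rph_c", "rph_e")
    }
    converged = np.zeros(n_vox, dtype=bool)
    failed = []

    # a single cohort-level warm start (whole-grid mean density) keeps
    # per-voxel fits fast and is identical for every voxel and any analysis
    # mask, so scan output does not depend on processing order or partition
    warm = None
    try:
        mean_gm = np.nanmean(cohort.voxel_data.reshape(len(cohort.table), -1), axis=1)
        y0 = base_y.copy()
        y0[fams, positions] = mean_gm[rows]
        data0 = FamilyData(y0, zyg, ages, fam_ids, n_phenotypes=p)
        warm = TwinACEModel(data0, age_effects=age_effects).fit(
            n_starts=max(n_starts, 2), seed=_voxel_seed(seed, 2**20)
        ).path_model
    except Exception:
        warm = None

    for v in range(n_vox):
        y = base_y.copy()
        y[fams, positions] = voxmat[rows, v]
        data = FamilyData(y, zyg, ages, fam_ids, n_phenotypes=p)
        vseed = _voxel_seed(seed, int(flat_idx[v]))
        try:
            m = TwinACEModel(data, age_effects=age_effects)
            full = m.fit(n_starts=n_starts, seed=vseed, start_model=warm)
            con = m.fit(
                constraint=constraint_name,
                constraint_target=target,
                n_starts=n_starts,
                seed=vseed,
                start_model=full.path_model,
            )
            test = lrt(full, con)
        except Exception as exc:  # pragma: no cover - defensive
            failed.append((int(flat_idx[v]), str(exc)))
            continue
        cs = full.change_stats(target=target)
        out["r"][v] = cs.r_ch
        out["chi2"][v] = test.chi2
        out["p"][v] = test.p
        out["rph_a"][v] = cs.rph_a
        out["rph_c"][v] = cs.rph_c
        out["rph_e"][v] = cs.rph_e
        converged[v] = full.converged and con.converged
        if not converged[v]:
            failed.append((int(flat_idx[v]), "non-convergence"))

    return VoxelResultMap(
        grid_shape=tuple(cohort.grid_shape),
        voxel_indices=flat_idx,
        r=out["r"],
        chi2=out["chi2"],
        p=out["p"],
        rph_a=out["rph_a"],
        rph_c=out["rph_c"],
        rph_e=out["rph_e"],
        converged=converged,
        hypothesis=hypothesis,
        hormone=cohort.hormone,
        failed_voxels=failed,
    )


@dataclass
class ScanSummary:
    """Post-FDR summary: mean correlation, clusters and component attribution."""

    n_significant: int
    mean_r: float | None
    clusters: list  # (size, centroid) per 6-connected component
    attribution: dict | None  # fractions per component among significant voxels
    component_fdr: dict | None

    def as_dict(self) -> dict:
        return {
            "n_significant": self.n_significant,
            "mean_r": self.mean_r,
            "clusters": [
                {"size": int(s), "centroid": [float(c) for c in ctr]} for s, ctr in self.clusters
            ],
            "attribution": self.attribution,
            "component_fdr": {k: v.as_dict() for k, v in self.component_fdr.items()}
            if self.component_fdr
            else None,
        }


def _clusters(mask_volume: np.ndarray) -> list:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    lab, n = ndimage.label(mask_volume, structure=structure)
    out = []
    for k in range(1, n + 1):
        where = np.argwhere(lab == k)
        out.append((len(where), tuple(where.mean(axis=0))))
    out.sort(reverse=True)
    return out


def summarize_significant(
    vmap: VoxelResultMap,
    fdr: FDRResult,
    cohort: Cohort | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    n_starts: int = 2,
) -> ScanSummary:
    """Summarise the FDR-significant voxel set.

    Reports the mean fitted correlation over significant voxels and their
    6-connected clusters.  When the cohort is supplied, each significant
    voxel additionally gets three component-zeroing likelihood-ratio tests
    (genetic / common-environment / unique-environment part of the tested
    covariance forced to zero); each component's p-values get their own FDR
    pass within the significant set, and a voxel is attributed to a
    component when that component's test (alone) survives — voxels where
    none or several components survive are counted as undetermined.
    """
    usable = vmap.usable()
    if fdr.mask.size != int(usable.sum()):
        raise ValueError("FDR result does not match the map's usable voxel count")
    sig_local = np.flatnonzero(usable)[fdr.mask]
    n_sig = len(sig_local)
    vol_mask = np.zeros(int(np.prod(vmap.grid_shape)), dtype=bool)
    vol_mask[vmap.voxel_indices[sig_local]] = True
    clusters = _clusters(vol_mask.reshape(vmap.grid_shape))
    if n_sig == 0:
        return ScanSummary(0, None, [], None, None)
    mean_r = float(np.nanmean(vmap.r[sig_local]))
    if cohort is None:
        return ScanSummary(n_sig, mean_r, clusters, None, None)

    table = cohort.table
    if "hormone" not in table.columns:
        table = prepare_hormone_table(
            table, hormone=cohort.hormone, detection_limit=cohort.detection_limit
        )
    target = _HYPOTHESIS_TARGET[vmap.hypothesis]
    (rows, fams, positions, base_y, zyg, ages, fam_ids, p) = _assembly_index(table, (1, 2))
    voxmat_all = cohort.voxel_data.reshape(len(cohort.table), -1)

    comp_p = {c: np.full(n_sig, np.nan) for c in "ace"}
    for k, vloc in enumerate(sig_local):
        flat = int(vmap.voxel_indices[vloc])
        y = base_y.copy()
        y[fams, positions] = voxmat_all[rows, flat]
        data = FamilyData(y, zyg, ages, fam_ids, n_phenotypes=p)
        vseed = _voxel_seed(seed, flat)
        m = TwinACEModel(data)
        full = m.fit(n_starts=n_starts, seed=vseed)
        for c in "ace":
            con = m.fit(
                constraint=f"rph_{c}_zero",
                constraint_target=target,
                n_starts=n_starts,
                seed=vseed,
                start_model=full.path_model,
            )
            comp_p[c][k] = lrt(full, con).p

    comp_fdr = {c: fdr_threshold(comp_p[c], alpha=alpha, method=fdr.method) for c in "ace"}
    rej = {c: comp_fdr[c].mask for c in "ace"}
    single = {
        c: rej[c] & ~np.any([rej[o] for o in "ace" if o != c], axis=0) for c in "ace"
    }
    attributed = {f"rph_{c}": float(np.mean(single[c])) for c in "ace"}
    attributed["undetermined"] = float(
        np.mean(~(single["a"] | single["c"] | single["e"]))
    )
    return ScanSummary(n_sig, mean_r, clusters, attributed, comp_fdr)


def write_maps(vmap: VoxelResultMap, fdr: FDRResult, out_dir: str) -> dict[str, str]:
    """Write NIfTI result volumes and a JSON sidecar; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    usable = vmap.usable()
    sig_local = np.flatnonzero(usable)[fdr.mask]
    sig_flat = vmap.voxel_indices[sig_local]
    volumes = {
        "r": vmap.to_volume("r"),
        "chi2": vmap.to_volume("chi2"),
        "neglog10p": -np.log10(np.maximum(vmap.to_volume("p"), 1e-300)),
        "rph_a": vmap.to_volume("rph_a"),
        "rph_c": vmap.to_volume("rph_c"),
        "rph_e": vmap.to_volume("rph_e"),
    }
    mask_vol = np.zeros(int(np.prod(vmap.grid_shape)), dtype=np.uint8)
    mask_vol[sig_flat] = 1
    for name, vol in volumes.items():
        path = os.path.join(out_dir, f"{vmap.hypothesis}_{name}.nii")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), np.eye(4)), path)
        paths[name] = path
    mpath = os.path.join(out_dir, f"{vmap.hypothesis}_sigmask.nii")
    nib.save(
        nib.Nifti1Image(mask_vol.reshape(vmap.grid_shape), np.eye(4)), mpath
    )
    paths["sigmask"] = mpath
    sidecar = {
        "hypothesis": vmap.hypothesis,
        "hormone": vmap.hormone,
        "grid_shape": list(vmap.grid_shape),
        "n_voxels_analysed": int(vmap.n_voxels),
        "n_voxels_usable": int(usable.sum()),
        "failed_voxels": vmap.failed_voxels,
        "fdr": fdr.as_dict(),
    }
    jpath = os.path.join(out_dir, f"{vmap.hypothesis}_fdr.json")
    with open(jpath, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    paths["sidecar"] = jpath
    return paths
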