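"""FIML estimation of the correlated-factor ACE twin model.

The interface follows the model/results convention of statsmodels:
:class:`TwinACEModel` is constructed from family-structured data,
``fit()`` maximises the full-information maximum likelihood (FIML) over
path coefficients, factor correlations and means — optionally under a
nonlinear equality constraint — and returns a :class:`TwinACEResults`
carrying the fitted :class:`~pubertwin.paths.PathModel`, the log-likelihood
and derived change statistics.  Nested fits are compared with
:func:`lrt` (-2 Δ log L against chi-square).

Each family contributes the multivariate-normal log-density of exactly its
observed phenotype subvector (twin 1 then twin 2, up to 2p values), using
the matching submatrix of the model-implied pair covariance: missing
occasions, censored hormone values and incomplete pairs all enter without
imputation, which is consistent under MCAR/MAR missingness.

Factor correlation matrices are parameterized hyperspherically (angles of a
Cholesky factor with unit-norm rows, box-bounded inside (0, pi)), so the
optimizer can never leave the positive-semidefinite cone; ``e`` paths are
kept positive through a log link.  Gradients are analytic throughout — the
pattern-wise score with respect to the pair covariance and mean vector is
chained through closed-form derivatives of the component matrices and of
each correlation matrix with respect to its angles — which keeps per-voxel
fits fast enough for mass-univariate scanning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .changes import ChangeStats, rph_decomposition
from .paths import (
    GENETIC_CROSS_TWIN_CORR,
    PathModel,
    angles_to_corr,
    corr_to_angles,
    corr_with_grads,
)

__all__ = [
    "FamilyData",
    "TwinACEModel",
    "TwinACEResults",
    "FitResult",
    "LRTResult",
    "Constraint",
    "fiml_loglik",
    "lrt",
]

_LOG2PI = math.log(2.0 * math.pi)

CONSTRAINT_NAMES = (
    "change_corr_zero",
    "cross_trait_age12_zero",
    "rph_a_zero",
    "rph_c_zero",
    "rph_e_zero",
)

# (i, j, sign) terms of the change covariance in the 4-variate model
_CH_TERMS = ((2, 3, +1.0), (0, 1, +1.0), (0, 3, -1.0), (1, 2, -1.0))


# ---------------------------------------------------------------------------
# data container


@dataclass
class _Pattern:
    zygosity: str
    obs: np.ndarray  # observed positions within the 2p pair vector
    Y: np.ndarray  # (n_fam, k) observed values
    ages: np.ndarray  # (n_fam, k) centred ages at each observed position
    families: list


class FamilyData:
    """Twin-pair observations grouped by zygosity and missingness pattern.

    ``y`` rows hold the 2p-vector (twin 1's p phenotypes, then twin 2's)
    with NaN marking missing values; singletons are pairs whose second
    member is entirely missing.
    """

    def __init__(
        self,
        y: np.ndarray,
        zygosity: np.ndarray,
        ages: np.ndarray | None = None,
        family_ids: list | None = None,
        n_phenotypes: int | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] % 2:
            raise ValueError("y must be (n_families, 2*p)")
        self.p = n_phenotypes or y.shape[1] // 2
        if y.shape[1] != 2 * self.p:
            raise ValueError("y width inconsistent with n_phenotypes")
        zygosity = np.asarray(zygosity)
        bad = set(np.unique(zygosity)) - set(GENETIC_CROSS_TWIN_CORR)
        if bad:
            raise ValueError(f"unknown zygosity labels {bad}")
        keep = np.isfinite(y).any(axis=1)
        self.y = y[keep]
        self.zygosity = zygosity[keep]
        if ages is None:
            ages = np.zeros_like(y)
        ages = np.asarray(ages, dtype=float)[keep]
        self.family_ids = (
            [family_ids[i] for i in np.flatnonzero(keep)]
            if family_ids is not None
            else [f"fam{i}" for i in range(keep.sum())]
        )
        # centre ages so mean intercepts stay interpretable
        obs = np.isfinite(self.y)
        self.age_center = float(np.nanmean(np.where(obs, ages, np.nan))) if obs.any() else 0.0
        ages = np.where(np.isfinite(ages), ages - self.age_center, 0.0)
        self.ages = ages
        self.n_families = len(self.y)
        self.n_observed = int(obs.sum())
        self.obs_per_phenotype = np.array(
            [obs[:, [j, j + self.p]].sum() for j in range(self.p)]
        )
        self._patterns = self._group_patterns()

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        hormone_col: str = "hormone",
        gm_col: str | None = "gm",
        gm_values: np.ndarray | None = None,
        occasions: tuple[int, ...] = (1, 2),
    ) -> "FamilyData":
        """Assemble pair vectors from an individual-occasion long table.

        Phenotype order per twin is (hormone, density) per occasion, i.e.
        the 4-variate longitudinal layout for ``occasions=(1, 2)`` and the
        bivariate second-occasion layout for ``occasions=(2,)``.
        ``gm_values`` may supply the density column directly (aligned with
        table rows), e.g. one voxel's data.
        """
        table = table.reset_index(drop=True)
        if gm_values is not None:
            gm = np.asarray(gm_values, dtype=float)
        elif gm_col is not None and gm_col in table.columns:
            gm = table[gm_col].to_numpy(dtype=float)
        else:
            gm = None
        if gm is not None and gm.shape[0] != len(table):
            raise ValueError("gm_values must align row-wise with the table")
        p = 2 * len(occasions)
        fam_ids, ys, zygs, ages = [], [], [], []
        for fid, g in table.groupby("family_id", sort=True):
            twins = sorted(g["twin_id"].unique())[:2]
            yv = np.full(2 * p, np.nan)
            av = np.full(2 * p, np.nan)
            for t, tid in enumerate(twins):
                sub = g[g["twin_id"] == tid]
                for k, occ in enumerate(occasions):
                    row = sub[sub["occasion"] == occ]
                    if row.empty:
                        continue
                    r = row.iloc[0]
                    base = t * p + 2 * k
                    yv[base] = r[hormone_col] if hormone_col in row.columns else np.nan
                    if gm is not None:
                        yv[base + 1] = gm[row.index[0]]
                    av[base] = av[base + 1] = r["age"]
            fam_ids.append(fid)
            ys.append(yv)
            zygs.append(g["zygosity"].iloc[0])
            ages.append(av)
        return cls(
            np.array(ys), np.array(zygs), np.array(ages), fam_ids, n_phenotypes=p
        )

    def _group_patterns(self) -> list[_Pattern]:
        pats: dict[tuple, list[int]] = {}
        obs = np.isfinite(self.y)
        for i in range(self.n_families):
            key = (str(self.zygosity[i]), obs[i].tobytes())
            pats.setdefault(key, []).append(i)
        out = []
        for (zyg, mask_bytes), idx in sorted(pats.items()):
            mask = np.frombuffer(mask_bytes, dtype=bool)
            o = np.flatnonzero(mask)
            rows = np.array(idx)
            out.append(
                _Pattern(
                    zygosity=zyg,
                    obs=o,
                    Y=self.y[np.ix_(rows, o)],
                    ages=self.ages[np.ix_(rows, o)],
                    families=[self.family_ids[i] for i in idx],
                )
            )
        return out

    def standardized(self) -> tuple["FamilyData", np.ndarray, np.ndarray]:
        """Copy with each phenotype centred/scaled; returns (data, shift, scale)."""
        p = self.p
        shift = np.zeros(p)
        scale = np.ones(p)
        for j in range(p):
            vals = np.concatenate([self.y[:, j], self.y[:, j + p]])
            vals = vals[np.isfinite(vals)]
            if vals.size > 1 and vals.std() > 0:
                shift[j] = vals.mean()
                scale[j] = vals.std()
        full_shift = np.tile(shift, 2)
        full_scale = np.tile(scale, 2)
        ystd = (self.y - full_shift) / full_scale
        out = FamilyData(
            ystd,
            self.zygosity,
            self.ages + self.age_center,
            self.family_ids,
            n_phenotypes=p,
        )
        return out, shift, scale


# ---------------------------------------------------------------------------
# likelihood core


def _pair_cov(model: PathModel) -> dict[str, np.ndarray]:
    A, C, E = model.component_matrices()
    within = A + C + E
    return {
        z: np.block([[within, rz * A + C], [rz * A + C, within]])
        for z, rz in GENETIC_CROSS_TWIN_CORR.items()
    }


def _loglik_core(
    sigma_by_z: dict[str, np.ndarray],
    mu_full: np.ndarray,
    slopes_full: np.ndarray | None,
    patterns: list[_Pattern],
    want_grad: bool = False,
):
    """FIML log-likelihood; optionally d ll / d Sigma_z, d ll / d mu terms."""
    twop = mu_full.shape[0]
    ll = 0.0
    G = {z: np.zeros((twop, twop)) for z in sigma_by_z} if want_grad else None
    h = np.zeros(twop) if want_grad else None
    h_age = np.zeros(twop) if want_grad else None
    for pat in patterns:
        sub = sigma_by_z[pat.zygosity][np.ix_(pat.obs, pat.obs)]
        n, k = pat.Y.shape
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return (-np.inf, None, None, None) if want_grad else -np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Linv = np.linalg.inv(L)
        Sinv = Linv.T @ Linv
        M = mu_full[pat.obs][None, :]
        if slopes_full is not None:
            M = M + slopes_full[pat.obs][None, :] * pat.ages
        R = pat.Y - M
        X = Sinv @ R.T  # (k, n) columns are Sigma^-1 r_i
        quad = float(np.sum(R.T * X))
        ll += -0.5 * (n * k * _LOG2PI + n * logdet + quad)
        if want_grad:
            Go = 0.5 * (X @ X.T - n * Sinv)
            G[pat.zygosity][np.ix_(pat.obs, pat.obs)] += Go
            h[pat.obs] += X.sum(axis=1)
            h_age[pat.obs] += np.einsum("kn,nk->k", X, pat.ages)
    if want_grad:
        return ll, G, h, h_age
    return ll


def fiml_loglik(model: PathModel, data: FamilyData, age_effects: bool = False) -> float:
    """Full-information ML log-likelihood of the data under ``model``.

    Sums, over families, the log-density of each family's observed
    phenotype subvector under the matching marginal of the model-implied
    pair distribution.  Raises if a family's observed submatrix is
    singular.
    """
    model.validate()
    if model.n_phenotypes != data.p:
        raise ValueError("model and data disagree on the number of phenotypes")
    sig = _pair_cov(model)
    mu = np.tile(model.means, 2)
    slopes = (
        np.tile(model.age_slopes, 2) if age_effects and model.age_slopes is not None else None
    )
    for pat in data._patterns:
        sub = sig[pat.zygosity][np.ix_(pat.obs, pat.obs)]
        if np.linalg.matrix_rank(sub, tol=1e-12) < len(pat.obs):
            raise np.linalg.LinAlgError(
                f"singular observed covariance for family {pat.families[0]} "
                f"(pattern {pat.obs.tolist()})"
            )
    ll = _loglik_core(sig, mu, slopes, data._patterns)
    if not np.isfinite(ll):
        raise np.linalg.LinAlgError("non-finite likelihood (near-singular model)")
    return float(ll)


# ---------------------------------------------------------------------------
# parameterization


_ANGLE_MARGIN = 0.02  # keep Cholesky angles away from the degenerate edges


class _Parameterization:
    """Pack/unpack a PathModel into an optimizer parameter vector.

    Paths ``a``/``c`` and means are free; ``e`` is log-linked; the three
    correlation matrices are hyperspherical angles in (0, pi), box-bounded
    away from the edges (any interior angle vector yields a valid
    correlation matrix).
    """

    def __init__(self, p: int, age_effects: bool = False) -> None:
        self.p = p
        self.m = p * (p - 1) // 2
        self.age_effects = age_effects
        n = 3 * p + 3 * self.m + p + (p if age_effects else 0)
        self.n = n
        i = 0
        self.s_a = slice(i, i + p); i += p
        self.s_c = slice(i, i + p); i += p
        self.s_t = slice(i, i + p); i += p  # log e
        self.s_ug = slice(i, i + self.m); i += self.m
        self.s_uc = slice(i, i + self.m); i += self.m
        self.s_ue = slice(i, i + self.m); i += self.m
        self.s_mu = slice(i, i + p); i += p
        self.s_b = slice(i, i + p) if age_effects else None
        self.n_cov = 3 * p + 3 * self.m
        self.angle_slices = (self.s_ug, self.s_uc, self.s_ue)
        self.bounds: list[tuple] = [(None, None)] * n
        for k in range(self.s_t.start, self.s_t.stop):
            self.bounds[k] = (-8.0, 4.0)
        for sl in self.angle_slices:
            for k in range(sl.start, sl.stop):
                self.bounds[k] = (_ANGLE_MARGIN, np.pi - _ANGLE_MARGIN)

    def unpack(self, theta: np.ndarray) -> PathModel:
        p = self.p
        e = np.exp(np.clip(theta[self.s_t], -30, 10))
        ang = lambda sl: np.clip(theta[sl], 1e-3, np.pi - 1e-3)
        return PathModel(
            a=theta[self.s_a].copy(),
            c=theta[self.s_c].copy(),
            e=e,
            R_g=angles_to_corr(ang(self.s_ug), p),
            R_c=angles_to_corr(ang(self.s_uc), p),
            R_e=angles_to_corr(ang(self.s_ue), p),
            means=theta[self.s_mu].copy(),
            age_slopes=theta[self.s_b].copy() if self.s_b else None,
        )

    def pack(self, model: PathModel) -> np.ndarray:
        theta = np.zeros(self.n)
        theta[self.s_a] = model.a
        theta[self.s_c] = model.c
        theta[self.s_t] = np.clip(np.log(np.maximum(model.e, 1e-8)), -8.0, 4.0)
        for sl, R in ((self.s_ug, model.R_g), (self.s_uc, model.R_c), (self.s_ue, model.R_e)):
            Rc = np.clip(R, -0.999, 0.999)
            np.fill_diagonal(Rc, 1.0)
            theta[sl] = np.clip(
                corr_to_angles(Rc, jitter=1e-6), _ANGLE_MARGIN, np.pi - _ANGLE_MARGIN
            )
        theta[self.s_mu] = model.means
        if self.s_b:
            theta[self.s_b] = model.age_slopes if model.age_slopes is not None else 0.0
        return theta

    def clip(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        for k, (lo, hi) in enumerate(self.bounds):
            if lo is not None:
                out[k] = min(max(out[k], lo), hi)
        return out


# ---------------------------------------------------------------------------
# constraints


@dataclass(frozen=True)
class Constraint:
    """A scalar equality constraint g(model) = 0 on the fitted parameters."""

    name: str
    kind: str  # 'cov_ch' | 'cov_ij' | 'comp_ch' | 'comp_ij'
    component: str | None = None
    i: int = 0
    j: int = 0

    def value(self, model: PathModel) -> float:
        comps = {"a": (model.a, model.R_g), "c": (model.c, model.R_c), "e": (model.e, model.R_e)}

        def cov_ij(i, j, only=None):
            total = 0.0
            for name, (x, R) in comps.items():
                if only is not None and name != only:
                    continue
                total += x[i] * R[i, j] * x[j]
            return total

        if self.kind == "cov_ch":
            return sum(s * cov_ij(i, j) for i, j, s in _CH_TERMS)
        if self.kind == "comp_ch":
            return sum(s * cov_ij(i, j, self.component) for i, j, s in _CH_TERMS)
        if self.kind == "cov_ij":
            return cov_ij(self.i, self.j)
        if self.kind == "comp_ij":
            return cov_ij(self.i, self.j, self.component)
        raise ValueError(f"unknown constraint kind {self.kind}")

    def terms(self) -> tuple[tuple, tuple]:
        """((i, j, sign), ...) covariance terms and the components involved."""
        if self.kind in ("cov_ch", "comp_ch"):
            ij = _CH_TERMS
        else:
            ij = ((self.i, self.j, 1.0),)
        comps = ("a", "c", "e") if self.kind.startswith("cov") else (self.component,)
        return ij, comps

    @staticmethod
    def for_name(name: str, p: int, target: str = "change") -> "Constraint":
        """Resolve a public constraint name for a p-phenotype model.

        ``target`` picks which covariance the component-zero constraints act
        on in the 4-variate model: the change covariance (``"change"``) or
        the second-occasion cross-trait covariance (``"age12_cross_trait"``).
        """
        if name == "change_corr_zero":
            if p != 4:
                raise ValueError("change_corr_zero needs the 4-phenotype model")
            return Constraint(name, "cov_ch")
        if name == "cross_trait_age12_zero":
            i, j = (2, 3) if p == 4 else (0, 1)
            return Constraint(name, "cov_ij", i=i, j=j)
        if name in ("rph_a_zero", "rph_c_zero", "rph_e_zero"):
            comp = name[4]
            if p == 4 and target == "change":
                return Constraint(name, "comp_ch", component=comp)
            i, j = (2, 3) if p == 4 else (0, 1)
            return Constraint(name, "comp_ij", component=comp, i=i, j=j)
        raise ValueError(f"unknown constraint {name!r}; choose from {CONSTRAINT_NAMES}")


# ---------------------------------------------------------------------------
# results


@dataclass
class LRTResult:
    """Likelihood-ratio test of a constrained against a full model."""

    chi2: float
    df: int
    p: float

    def __str__(self) -> str:
        return f"chi2({self.df}) = {self.chi2:.4f}, p = {self.p:.4g}"


def lrt(full: "TwinACEResults", constrained: "TwinACEResults") -> LRTResult:
    """-2 Δ log-likelihood referred to chi-square.

    ``chi2 = 2 (logL_full - logL_constrained)``, clipped at zero (the
    difference can go marginally negative from optimizer tolerance);
    degrees of freedom are the difference in free parameter counts.
    """
    df = full.n_params - constrained.n_params
    if df <= 0:
        raise ValueError("constrained model must have fewer free parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


@dataclass
class TwinACEResults:
    """Fitted ACE model: estimates, likelihood and derived statistics."""

    model: "TwinACEModel"
    path_model: PathModel
    loglik: float
    n_params: int
    converged: bool
    constraint: Constraint | None = None
    n_restarts_used: int = 0
    optimizer_message: str = ""

    def change_stats(self, target: str = "change") -> ChangeStats:
        """Latent-change (or age-12 cross-trait) correlation and its
        genetic/common/unique-environment decomposition."""
        if self.model.p == 2 and target == "change":
            target = "age12_cross_trait"
        return rph_decomposition(self.path_model, target=target)

    def compare(self, constrained: "TwinACEResults") -> LRTResult:
        return lrt(self, constrained)

    def variance_components(self) -> dict[str, np.ndarray]:
        return self.path_model.variance_components()

    def to_dict(self) -> dict:
        """JSON-serialisable export of the fitted parameters and fit info."""
        pm = self.path_model
        out = {
            "a": pm.a.tolist(),
            "c": pm.c.tolist(),
            "e": pm.e.tolist(),
            "R_g": pm.R_g.tolist(),
            "R_c": pm.R_c.tolist(),
            "R_e": pm.R_e.tolist(),
            "means": pm.means.tolist(),
            "age_slopes": pm.age_slopes.tolist() if pm.age_slopes is not None else None,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "converged": self.converged,
            "constraint": self.constraint.name if self.constraint else None,
        }
        if self.model.p in (2, 4):
            out["change_stats"] = self.change_stats().as_dict()
        return out

    def summary(self) -> str:
        pm = self.path_model
        vc = pm.variance_components()
        lines = [
            "Twin ACE model (FIML)",
            "=" * 64,
            f"families: {self.model.data.n_families}   observed values: {self.model.data.n_observed}",
            f"log-likelihood: {self.loglik:.4f}   free parameters: {self.n_params}",
            f"converged: {self.converged}"
            + (f"   constraint: {self.constraint.name}" if self.constraint else ""),
            "-" * 64,
            f"{'phenotype':<16}{'mean':>9}{'a2':>8}{'c2':>8}{'e2':>8}{'total var':>11}",
        ]
        tot = pm.a**2 + pm.c**2 + pm.e**2
        for i, lab in enumerate(pm.labels):
            lines.append(
                f"{lab:<16}{pm.means[i]:>9.3f}{vc['a2'][i]:>8.3f}{vc['c2'][i]:>8.3f}"
                f"{vc['e2'][i]:>8.3f}{tot[i]:>11.4f}"
            )
        if self.model.p == 4:
            cs = self.change_stats()
            lines += [
                "-" * 64,
                f"change correlation r_ch = {cs.r_ch:.4f} "
                f"(rph-a {cs.rph_a:.4f}, rph-c {cs.rph_c:.4f}, rph-e {cs.rph_e:.4f})",
            ]
        return "\n".join(lines)


FitResult = TwinACEResults


# ---------------------------------------------------------------------------
# model


class TwinACEModel:
    """Correlated-factor ACE model for MZ/DZ twin-pair data.

    Parameters
    ----------
    data
        :class:`FamilyData` (use :meth:`from_cohort` / :meth:`from_table`).
    age_effects
        Add a per-phenotype linear age term to the means model (the age
        covariate used as a sensitivity analysis for between-subject age
        differences at each occasion).
    """

    def __init__(self, data: FamilyData, age_effects: bool = False) -> None:
        self.data = data
        self.p = data.p
        self.age_effects = age_effects
        self.parameterization = _Parameterization(self.p, age_effects)
        self._std_data, self._shift, self._scale = data.standardized()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        hormone_col: str = "hormone",
        gm_col: str | None = "gm",
        gm_values: np.ndarray | None = None,
        occasions: tuple[int, ...] = (1, 2),
        age_effects: bool = False,
    ) -> "TwinACEModel":
        data = FamilyData.from_table(
            table, hormone_col=hormone_col, gm_col=gm_col, gm_values=gm_values, occasions=occasions
        )
        return cls(data, age_effects=age_effects)

    @classmethod
    def from_cohort(
        cls,
        cohort,
        voxel: tuple[int, int, int] | None = None,
        hormone_col: str = "hormone",
        occasions: tuple[int, ...] = (1, 2),
        age_effects: bool = False,
    ) -> "TwinACEModel":
        """Build from a :class:`~pubertwin.simulate.Cohort` whose table has a
        prepared ``hormone`` column; ``voxel`` selects the density series."""
        gm_values = cohort.gm_at_voxel(voxel) if voxel is not None else None
        return cls.from_table(
            cohort.table,
            hormone_col=hormone_col,
            gm_col=None,
            gm_values=gm_values,
            occasions=occasions,
            age_effects=age_effects,
        )

    @classmethod
    def bivariate_age12(cls, cohort, voxel=None, hormone_col="hormone", age_effects=False):
        """Bivariate second-occasion submodel (hormone and density at age 12)."""
        return cls.from_cohort(
            cohort, voxel=voxel, hormone_col=hormone_col, occasions=(2,), age_effects=age_effects
        )

    # -- objective ----------------------------------------------------------

    def _negloglik_and_grad(self, theta: np.ndarray, patterns) -> tuple[float, np.ndarray]:
        par = self.parameterization
        model = par.unpack(theta)
        sig = _pair_cov(model)
        mu = np.tile(model.means, 2)
        slopes = np.tile(model.age_slopes, 2) if par.age_effects else None
        ll, G, h, h_age = _loglik_core(sig, mu, slopes, patterns, want_grad=True)
        if not np.isfinite(ll):
            return 1e12, np.zeros(par.n)
        p = par.p
        # collapse d ll / d Sigma_z into directions for the A, C, E blocks:
        # Sigma_z = I2 (x) (A+C+E) + offdiag2 (x) (rz A + C)
        GwT = np.zeros((p, p))
        Gx = {}
        for z, Gz in G.items():
            GwT += Gz[:p, :p] + Gz[p:, p:]
            Gx[z] = Gz[:p, p:] + Gz[p:, :p]
        GA = GwT + GENETIC_CROSS_TWIN_CORR["MZ"] * Gx["MZ"] + GENETIC_CROSS_TWIN_CORR["DZ"] * Gx["DZ"]
        GC = GwT + Gx["MZ"] + Gx["DZ"]
        GE = GwT

        grad = np.zeros(par.n)
        # path coefficients: d<G, D R D>/dx_i = 2 ((G * R) x)_i
        grad[par.s_a] = 2.0 * ((GA * model.R_g) @ model.a)
        grad[par.s_c] = 2.0 * ((GC * model.R_c) @ model.c)
        grad[par.s_t] = 2.0 * ((GE * model.R_e) @ model.e) * model.e  # chain e = exp(t)
        # correlation angles: analytic derivative of R w.r.t. each angle
        for sl, Gm, x in ((par.s_ug, GA, model.a), (par.s_uc, GC, model.c), (par.s_ue, GE, model.e)):
            H = Gm * np.outer(x, x)  # d<G, D R D> / dR
            _, dRs = corr_with_grads(np.clip(theta[sl], 1e-3, np.pi - 1e-3), p)
            grad[sl] = np.einsum("kij,ij->k", dRs, H)
        # means (and slopes) are linear in the likelihood's mean vector
        grad[par.s_mu] = h[:p] + h[p:]
        if par.s_b:
            grad[par.s_b] = h_age[:p] + h_age[p:]
        return -ll, -grad

    # -- starting values ----------------------------------------------------

    def _moment_start(self, data: FamilyData) -> PathModel:
        p = data.p
        y1, y2 = data.y[:, :p], data.y[:, p:]
        stacked = np.vstack([y1, y2])
        counts = np.isfinite(stacked).sum(axis=0)
        mu = np.where(
            counts > 0, np.nansum(np.nan_to_num(stacked, nan=0.0), axis=0) / np.maximum(counts, 1), 0.0
        )

        def pairwise(X, Y):
            out = np.zeros((p, p))
            for i in range(p):
                for j in range(p):
                    v = np.isfinite(X[:, i]) & np.isfinite(Y[:, j])
                    if v.sum() > 2:
                        out[i, j] = np.mean((X[v, i] - mu[i]) * (Y[v, j] - mu[j]))
                    else:
                        out[i, j] = 0.0 if i != j else 1.0
            return out

        Sw = pairwise(stacked, stacked)
        cross = {}
        for z in ("MZ", "DZ"):
            m = data.zygosity == z
            if m.sum() >= 3:
                Sx = pairwise(y1[m], y2[m])
                cross[z] = 0.5 * (Sx + Sx.T)
        if "MZ" in cross and "DZ" in cross:
            A = 2.0 * (cross["MZ"] - cross["DZ"])
            C = 2.0 * cross["DZ"] - cross["MZ"]
            E = Sw - cross["MZ"]
        else:  # fall back to an even split when a zygosity group is absent
            A = C = Sw / 3.0
            E = Sw / 3.0

        def to_paths(M, floor):
            w, V = np.linalg.eigh(0.5 * (M + M.T))
            M = (V * np.maximum(w, floor)) @ V.T
            d = np.sqrt(np.diag(M))
            R = M / np.outer(d, d)
            np.fill_diagonal(R, 1.0)
            R = np.clip(R, -0.95, 0.95)
            np.fill_diagonal(R, 1.0)
            w2, V2 = np.linalg.eigh(R)
            R = (V2 * np.maximum(w2, 1e-3)) @ V2.T
            dd = np.sqrt(np.diag(R))
            R = R / np.outer(dd, dd)
            return d, R

        a, Rg = to_paths(A, 0.02)
        c, Rc = to_paths(C, 0.02)
        e, Re = to_paths(E, 0.05)
        e = np.maximum(e, 0.15)
        return PathModel(a=a, c=c, e=e, R_g=Rg, R_c=Rc, R_e=Re, means=mu)

    def _neutral_start(self, data: FamilyData) -> PathModel:
        p = data.p
        I = np.eye(p)
        return PathModel(
            a=np.full(p, np.sqrt(0.33)),
            c=np.full(p, np.sqrt(0.2)),
            e=np.full(p, np.sqrt(0.45)),
            R_g=I.copy(),
            R_c=I.copy(),
            R_e=I.copy(),
            means=np.zeros(p),
        )

    # -- optimizers ---------------------------------------------------------

    def _minimize(self, theta0, patterns, maxiter=1500):
        return minimize(
            self._negloglik_and_grad,
            theta0,
            args=(patterns,),
            jac=True,
            method="L-BFGS-B",
            bounds=self.parameterization.bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )

    def _constraint_val_grad(self, constraint: Constraint, theta: np.ndarray):
        """g(theta) and dg/dtheta (analytic in paths, exact through angles).

        theta lives on the standardized scale but g is evaluated on the raw
        data scale (each covariance term weighted by the product of the two
        phenotypes' scale factors) — the terms of the change covariance
        carry different scale factors, so a standardized-scale zero would
        not be a raw-scale zero.
        """
        par = self.parameterization
        p = par.p
        model = par.unpack(theta)
        ij_terms, comps = constraint.terms()
        slices = {
            "a": (model.a, model.R_g, par.s_a, par.s_ug),
            "c": (model.c, model.R_c, par.s_c, par.s_uc),
            "e": (model.e, model.R_e, par.s_t, par.s_ue),
        }
        w = self._scale
        val = 0.0
        grad = np.zeros(par.n)
        for comp in comps:
            x, R, s_x, s_u = slices[comp]
            VR = np.zeros((p, p))
            gx = np.zeros(p)
            for i, j, sgn in ij_terms:
                sw = sgn * w[i] * w[j]
                val += sw * x[i] * R[i, j] * x[j]
                gx[i] += sw * R[i, j] * x[j]
                gx[j] += sw * R[i, j] * x[i]
                VR[i, j] += 0.5 * sw * x[i] * x[j]
                VR[j, i] += 0.5 * sw * x[i] * x[j]
            if comp == "e":
                gx = gx * x  # chain e = exp(t)
            grad[s_x] += gx
            _, dRs = corr_with_grads(np.clip(theta[s_u], 1e-3, np.pi - 1e-3), p)
            grad[s_u] += np.einsum("kij,ij->k", dRs, VR)
        return val, grad

    def _projected_grad_norm(self, theta, patterns, constraint: Constraint | None = None):
        """Max |gradient| after projecting out the constraint direction and
        zeroing coordinates pinned at their bounds (an optimality check that
        does not rely on any one optimizer's success flag)."""
        _, gf = self._negloglik_and_grad(theta, patterns)
        if constraint is not None:
            _, gg = self._constraint_val_grad(constraint, theta)
            denom = float(gg @ gg)
            if denom > 1e-30:
                gf = gf - ((gf @ gg) / denom) * gg
        for k, (lo, hi) in enumerate(self.parameterization.bounds):
            if lo is not None and (theta[k] <= lo + 1e-9 or theta[k] >= hi - 1e-9):
                gf[k] = 0.0
        return float(np.abs(gf).max())

    def _minimize_constrained(
        self, theta0, patterns, constraint: Constraint, g_tol=1e-8, maxiter=150
    ):
        """SLSQP first, augmented-Lagrangian fallback, until |g| <= g_tol."""
        gfun = lambda th: self._constraint_val_grad(constraint, th)[0]
        gjac = lambda th: self._constraint_val_grad(constraint, th)[1]
        res = minimize(
            self._negloglik_and_grad,
            theta0,
            args=(patterns,),
            jac=True,
            method="SLSQP",
            bounds=self.parameterization.bounds,
            constraints=[{"type": "eq", "fun": gfun, "jac": gjac}],
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        theta = res.x
        gv = gfun(theta)
        if not np.isfinite(self._negloglik_and_grad(theta, patterns)[0]):
            theta, gv = theta0.copy(), gfun(theta0)
        if abs(gv) > g_tol:
            lam, rho = 0.0, 1e3
            prev = abs(gv)
            for _ in range(8):
                def fun(th, lam=lam, rho=rho):
                    f, gr = self._negloglik_and_grad(th, patterns)
                    v, gg = self._constraint_val_grad(constraint, th)
                    return f + lam * v + rho * v * v, gr + (lam + 2.0 * rho * v) * gg

                inner = minimize(
                    fun, theta, jac=True, method="L-BFGS-B",
                    bounds=self.parameterization.bounds,
                    options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7},
                )
                theta = inner.x
                gv = gfun(theta)
                if abs(gv) < g_tol:
                    break
                lam += 2.0 * rho * gv
                if abs(gv) > 0.25 * prev:
                    rho *= 10.0
                prev = abs(gv)
        return theta, gv

    # -- fit ----------------------------------------------------------------

    def fit(
        self,
        constraint: str | Constraint | None = None,
        constraint_target: str = "change",
        n_starts: int = 5,
        seed: int | None = 0,
        start_model: PathModel | None = None,
        maxiter: int = 600,
    ) -> TwinACEResults:
        """Maximise the FIML likelihood, optionally under a constraint.

        Parameters
        ----------
        constraint
            ``None`` for the full model, one of the supported names
            (``change_corr_zero``, ``cross_trait_age12_zero``,
            ``rph_a/c/e_zero``) or a :class:`Constraint`.
        n_starts
            Total number of starting points tried (warm start if given,
            then a moment-based start, a neutral start and seeded jitters);
            the best converged likelihood wins, ties broken by
            parameter-vector norm.
        start_model
            Optional warm start (a PathModel on the raw data scale), e.g.
            the fit of a neighbouring analysis unit.
        """
        if isinstance(constraint, str):
            if constraint == "none":
                constraint = None
            else:
                constraint = Constraint.for_name(constraint, self.p, constraint_target)

        par = self.parameterization
        data_std = self._std_data
        patterns = data_std._patterns
        rng = np.random.default_rng(seed)

        starts: list[np.ndarray] = []
        if start_model is not None:
            starts.append(par.pack(self._standardize_model(start_model)))
        starts.append(par.pack(self._moment_start(data_std)))
        starts.append(par.pack(self._neutral_start(data_std)))
        while len(starts) < max(n_starts, 1):
            jit = rng.normal(0.0, 0.25, size=par.n)
            starts.append(par.clip(starts[min(1, len(starts) - 1)] + jit))
        starts = starts[: max(n_starts, 1)]

        best = None
        restarts_used = 0
        n_at_best = 0
        for theta0 in starts:
            restarts_used += 1
            if constraint is None:
                res = self._minimize(theta0, patterns, maxiter=maxiter)
                theta = res.x
                ok = bool(res.success) or self._projected_grad_norm(theta, patterns) < 0.5
                msg = res.message
            else:
                theta, gv = self._minimize_constrained(theta0, patterns, constraint)
                ok = abs(gv) < 1e-7 and self._projected_grad_norm(theta, patterns, constraint) < 0.5
                msg = f"|g| = {abs(gv):.2e}"
            ll = -self._negloglik_and_grad(theta, patterns)[0]
            cand = (ok, ll, -np.linalg.norm(theta), theta, msg)
            if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
                if best is not None and abs(cand[1] - best[1]) < 1e-6:
                    n_at_best += 1
                else:
                    n_at_best = 1
                best = cand
            elif best[0] and abs(cand[1] - best[1]) < 1e-6:
                n_at_best += 1
            # stop early once two starts agree on a converged optimum
            if best[0] and n_at_best >= 2:
                break

        ok, _, _, theta, msg = best
        model_std = par.unpack(theta)
        model_raw = self._destandardize_model(model_std)
        ll_raw = fiml_loglik(model_raw, self.data, age_effects=self.age_effects)
        n_free = par.n - (1 if constraint is not None else 0)
        return TwinACEResults(
            model=self,
            path_model=model_raw,
            loglik=ll_raw,
            n_params=n_free,
            converged=ok,
            constraint=constraint,
            n_restarts_used=restarts_used,
            optimizer_message=str(msg),
        )

    # -- scale transforms ---------------------------------------------------

    def _destandardize_model(self, m: PathModel) -> PathModel:
        s, mu = self._scale, self._shift
        return PathModel(
            a=m.a * s,
            c=m.c * s,
            e=m.e * s,
            R_g=m.R_g,
            R_c=m.R_c,
            R_e=m.R_e,
            means=m.means * s + mu,
            age_slopes=m.age_slopes * s if m.age_slopes is not None else None,
        )

    def _standardize_model(self, m: PathModel) -> PathModel:
        s, mu = self._scale, self._shift
        return PathModel(
            a=m.a / s,
            c=m.c / s,
            e=m.e / s,
            R_g=m.R_g,
            R_c=m.R_c,
            R_e=m.R_e,
            means=(m.means - mu) / s,
            age_slopes=m.age_slopes / s if m.age_slopes is not None else None,
        )

    def loglik(self, model: PathModel) -> float:
        """Raw-scale FIML log-likelihood of an arbitrary path model."""
        return fiml_loglik(model, self.data, age_effects=self.age_effects)
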