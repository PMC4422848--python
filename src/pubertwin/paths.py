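"""Correlated-factor ACE path model for twin pairs.

The model decomposes each phenotype into additive-genetic (A), common- or
shared-environment (C) and unique-environment (E) latent factors.  Factors of
the same kind are allowed to correlate across phenotypes (the genetic,
common- and unique-environmental correlation matrices ``R_g``, ``R_c``,
``R_e``), which is what carries cross-trait and cross-age covariance.

Across the two members of a twin pair, A factors correlate 1.0 in
monozygotic (MZ) and 0.5 in dizygotic (DZ) pairs, C factors correlate 1.0 by
definition, and E factors are independent.

Phenotype index convention for the longitudinal 4-variate model::

    0 = hormone level, first occasion  (age 9)
    1 = grey-matter density, first occasion  (age 9)
    2 = hormone level, second occasion (age 12)
    3 = grey-matter density, second occasion (age 12)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PathModel",
    "GENETIC_CROSS_TWIN_CORR",
    "COMMON_ENV_CROSS_TWIN_CORR",
    "expected_cov",
    "component_covariances",
    "angles_to_corr",
    "corr_with_grads",
    "corr_to_angles",
    "random_path_model",
]

#: Cross-twin correlation of additive-genetic factors by zygosity.
GENETIC_CROSS_TWIN_CORR = {"MZ": 1.0, "DZ": 0.5}
#: Cross-twin correlation of common-environment factors (any zygosity).
COMMON_ENV_CROSS_TWIN_CORR = 1.0

# canonical labels for the 4-variate longitudinal model
PHENOTYPE_LABELS = (
    "hormone_age9",
    "density_age9",
    "hormone_age12",
    "density_age12",
)


def _check_corr(R: np.ndarray, name: str, tol: float = 1e-8) -> None:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {R.shape}")
    if not np.allclose(R, R.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=tol):
        raise ValueError(f"{name} must have a unit diagonal")
    w = np.linalg.eigvalsh(0.5 * (R + R.T))
    if w.min() < -tol:
        raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})")


@dataclass
class PathModel:
    """Paths and factor correlations of a p-phenotype ACE model.

    Parameters
    ----------
    a, c, e
        Path coefficients (factor loadings) of each phenotype on its A, C
        and E factor.  Only squares and products are identified; ``e`` must
        be strictly positive for identifiability.
    R_g, R_c, R_e
        p x p correlation matrices of the A, C and E factors across
        phenotypes (within an individual).
    means
        Phenotype means (intercepts of the means model).
    age_slopes
        Optional per-phenotype linear age effect on the mean; ``None``
        disables the age covariate.
    """

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    R_g: np.ndarray
    R_c: np.ndarray
    R_e: np.ndarray
    means: np.ndarray | None = None
    age_slopes: np.ndarray | None = None
    labels: tuple[str, ...] = field(default=PHENOTYPE_LABELS)

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.e = np.atleast_1d(np.asarray(self.e, dtype=float))
        self.R_g = np.asarray(self.R_g, dtype=float)
        self.R_c = np.asarray(self.R_c, dtype=float)
        self.R_e = np.asarray(self.R_e, dtype=float)
        p = self.a.shape[0]
        if self.means is None:
            self.means = np.zeros(p)
        self.means = np.asarray(self.means, dtype=float)
        if self.age_slopes is not None:
            self.age_slopes = np.asarray(self.age_slopes, dtype=float)
        if len(self.labels) != p:
            self.labels = tuple(f"phenotype_{i}" for i in range(p))

    @property
    def n_phenotypes(self) -> int:
        return self.a.shape[0]

    def validate(self) -> "PathModel":
        """Raise ``ValueError`` if the model is not a valid ACE path model."""
        p = self.n_phenotypes
        for v, name in ((self.c, "c"), (self.e, "e"), (self.means, "means")):
            if v.shape != (p,):
                raise ValueError(f"{name} must have shape ({p},), got {v.shape}")
        if np.any(self.e <= 0):
            raise ValueError("all e paths must be strictly positive")
        for R, name in ((self.R_g, "R_g"), (self.R_c, "R_c"), (self.R_e, "R_e")):
            if R.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
            _check_corr(R, name)
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.c)):
            raise ValueError("non-finite path coefficient")
        return self

    # -- derived quantities -------------------------------------------------

    def component_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the (A, C, E) covariance components, each diag(x) R diag(x)."""
        Da, Dc, De = np.diag(self.a), np.diag(self.c), np.diag(self.e)
        return Da @ self.R_g @ Da, Dc @ self.R_c @ Dc, De @ self.R_e @ De

    def phenotypic_cov(self) -> np.ndarray:
        """Within-individual phenotypic covariance A + C + E."""
        A, C, E = self.component_matrices()
        return A + C + E

    def variance_components(self) -> dict[str, np.ndarray]:
        """Standardised a^2, c^2, e^2 per phenotype (fractions of variance)."""
        tot = self.a**2 + self.c**2 + self.e**2
        return {"a2": self.a**2 / tot, "c2": self.c**2 / tot, "e2": self.e**2 / tot}

    def with_zeroed_cross(self, pairs, components=("g", "c", "e")) -> "PathModel":
        """Copy with the cross-phenotype correlations of the given index pairs
        set to zero in the selected component matrices."""
        mats = {"g": self.R_g.copy(), "c": self.R_c.copy(), "e": self.R_e.copy()}
        for comp in components:
            for i, j in pairs:
                mats[comp][i, j] = mats[comp][j, i] = 0.0
        return replace(self, R_g=mats["g"], R_c=mats["c"], R_e=mats["e"])


def component_covariances(model: PathModel):
    """Alias for :meth:`PathModel.component_matrices` as a free function."""
    return model.component_matrices()


def expected_cov(model: PathModel, zygosity: str) -> np.ndarray:
    """Model-implied 2p x 2p covariance of a twin pair's phenotype vector.

    The vector is ordered (twin 1 phenotypes, twin 2 phenotypes).  The
    within-twin p x p block is ``A + C + E``; the cross-twin block is
    ``r_z * A + C`` with ``r_z`` = 1 (MZ) or 0.5 (DZ).
    """
    model.validate()
    try:
        rz = GENETIC_CROSS_TWIN_CORR[zygosity]
    except KeyError:
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}") from None
    A, C, E = model.component_matrices()
    within = A + C + E
    cross = rz * A + COMMON_ENV_CROSS_TWIN_CORR * C
    return np.block([[within, cross], [cross, within]])


# -- hyperspherical parameterization of correlation matrices -----------------
#
# A correlation matrix is written R = L L' with L lower triangular, rows of
# unit norm, built from angles in (0, pi).  Any angle vector maps to a valid
# (PSD, unit-diagonal) correlation matrix, which lets an optimizer move in an
# unconstrained space after a logistic squash u -> pi/(1+exp(-u)).


def _chol_from_angles(theta: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, p):
        run = 1.0
        for j in range(i):
            L[i, j] = run * np.cos(theta[k])
            run *= np.sin(theta[k])
            k += 1
        L[i, i] = run
    return L


def angles_to_corr(theta: np.ndarray, p: int) -> np.ndarray:
    """Map p(p-1)/2 angles in (0, pi) to a p x p correlation matrix."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (p * (p - 1) // 2,):
        raise ValueError("wrong number of angles")
    L = _chol_from_angles(theta, p)
    return L @ L.T


def corr_with_grads(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and its derivative w.r.t. each angle.

    Returns ``R`` (p x p) and ``dR`` (m x p x p) with m = p(p-1)/2.  The
    k-th angle lives in one row i of the Cholesky factor L, so dR/dtheta_k
    = dL_i l_i' + l_i dL_i' touches only row/column i.
    """
    theta = np.asarray(theta, dtype=float)
    m = p * (p - 1) // 2
    if theta.shape != (m,):
        raise ValueError("wrong number of angles")
    L = _chol_from_angles(theta, p)
    R = L @ L.T
    dR = np.zeros((m, p, p))
    k = 0
    for i in range(1, p):
        row_start = k
        for t in range(i):
            th_t = theta[row_start + t]
            dL = np.zeros(p)
            # entries j < t unaffected; j == t flips cos -> -sin; j > t and
            # the diagonal carry an extra sin factor -> multiply by cot
            sin_t, cos_t = np.sin(th_t), np.cos(th_t)
            prod = 1.0
            for kk in range(t):
                prod *= np.sin(theta[row_start + kk])
            dL[t] = -prod * sin_t
            cot = cos_t / sin_t
            for j in range(t + 1, i + 1):
                dL[j] = L[i, j] * cot
            w = L @ dL
            dR[k, i, :] += w
            dR[k, :, i] += w
            k += 1
    return R, dR


def corr_to_angles(R: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Inverse of :func:`angles_to_corr` (used for starting values)."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    Rj = R + jitter * np.eye(p)
    Rj /= np.sqrt(np.outer(np.diag(Rj), np.diag(Rj)))
    try:
        L = np.linalg.cholesky(Rj)
    except np.linalg.LinAlgError:
        # project onto the PSD cone (eigenvalue clip) and renormalise
        w, V = np.linalg.eigh(0.5 * (Rj + Rj.T))
        Rj = (V * np.maximum(w, 1e-6)) @ V.T
        d = np.sqrt(np.diag(Rj))
        Rj = Rj / np.outer(d, d) + 1e-9 * np.eye(p)
        L = np.linalg.cholesky(Rj)
    theta = np.empty(p * (p - 1) // 2)
    k = 0
    for i in range(1, p):
        run = 1.0
        for j in range(i):
            x = np.clip(L[i, j] / max(run, 1e-300), -1.0, 1.0)
            theta[k] = np.arccos(x)
            run *= np.sin(theta[k])
            k += 1
    return theta


def random_path_model(
    rng: np.random.Generator,
    p: int = 4,
    total_var: tuple[float, float] = (0.5, 2.0),
    min_e2: float = 0.05,
) -> PathModel:
    """Draw a random valid :class:`PathModel` (for tests and calibration).

    Variance fractions a^2, c^2, e^2 are Dirichlet with e^2 bounded away
    from zero; factor correlation matrices are drawn uniformly over angle
    space, which guarantees validity.
    """
    n_ang = p * (p - 1) // 2
    fracs = rng.dirichlet(np.ones(3), size=p)
    fracs[:, 2] = np.maximum(fracs[:, 2], min_e2)
    fracs /= fracs.sum(axis=1, keepdims=True)
    tot = rng.uniform(*total_var, size=p)
    a = np.sqrt(fracs[:, 0] * tot)
    c = np.sqrt(fracs[:, 1] * tot)
    e = np.sqrt(fracs[:, 2] * tot)
    mats = []
    for _ in range(3):
        theta = rng.uniform(0.15 * np.pi, 0.85 * np.pi, size=n_ang)
        mats.append(angles_to_corr(theta, p))
    means = rng.normal(0.0, 1.0, size=p)
    return PathModel(a=a, c=c, e=e, R_g=mats[0], R_c=mats[1], R_e=mats[2], means=means)
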