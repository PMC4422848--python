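"""Latent-change algebra for the longitudinal 4-phenotype ACE model.

All change quantities are functions of fitted paths and factor correlations
(latent change), never per-subject difference scores — subjects observed at
only one occasion still contribute through FIML.

With phenotypes indexed 0 = hormone age 9, 1 = density age 9,
2 = hormone age 12, 3 = density age 12, the variance of latent grey-matter
change is

    V_chGM = Var(1) + Var(3) - 2 Cov(1, 3)

where each covariance expands over the three components,
Cov(i, j) = a_i r_g(i,j) a_j + c_i r_c(i,j) c_j + e_i r_e(i,j) e_j, and the
covariance of the two latent changes is the four-term cross-trait sum

    Cov_ch = Cov(2,3) + Cov(0,1) - Cov(0,3) - Cov(1,2).

The phenotypic change correlation r_ch = Cov_ch / sqrt(V_chGM V_chH)
decomposes exactly into a genetic part (rph-a: only the r_g terms of the
numerator), a common-environment part (rph-c) and a unique-environment part
(rph-e); the three sum to r_ch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paths import PathModel

__all__ = [
    "ChangeStats",
    "cross_trait_covariance",
    "change_variance",
    "change_covariance",
    "rph_decomposition",
]

# (i, j, sign) terms of Cov(chGM, chH) = Cov(X3-X1, X2-X0)
_CHANGE_COV_TERMS = ((2, 3, +1.0), (0, 1, +1.0), (0, 3, -1.0), (1, 2, -1.0))

#: change variances below this are treated as degenerate (correlation undefined)
DEGENERATE_VARIANCE = 1e-10


@dataclass
class ChangeStats:
    """Latent-change summary of a fitted (or true) path model.

    ``rph_a + rph_c + rph_e == r_ch`` by construction; all three (and
    ``r_ch``) are ``nan`` when either change variance is degenerate.
    """

    V_chGM: float
    V_chH: float
    Cov_ch: float
    r_ch: float
    rph_a: float
    rph_c: float
    rph_e: float
    target: str = "change"

    def as_dict(self) -> dict[str, float]:
        return {
            "V_chGM": self.V_chGM,
            "V_chH": self.V_chH,
            "Cov_ch": self.Cov_ch,
            "r_ch": self.r_ch,
            "rph_a": self.rph_a,
            "rph_c": self.rph_c,
            "rph_e": self.rph_e,
        }


def _component_cov(model: PathModel, i: int, j: int) -> tuple[float, float, float]:
    """(A, C, E) parts of the model-implied covariance of phenotypes i, j."""
    ga = model.a[i] * model.R_g[i, j] * model.a[j]
    gc = model.c[i] * model.R_c[i, j] * model.c[j]
    ge = model.e[i] * model.R_e[i, j] * model.e[j]
    return ga, gc, ge


def cross_trait_covariance(model: PathModel, i: int, j: int) -> float:
    """Model-implied covariance of phenotypes ``i`` and ``j`` within a person."""
    return float(sum(_component_cov(model, i, j)))


def change_variance(model: PathModel, phenotype_pair: tuple[int, int] = (1, 3)) -> float:
    """Variance of the latent change ``X_j - X_i`` for a baseline/follow-up pair.

    Defaults to grey-matter density, pair ``(1, 3)``; use ``(0, 2)`` for the
    hormone.  Expands as Var(i) + Var(j) - 2(a_i r_g a_j + c_i r_c c_j +
    e_i r_e e_j).
    """
    i, j = phenotype_pair
    var_i = model.a[i] ** 2 + model.c[i] ** 2 + model.e[i] ** 2
    var_j = model.a[j] ** 2 + model.c[j] ** 2 + model.e[j] ** 2
    return float(var_i + var_j - 2.0 * cross_trait_covariance(model, i, j))


def _change_cov_components(model: PathModel) -> tuple[float, float, float]:
    parts = np.zeros(3)
    for i, j, sgn in _CHANGE_COV_TERMS:
        parts += sgn * np.array(_component_cov(model, i, j))
    return float(parts[0]), float(parts[1]), float(parts[2])


def change_covariance(model: PathModel) -> float:
    """Covariance of latent grey-matter change with latent hormone change."""
    return float(sum(_change_cov_components(model)))


def rph_decomposition(model: PathModel, target: str = "change") -> ChangeStats:
    """Decompose a phenotypic correlation into A/C/E-transmitted parts.

    Parameters
    ----------
    target
        ``"change"`` — correlation between latent hormone change and latent
        density change (4-variate longitudinal model).
        ``"age12_cross_trait"`` — correlation between hormone and density at
        the second occasion (uses phenotypes 2 and 3; also valid for a
        bivariate model where they are phenotypes 0 and 1).

    Returns
    -------
    ChangeStats
        With ``rph_a + rph_c + rph_e = r_ch`` exactly.  For the
        ``age12_cross_trait`` target, ``V_chGM``/``V_chH`` hold the two
        phenotype variances instead of change variances.
    """
    if target == "change":
        if model.n_phenotypes != 4:
            raise ValueError("change decomposition needs the 4-phenotype model")
        v_gm = change_variance(model, (1, 3))
        v_h = change_variance(model, (0, 2))
        cov_a, cov_c, cov_e = _change_cov_components(model)
    elif target == "age12_cross_trait":
        if model.n_phenotypes == 4:
            i, j = 2, 3
        elif model.n_phenotypes == 2:
            i, j = 0, 1
        else:
            raise ValueError("cross-trait decomposition needs 2 or 4 phenotypes")
        v_h = float(model.a[i] ** 2 + model.c[i] ** 2 + model.e[i] ** 2)
        v_gm = float(model.a[j] ** 2 + model.c[j] ** 2 + model.e[j] ** 2)
        cov_a, cov_c, cov_e = _component_cov(model, i, j)
    else:
        raise ValueError(f"unknown target {target!r}")

    cov = cov_a + cov_c + cov_e
    if v_gm < DEGENERATE_VARIANCE or v_h < DEGENERATE_VARIANCE:
        if v_gm < -1e-8 or v_h < -1e-8:
            raise ValueError("negative change variance — invalid model")
        nan = float("nan")
        return ChangeStats(v_gm, v_h, cov, nan, nan, nan, nan, target=target)
    denom = np.sqrt(v_gm * v_h)
    return ChangeStats(
        V_chGM=v_gm,
        V_chH=v_h,
        Cov_ch=cov,
        r_ch=cov / denom,
        rph_a=cov_a / denom,
        rph_c=cov_c / denom,
        rph_e=cov_e / denom,
        target=target,
    )
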