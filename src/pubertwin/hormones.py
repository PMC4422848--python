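"""Raw hormone measurements -> analysis-ready log-scale phenotype.

Urinary hormones (LH, FSH, estradiol) are measured on two consecutive
mornings together with creatinine; dividing by creatinine corrects for
urine dilution.  Salivary testosterone needs no creatinine correction.
Per-day values below the assay detection limit are unusable: the phenotype
is the mean of the usable days, the single usable day's value when only one
day is quantifiable, and missing when neither is.  The resulting phenotype
is strongly left-skewed and is natural-log transformed before modelling;
Mardia's multivariate skewness/kurtosis test checks the normality assumption
after transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DETECTION_LIMITS",
    "URINE_HORMONES",
    "HormoneRecord",
    "MardiaResult",
    "normalize_creatinine",
    "combine_days",
    "log_transform",
    "prepare_hormone_table",
    "qc_report",
    "mardia_test",
]

#: Assay lower limits of detection, raw concentration scale.
DETECTION_LIMITS = {"lh": 0.1, "fsh": 0.11, "estradiol": 150.0, "testosterone": 11.0}

#: Hormones assayed in urine (creatinine-corrected); testosterone is salivary.
URINE_HORMONES = frozenset({"lh", "fsh", "estradiol"})


@dataclass
class HormoneRecord:
    """Two-day raw assay values for one individual-occasion."""

    level_day1: float
    level_day2: float
    creatinine_day1: float | None = None
    creatinine_day2: float | None = None
    below_limit_day1: bool = False
    below_limit_day2: bool = False
    hormone: str = "fsh"


@dataclass
class MardiaResult:
    """Mardia's multivariate skewness and kurtosis statistics.

    ``skewness_stat`` is n*b1p/6, asymptotically chi-square with
    p(p+1)(p+2)/6 degrees of freedom; ``kurtosis_stat`` is the standardised
    b2p, asymptotically standard normal (two-sided p-value).
    """

    b1p: float
    b2p: float
    skewness_stat: float
    kurtosis_stat: float
    df_skewness: int
    p_skewness: float
    p_kurtosis: float
    n: int
    p: int


def normalize_creatinine(record: HormoneRecord) -> tuple[float, float]:
    """Per-day creatinine-corrected levels (U/mmol or pmol/mmol).

    Salivary testosterone passes through unchanged.  Days flagged below the
    detection limit come back as NaN.  Zero/negative creatinine on a day
    with a quantifiable level is an error.
    """
    out = []
    for level, creat, below in (
        (record.level_day1, record.creatinine_day1, record.below_limit_day1),
        (record.level_day2, record.creatinine_day2, record.below_limit_day2),
    ):
        if below or level is None or not np.isfinite(level):
            out.append(np.nan)
            continue
        if record.hormone in URINE_HORMONES:
            if creat is None or not np.isfinite(creat):
                out.append(np.nan)
                continue
            if creat <= 0:
                raise ValueError(f"creatinine must be positive, got {creat}")
            out.append(level / creat)
        else:
            out.append(level)
    return out[0], out[1]


def combine_days(day1: float, day2: float) -> float:
    """Average the two days; one usable day stands alone; none -> NaN."""
    usable = [d for d in (day1, day2) if d is not None and np.isfinite(d)]
    if not usable:
        return np.nan
    return float(np.mean(usable))


def log_transform(x: float) -> float:
    """Natural log; NaN propagates; non-positive finite values are an error."""
    if x is None or (np.isscalar(x) and np.isnan(x)):
        return np.nan
    if x <= 0:
        raise ValueError(f"log transform requires a positive level, got {x}")
    return float(np.log(x))


def prepare_hormone_table(
    table: pd.DataFrame,
    hormone: str = "fsh",
    impute_below_limit: bool = False,
    detection_limit: float | None = None,
    out_column: str = "hormone",
) -> pd.DataFrame:
    """Run normalise -> combine -> log over a cohort table.

    Expects columns ``hormone_day1/2``, ``creatinine_day1/2``,
    ``below_limit_day1/2``.  Adds ``out_column`` with the log-scale
    phenotype (NaN where no day is usable).

    ``impute_below_limit=True`` replaces occasions where *both* days are
    below the limit with ``detection_limit / sqrt(2)`` instead of missing
    (off by default; missing is handled by FIML downstream).
    """
    if detection_limit is None:
        detection_limit = DETECTION_LIMITS.get(hormone)
    out = table.copy()
    values = np.full(len(table), np.nan)
    for k, (_, row) in enumerate(table.iterrows()):
        rec = HormoneRecord(
            level_day1=row.get("hormone_day1", np.nan),
            level_day2=row.get("hormone_day2", np.nan),
            creatinine_day1=row.get("creatinine_day1", np.nan),
            creatinine_day2=row.get("creatinine_day2", np.nan),
            below_limit_day1=bool(row.get("below_limit_day1", False)),
            below_limit_day2=bool(row.get("below_limit_day2", False)),
            hormone=hormone,
        )
        d1, d2 = normalize_creatinine(rec)
        combined = combine_days(d1, d2)
        if np.isnan(combined) and impute_below_limit and (
            rec.below_limit_day1 and rec.below_limit_day2
        ):
            if detection_limit is None:
                raise ValueError("imputation requested but no detection limit known")
            combined = detection_limit / np.sqrt(2.0)
        values[k] = log_transform(combined) if np.isfinite(combined) else np.nan
    out[out_column] = values
    return out


def qc_report(table: pd.DataFrame, by: str | None = "occasion") -> pd.DataFrame:
    """Counts of subjects below the detection limit on 0/1/2 days.

    Mirrors the demographic-table style of reporting; grouped by ``by``
    (set to ``None`` for a single overall row).
    """
    t = table.copy()
    t["_n_below"] = t["below_limit_day1"].astype(int) + t["below_limit_day2"].astype(int)
    groups = t.groupby(by) if by is not None else [("all", t)]
    rows = []
    for key, g in groups:
        counts = g["_n_below"].value_counts()
        rows.append(
            {
                by or "group": key,
                "n": len(g),
                "below_0_days": int(counts.get(0, 0)),
                "below_1_day": int(counts.get(1, 0)),
                "below_2_days": int(counts.get(2, 0)),
            }
        )
    return pd.DataFrame(rows)


def mardia_test(sample: np.ndarray) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis test of normality.

    Parameters
    ----------
    sample
        n x p matrix of complete rows, n > p.

    Notes
    -----
    b1p = mean over all pairs (i, j) of (x_i' S^-1 x_j)^3 and
    b2p = mean of (x_i' S^-1 x_i)^2, with x centred and S the
    maximum-likelihood covariance (divisor n).  n*b1p/6 is referred to a
    chi-square with p(p+1)(p+2)/6 df; b2p is standardised against mean
    p(p+2) and variance 8 p (p+2) / n.
    """
    X = np.asarray(sample, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    if np.isnan(X).any():
        raise ValueError("sample must contain complete rows only")
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / n
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ValueError("rank-deficient sample covariance") from None
    if np.linalg.cond(S) > 1e12:
        raise ValueError("rank-deficient sample covariance")
    # Mahalanobis kernel; blockwise to keep memory bounded for large n
    W = Xc @ Sinv
    b1 = 0.0
    block = 2048
    for start in range(0, n, block):
        M = W[start : start + block] @ Xc.T
        b1 += float(np.sum(M**3))
    b1 /= n * n
    d2 = np.einsum("ij,ij->i", W, Xc)
    b2 = float(np.mean(d2**2))

    df = p * (p + 1) * (p + 2) // 6
    skew_stat = n * b1 / 6.0
    p_skew = float(stats.chi2.sf(skew_stat, df))
    z_kurt = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    p_kurt = float(2.0 * stats.norm.sf(abs(z_kurt)))
    return MardiaResult(
        b1p=b1,
        b2p=b2,
        skewness_stat=float(skew_stat),
        kurtosis_stat=float(z_kurt),
        df_skewness=df,
        p_skewness=p_skew,
        p_kurtosis=p_kurt,
        n=n,
        p=p,
    )
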