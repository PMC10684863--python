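"""Percentile dichotomization and logistic predicted-probability curves.

Each phenotype's frequencies are dichotomized at the 75th percentile of
the empirical distribution of the stratum being fitted ("high" means
strictly above the cutoff), and a logistic regression of the high label
on age in months gives the predicted probability of presenting the
phenotype in high frequency along the age continuum.  Model calibration
is assessed by the Hosmer-Lemeshow decile-of-risk test.

Percentiles use linear interpolation (type-7); this matters because
percentile dialects differ across software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import CohortTable
from .panel import PHENOTYPES

__all__ = [
    "DichotomizedSeries",
    "LogisticFit",
    "dichotomize",
    "fit_logistic",
    "predicted_probability",
    "hosmer_lemeshow",
    "fit_stratum",
    "probability_curves",
]


@dataclass
class DichotomizedSeries:
    phenotype: str
    cutoff: float                 # % units
    labels: np.ndarray            # 1 = strictly above cutoff
    percentile: float = 75.0

    @property
    def proportion_high(self) -> float:
        return float(self.labels.mean())


def dichotomize(values, percentile: float = 75.0,
                phenotype: str = "") -> DichotomizedSeries:
    """Label values strictly above the linear-interpolation empirical
    percentile as high; ties at the cutoff are low (keeps the high class
    at most 100-percentile percent under heavy ties)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to dichotomize")
    if np.all(v == v[0]):
        raise ValueError("constant series cannot be dichotomized")
    cutoff = float(np.percentile(v, percentile))  # numpy default: type-7
    labels = (v > cutoff).astype(int)
    return DichotomizedSeries(phenotype=phenotype, cutoff=cutoff,
                              labels=labels, percentile=percentile)


@dataclass
class LogisticFit:
    stratum: str
    phenotype: str
    beta0: float                 # log-odds at age 0
    beta1: float                 # log-odds per month of age
    beta1_se: float
    p_slope: float               # Wald two-sided
    converged: bool
    n: int
    note: str = ""


def fit_logistic(labels, age_months, stratum: str = "ALL",
                 phenotype: str = "") -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary label on age.

    Newton/IRLS via statsmodels; complete separation yields a
    ``converged=False`` fit flagged with an infinite-slope warning rather
    than an exception.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(age_months, dtype=float)
    if y.shape != x.shape:
        raise ValueError("labels and ages must have equal length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # perfect separation raises in statsmodels
            return LogisticFit(stratum, phenotype, np.nan, np.inf, np.inf,
                               np.nan, converged=False, n=y.size,
                               note=f"complete separation: {exc}")
    converged = bool(res.mle_retvals.get("converged", False))
    note = ""
    if not converged or not np.isfinite(res.bse).all():
        converged = False
        note = "non-converged fit (possible quasi-separation; slope unstable)"
    return LogisticFit(stratum, phenotype,
                       beta0=float(res.params[0]), beta1=float(res.params[1]),
                       beta1_se=float(res.bse[1]),
                       p_slope=float(res.pvalues[1]),
                       converged=converged, n=y.size, note=note)


def predicted_probability(fit: LogisticFit, age_months) -> np.ndarray:
    """Inverse-logit of beta0 + beta1 * age; strictly monotone in age for
    a nonzero slope."""
    if not fit.converged:
        raise ValueError("predicted probabilities require a converged fit")
    age = np.asarray(age_months, dtype=float)
    return expit(fit.beta0 + fit.beta1 * age)


def hosmer_lemeshow(probs, labels, bins: int = 10) -> dict[str, float]:
    """Hosmer-Lemeshow goodness-of-fit on `bins` near-equal groups of
    subjects ranked by fitted probability.

    chi2 sums (observed - expected)^2 / expected over bins for both
    outcomes; df = g - 2.  Bins collapsed by tied probabilities are
    merged with a warning.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size != y.size:
        raise ValueError("probs and labels must have equal length")
    if p.size < bins:
        raise ValueError(f"need at least {bins} subjects for {bins} bins")
    ranks = pd.qcut(pd.Series(p).rank(method="first"), q=bins,
                    labels=False, duplicates="drop")
    g = int(ranks.max()) + 1
    if g < bins:
        warnings.warn(f"tied probabilities collapsed {bins} bins to {g}",
                      stacklevel=2)
    chi2 = 0.0
    for b in range(g):
        sel = ranks.to_numpy() == b
        e1 = p[sel].sum()
        e0 = (1 - p[sel]).sum()
        o1 = y[sel].sum()
        o0 = (1 - y[sel]).sum()
        if e1 <= 0 or e0 <= 0:
            warnings.warn(f"bin {b} has zero expected count; skipped",
                          stacklevel=2)
            continue
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = g - 2
    return {"chi2": float(chi2), "df": float(df),
            "p": float(stats.chi2.sf(chi2, df))}


def fit_stratum(cohort: CohortTable, stratum: str = "ALL",
                percentile: float = 75.0, hl_bins: int = 10) -> pd.DataFrame:
    """Dichotomize and fit every phenotype within one stratum.

    The percentile cutoff is computed within the stratum being fitted
    (its own empirical distribution).  Returns a tidy frame with one row
    per phenotype: cutoff, coefficients, Wald slope p, and
    Hosmer-Lemeshow statistics.
    """
    df = cohort.subset(None, stratum)
    if len(df) < max(4, hl_bins):
        raise ValueError(f"stratum {stratum!r} too small (n={len(df)})")
    rows = []
    ages = df["age_months"].to_numpy()
    for p in PHENOTYPES:
        d = dichotomize(df[p].to_numpy(), percentile, phenotype=p)
        fit = fit_logistic(d.labels, ages, stratum=stratum, phenotype=p)
        if fit.converged:
            hl = hosmer_lemeshow(predicted_probability(fit, ages),
                                 d.labels, bins=hl_bins)
        else:
            hl = {"chi2": np.nan, "df": np.nan, "p": np.nan}
        rows.append({
            "stratum": stratum, "phenotype": p, "cutoff": d.cutoff,
            "prop_high": d.proportion_high,
            "beta0": fit.beta0, "beta1": fit.beta1,
            "beta1_se": fit.beta1_se, "p_slope": fit.p_slope,
            "converged": fit.converged,
            "hl_chi2": hl["chi2"], "hl_df": hl["df"], "hl_p": hl["p"],
            "n": fit.n, "note": fit.note,
        })
    return pd.DataFrame(rows)


def probability_curves(fits: pd.DataFrame, age_grid=None) -> pd.DataFrame:
    """Predicted-probability curves on an age grid (months), one row per
    (stratum, phenotype, age) — suitable for replotting the scatter of
    predicted probabilities along the age continuum."""
    if age_grid is None:
        age_grid = np.arange(9, 228)
    age_grid = np.asarray(age_grid, dtype=float)
    out = []
    for _, row in fits.iterrows():
        if not row["converged"]:
            continue
        prob = expit(row["beta0"] + row["beta1"] * age_grid)
        out.append(pd.DataFrame({
            "stratum": row["stratum"], "phenotype": row["phenotype"],
            "age_months": age_grid, "probability": prob,
        }))
    if not out:
        return pd.DataFrame(columns=["stratum", "phenotype",
                                     "age_months", "probability"])
    return pd.concat(out, ignore_index=True)
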