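"""Adjacent-age-group and sex-matched Mann-Whitney comparisons.

The rhythm of a phenotype across childhood is read off pairwise
two-sided Mann-Whitney tests between each age group and the immediately
earlier one (optionally within one sex), plus male-vs-female tests at
matching age ranges.  Significance is annotated with the conventional
star coding (* / ** / *** / **** at p <= 0.05 / 0.01 / 0.001 / 0.0001).

No multiple-testing correction is applied by default (per-test p-values
are reported, mirroring common practice for these descriptive panels);
Benjamini-Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable
from .panel import PHENOTYPES

__all__ = [
    "MWResult",
    "ComparisonResult",
    "mann_whitney",
    "star_code",
    "adjacent_comparisons",
    "sex_matched_comparisons",
    "comparisons_to_frame",
    "significance_table",
]

#: Above this product of sample sizes the exact null distribution is not
#: enumerated and the tie-corrected normal approximation is used.
EXACT_LIMIT = 400


@dataclass(frozen=True)
class MWResult:
    u: float           # min(U_x, U_y), ties counted half to each side
    p: float           # two-sided
    method: str        # 'exact' or 'normal'
    note: str = ""


def mann_whitney(x, y, mode: str = "auto") -> MWResult:
    """Two-sided Mann-Whitney test.

    ``U`` is reported under the min(U_x, U_y) convention, where U_x counts
    (x_i, y_j) pairs with x_i > y_j plus half the ties.  Mode ``auto`` uses
    the exact null distribution when there are no ties and
    ``n_x * n_y <= 400``, otherwise the tie-corrected normal approximation
    with continuity correction.  ``exact`` falls back to normal when ties
    are present (with a note); ``normal`` always approximates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    note = ""
    if mode == "normal":
        method = "asymptotic"
    elif mode == "exact":
        if has_ties:
            method = "asymptotic"
            note = "ties present; exact mode fell back to normal approximation"
        else:
            method = "exact"
    else:  # auto
        method = "exact" if (not has_ties and x.size * y.size <= EXACT_LIMIT) \
            else "asymptotic"

    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence either way
        return MWResult(u=x.size * y.size / 2.0, p=1.0, method="degenerate",
                        note="all values identical")

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)               # pairs with x > y (+ half ties)
    u2 = x.size * y.size - u1
    return MWResult(u=min(u1, u2), p=float(min(res.pvalue, 1.0)),
                    method="exact" if method == "exact" else "normal",
                    note=note)


def star_code(p: float) -> str:
    """Significance stars: ns, then * / ** / *** / **** at thresholds
    p <= 0.05, 0.01, 0.001, 0.0001 (boundaries inclusive)."""
    if not 0.0 <= p <= 1.0 or np.isnan(p):
        raise ValueError(f"p-value must lie in [0, 1], got {p!r}")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    phenotype: str
    group_a: str
    group_b: str
    stratum: str            # ALL / male / female / male-vs-female
    n_a: int
    n_b: int
    u: float
    p: float
    direction: str          # increase / decrease / none, sign of med_b - med_a
    stars: str
    method: str
    p_adjusted: float | None = None


def _compare(xa, xb, phenotype, ga, gb, stratum) -> ComparisonResult:
    res = mann_whitney(xa, xb)
    med_a, med_b = float(np.median(xa)), float(np.median(xb))
    if med_b > med_a:
        direction = "increase"
    elif med_b < med_a:
        direction = "decrease"
    else:
        direction = "none"
    return ComparisonResult(
        phenotype=phenotype, group_a=ga, group_b=gb, stratum=stratum,
        n_a=len(xa), n_b=len(xb), u=res.u, p=res.p,
        direction=direction, stars=star_code(res.p), method=res.method,
    )


def _maybe_adjust(results: list[ComparisonResult],
                  adjust: bool) -> list[ComparisonResult]:
    if not adjust or not results:
        return results
    padj = multipletests([r.p for r in results], method="fdr_bh")[1]
    return [ComparisonResult(**{**r.__dict__, "p_adjusted": float(q)})
            for r, q in zip(results, padj)]


def adjacent_comparisons(cohort: CohortTable, stratum: str = "ALL",
                         adjust: bool = False) -> list[ComparisonResult]:
    """One Mann-Whitney comparison per phenotype per adjacent group pair,
    each later group tested against the immediately earlier one.

    Groups with fewer than 2 subjects in the stratum are skipped with a
    warning, so a cohort with one empty group yields 4 pairs x 12
    phenotypes instead of 5 x 12.
    """
    pairs = cohort.scheme.adjacent_pairs()
    if not pairs:
        raise ValueError("scheme must have at least two groups")
    results: list[ComparisonResult] = []
    for ga, gb in pairs:
        a = cohort.subset(ga, stratum)
        b = cohort.subset(gb, stratum)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"skipping {ga} vs {gb} (stratum {stratum}): "
                f"n={len(a)}, {len(b)}", stacklevel=2)
            continue
        for p in PHENOTYPES:
            results.append(_compare(a[p].to_numpy(), b[p].to_numpy(),
                                    p, ga, gb, stratum))
    return _maybe_adjust(results, adjust)


def sex_matched_comparisons(cohort: CohortTable,
                            adjust: bool = False) -> list[ComparisonResult]:
    """Male-vs-female Mann-Whitney comparison per phenotype within each
    age group (direction is the sign of the female-minus-male median)."""
    results: list[ComparisonResult] = []
    for g in cohort.scheme.labels:
        m = cohort.subset(g, "male")
        f = cohort.subset(g, "female")
        if len(m) < 2 or len(f) < 2:
            warnings.warn(f"skipping sex comparison at {g}: "
                          f"n male={len(m)}, female={len(f)}", stacklevel=2)
            continue
        for p in PHENOTYPES:
            results.append(_compare(m[p].to_numpy(), f[p].to_numpy(),
                                    p, f"{g}:male", f"{g}:female",
                                    "male-vs-female"))
    return _maybe_adjust(results, adjust)


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy one-row-per-comparison table (CSV-ready)."""
    return pd.DataFrame([r.__dict__ for r in results])


def significance_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Phenotype x group-pair table of star codes, mirroring the figure
    annotations (arrows give the direction of the later group's median)."""
    arrow = {"increase": "^", "decrease": "v", "none": ""}
    rows = {}
    for r in results:
        cell = r.stars if r.stars == "ns" else f"{r.stars}{arrow[r.direction]}"
        rows.setdefault(r.phenotype, {})[f"{r.group_a} -> {r.group_b}"] = cell
    return pd.DataFrame(rows).T.reindex(list(PHENOTYPES))
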