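"""Global-median signatures and equalized heatmap matrices.

A signature converts each phenotype's continuous frequencies into the
proportion (%) of each age group's subjects strictly above that
phenotype's global median (computed over the whole stratum, not per
group).  By construction the subject-weighted mean of each column is
~50%, so cells above 50% mark age groups where the phenotype is
over-represented; those cells carry a highlight flag (the radar-chart
asterisks).

"Equalization" for the heatmap view is per-phenotype min-max rescaling
of the proportions across age groups to [0, 1] (each row of the heatmap
uses its own full color range); a rank-based alternative is available.
The 50th-percentile contour flags cells at or above the column median of
the equalized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .panel import PHENOTYPES

__all__ = [
    "SignatureMatrix",
    "HeatmapMatrix",
    "global_median_cutoffs",
    "signature_proportions",
    "equalize_heatmap",
    "radar_table",
    "orbital_table",
]


@dataclass
class SignatureMatrix:
    values: pd.DataFrame       # groups x phenotypes, % of subjects above cutoff
    cutoffs: pd.Series         # per-phenotype global median (% units)
    group_sizes: pd.Series     # subjects per group in the stratum
    stratum: str

    @property
    def highlight(self) -> pd.DataFrame:
        """Cells strictly above 50% of subjects."""
        return self.values > 50.0


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame       # groups x phenotypes in [0, 1]
    contour: pd.DataFrame      # cells at/above the column median (the
                               # heatmap's 50th-percentile line)
    method: str                # 'minmax' or 'rank'


def global_median_cutoffs(cohort: CohortTable, stratum: str = "ALL") -> pd.Series:
    """Per-phenotype median over all subjects of the stratum (pooled
    across age groups — the 'global' median)."""
    df = cohort.subset(None, stratum)
    if len(df) < 2:
        raise ValueError(f"stratum {stratum!r} needs at least 2 subjects")
    return df[list(PHENOTYPES)].median()


def signature_proportions(cohort: CohortTable, cutoffs: pd.Series | None = None,
                          stratum: str = "ALL") -> SignatureMatrix:
    """Proportion (%) of each age group's subjects strictly above each
    phenotype's global-median cutoff.

    Empty groups yield NaN cells (flagged by the NaN itself).  With the
    default cutoffs, Sum_g n_g * cell[g, p] / 100 equals the total count
    of subjects above the global cutoff.
    """
    if cutoffs is None:
        cutoffs = global_median_cutoffs(cohort, stratum)
    cutoffs = cutoffs.reindex(list(PHENOTYPES))
    if cutoffs.isna().any():
        raise ValueError("cutoffs must cover all 12 phenotypes")
    rows, sizes = {}, {}
    for g in cohort.scheme.labels:
        df = cohort.subset(g, stratum)
        sizes[g] = len(df)
        if len(df) == 0:
            rows[g] = pd.Series(np.nan, index=list(PHENOTYPES))
        else:
            above = df[list(PHENOTYPES)].gt(cutoffs, axis=1)
            rows[g] = 100.0 * above.mean()
    values = pd.DataFrame(rows).T.reindex(list(cohort.scheme.labels))
    return SignatureMatrix(values=values, cutoffs=cutoffs,
                           group_sizes=pd.Series(sizes), stratum=stratum)


def equalize_heatmap(signature: SignatureMatrix,
                     method: str = "minmax") -> HeatmapMatrix:
    """Rescale each phenotype column across age groups to [0, 1].

    ``minmax`` maps the column minimum to 0 and maximum to 1 (constant
    columns map to 0.5); ``rank`` uses the rank of each group within the
    column scaled to [0, 1].  Both preserve within-column order.
    """
    v = signature.values
    if method == "minmax":
        lo, hi = v.min(axis=0), v.max(axis=0)
        rng = hi - lo
        eq = (v - lo).div(rng.replace(0.0, np.nan), axis=1)
        eq.loc[:, (rng == 0.0).to_numpy()] = 0.5
    elif method == "rank":
        denom = (v.notna().sum(axis=0) - 1).replace(0, np.nan)
        eq = (v.rank(axis=0) - 1).div(denom, axis=1)
        eq.loc[:, (v.nunique(axis=0) <= 1).to_numpy()] = 0.5
    else:
        raise ValueError(f"unknown equalization method {method!r}")
    contour = eq.ge(eq.median(axis=0), axis=1)
    return HeatmapMatrix(values=eq, contour=contour, method=method)


def radar_table(signature: SignatureMatrix) -> pd.DataFrame:
    """Tidy radar-chart data: one row per (group, phenotype) with the
    proportion and its above-50% highlight — numerically identical to the
    SignatureMatrix."""
    long = (signature.values.rename_axis(index="age_group",
                                         columns="phenotype")
            .stack().rename("proportion_pct").reset_index())
    long["highlight"] = long["proportion_pct"] > 50.0
    return long


def orbital_table(signature: SignatureMatrix) -> pd.DataFrame:
    """Orbital-chart data: circle size and color both encode the
    proportion of subjects above the cutoff."""
    long = radar_table(signature)
    long["size"] = long["proportion_pct"]
    long["color"] = long["proportion_pct"]
    return long


def plot_heatmap(heat: HeatmapMatrix, ax=None):
    """Basic rendering of an equalized heatmap (requires matplotlib).

    Phenotypes as rows, age groups as columns; dots mark cells on the
    50th-percentile contour.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    v = heat.values.T  # phenotypes x groups
    ax.imshow(v.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(v.shape[1]), v.columns, rotation=45, ha="right")
    ax.set_yticks(range(v.shape[0]), v.index)
    for i, p in enumerate(v.index):
        for j, g in enumerate(v.columns):
            if heat.contour.loc[g, p]:
                ax.plot(j, i, ".", color="white", ms=4)
    ax.set_title("equalized signature rhythm")
    return ax
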