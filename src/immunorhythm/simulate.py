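"""Synthetic pediatric cohort generator.

Generates subject-level phenotype frequency tables with the statistical
structure the downstream analysis assumes: compositional lineages that
sum to 100%, age-group-dependent rhythms on a latent log-ratio scale,
optional sex offsets, and per-group latent correlation structure.

Model: for a subject in age group ``g`` of sex ``s``, draw a 12-dim
Gaussian ``z ~ N(mu[., g] + delta[., g, s], diag(sigma) R[g] diag(sigma))``
and map each lineage's four latent coordinates to frequencies via the
softmax (logistic-normal) transform scaled to 100.  A logistic-normal is
used instead of a Dirichlet because the Dirichlet cannot encode arbitrary
cross-lineage correlations, which the network analysis requires.

The softmax attenuates latent correlations nonlinearly, so targeting a
realized rank correlation is done by Monte-Carlo calibration
(:func:`inject_correlation`), which always reports the attained value.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEFAULT_SCHEME, AgeGroupScheme, CohortTable
from .panel import LINEAGES, PHENOTYPES, lineage_of

__all__ = [
    "RhythmParams",
    "InjectionReport",
    "generate_cohort",
    "inject_correlation",
    "study_params",
    "null_params",
    "nearest_correlation",
    "STUDY_GROUP_SIZES",
]

#: Published per-group subject counts (male, female) used as generator
#: defaults: totals 135/147/129/133/140/128, overall 812 (408 M, 404 F).
STUDY_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "9Mths-1Yr": (62, 73),
    "2Yrs": (67, 80),
    "3-4Yrs": (67, 62),
    "5-7Yrs": (72, 61),
    "8-10Yrs": (71, 69),
    "11-18Yrs": (69, 59),
}

_P = list(PHENOTYPES)


def nearest_correlation(R: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalue clipping followed by unit-diagonal rescaling; adequate for
    the mild indefiniteness produced by entry-wise edits.
    """
    A = (R + R.T) / 2.0
    w, V = np.linalg.eigh(A)
    if w.min() >= eps:
        out = A
    else:
        out = (V * np.clip(w, eps, None)) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


@dataclass
class RhythmParams:
    """All knobs of the generator.

    Attributes
    ----------
    scheme : AgeGroupScheme
        Age binning; ages are drawn uniformly within each group interval.
    mu : pandas.DataFrame
        Latent means, groups x 12 phenotypes (log-ratio scale).
    sigma : pandas.Series
        Latent standard deviations per phenotype (> 0).
    R : dict[str, numpy.ndarray]
        Per-group 12x12 latent correlation matrix (symmetric PSD, unit
        diagonal).
    sex_delta : dict[tuple[str, str], pandas.Series]
        Latent offsets keyed by (group, sex); missing keys mean zero.
    group_sizes : dict[str, tuple[int, int]]
        (n_male, n_female) per group; zero sizes give empty groups.
    seed : int
        Base seed; per-group substreams are derived deterministically.
    """

    scheme: AgeGroupScheme = DEFAULT_SCHEME
    mu: pd.DataFrame = None  # type: ignore[assignment]
    sigma: pd.Series = None  # type: ignore[assignment]
    R: dict[str, np.ndarray] = field(default_factory=dict)
    sex_delta: dict[tuple[str, str], pd.Series] = field(default_factory=dict)
    group_sizes: dict[str, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        labels = list(self.scheme.labels)
        if list(self.mu.index) != labels:
            raise ValueError("mu rows must match scheme labels in order")
        if list(self.mu.columns) != _P or list(self.sigma.index) != _P:
            raise ValueError("mu columns / sigma index must be the 12-phenotype panel")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")
        for g in labels:
            Rg = self.R[g]
            if Rg.shape != (12, 12) or not np.allclose(Rg, Rg.T, atol=1e-10):
                raise ValueError(f"R[{g}] must be symmetric 12x12")
            if not np.allclose(np.diag(Rg), 1.0, atol=1e-10):
                raise ValueError(f"R[{g}] must have unit diagonal")
            if np.linalg.eigvalsh(Rg).min() < -1e-8:
                raise ValueError(f"R[{g}] is not positive semi-definite")
            nm, nf = self.group_sizes.get(g, (0, 0))
            if nm < 0 or nf < 0:
                raise ValueError("group sizes must be non-negative")

    def copy(self) -> "RhythmParams":
        return copy.deepcopy(self)

    def trend_signs(self) -> pd.Series:
        """Injected monotone-trend sign per phenotype: sign of the latent
        mean change from the first to the last age group."""
        diff = self.mu.iloc[-1] - self.mu.iloc[0]
        return np.sign(diff).astype(int)


def _latent_factor(R: np.ndarray) -> np.ndarray:
    """Factor A with A @ A.T == R, robust to semi-definiteness."""
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.clip(w, 0.0, None))


def _softmax_compositions(z: np.ndarray) -> np.ndarray:
    """Map latent (n, 12) to frequencies (n, 12): per-lineage softmax x 100."""
    out = np.empty_like(z)
    for members in LINEAGES.values():
        idx = [_P.index(p) for p in members]
        zl = z[:, idx]
        zl = zl - zl.max(axis=1, keepdims=True)
        e = np.exp(zl)
        out[:, idx] = 100.0 * e / e.sum(axis=1, keepdims=True)
    return out


def generate_cohort(params: RhythmParams, seed: int | None = None) -> CohortTable:
    """Draw a full cohort; identical params + seed give an identical table."""
    params.validate()
    base_seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    streams = ss.spawn(len(params.scheme.labels))

    rows: list[pd.DataFrame] = []
    counter = 0
    for g, child_ss in zip(params.scheme.labels, streams):
        rng = np.random.default_rng(child_ss)
        nm, nf = params.group_sizes.get(g, (0, 0))
        n = nm + nf
        if n == 0:
            continue
        lo, hi = params.scheme.interval(g)
        ages = rng.integers(lo, hi, size=n)
        sexes = np.array(["male"] * nm + ["female"] * nf)

        mean = np.tile(params.mu.loc[g].to_numpy(), (n, 1))
        for s in ("male", "female"):
            d = params.sex_delta.get((g, s))
            if d is not None:
                mean[sexes == s] += d.reindex(_P).fillna(0.0).to_numpy()
        A = _latent_factor(params.R[g])
        eps = rng.standard_normal((n, 12))
        z = mean + (eps @ A.T) * params.sigma.to_numpy()
        freqs = _softmax_compositions(z)

        df = pd.DataFrame(freqs, columns=_P)
        df.insert(0, "age_months", ages)
        df.insert(0, "sex", sexes)
        df.insert(0, "subject_id",
                  [f"S{counter + i:04d}" for i in range(n)])
        counter += n
        rows.append(df)

    if not rows:
        raise ValueError("all group sizes are zero; nothing to generate")
    table = pd.concat(rows, ignore_index=True)
    return CohortTable(table, scheme=params.scheme)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _mu_frame(values: dict[str, list[float]], scheme: AgeGroupScheme) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(scheme.labels))[_P]


# Latent means of the "study" preset, tuned to the qualitative shapes
# the study describes: naive T decline, memory T rise with waves at 2Yrs and
# 8-10Yrs, NCD19 mid-childhood peak, CMCD19 high at both ends, nCMCD19
# unimodal at 2Yrs, eEFCD19 bimodal at 2Yrs and 8-10Yrs.
_STUDY_MU = {
    "NCD4":    [2.20, 2.00, 1.80, 1.60, 1.30, 1.10],
    "eEFCD4":  [-0.80, -0.80, -0.70, -0.50, -0.70, -0.30],
    "CMCD4":   [0.60, 0.90, 1.00, 1.00, 1.30, 1.20],
    "EMCD4":   [-0.50, -0.20, 0.00, 0.20, 0.50, 0.50],
    "NCD8":    [2.20, 2.10, 1.80, 1.70, 1.40, 1.20],
    "eEFCD8":  [-0.50, -0.20, -0.20, -0.20, -0.10, 0.20],
    "CMCD8":   [0.30, 0.60, 0.50, 0.50, 0.90, 0.70],
    "EMCD8":   [-0.30, 0.10, 0.30, 0.30, 0.70, 0.50],
    "NCD19":   [1.55, 1.75, 2.00, 1.95, 1.60, 1.20],
    "eEFCD19": [-0.80, -0.35, -0.60, -0.60, -0.20, -0.45],
    "nCMCD19": [-0.80, -0.30, -0.70, -0.80, -0.90, -1.00],
    "CMCD19":  [0.80, 0.35, 0.15, 0.25, 0.50, 1.15],
}

#: Latent correlations present in every age group (conserved axes).
_COMMON_LATENT = {
    ("NCD4", "NCD8"): 0.75,
    ("CMCD4", "CMCD8"): 0.70,
    ("EMCD4", "EMCD8"): 0.70,
    ("NCD4", "NCD19"): 0.45,
}

#: Extra latent correlations carried only by the adolescent group,
#: producing the connectivity peak at 11-18Yrs.  All lie in the CD8 x CD19
#: cross-block, which carries no conserved axis: closure shadows of the
#: conserved CD4-CD8 / CD4-CD19 axes would otherwise make these pairs
#: correlated in every group and hence not selective.
_ADOLESCENT_LATENT = {
    ("NCD8", "NCD19"): 0.45,
    ("eEFCD8", "eEFCD19"): 0.50,
    ("CMCD8", "CMCD19"): 0.45,
    ("EMCD8", "CMCD19"): 0.45,
    ("eEFCD8", "nCMCD19"): 0.45,
    ("EMCD8", "eEFCD19"): 0.45,
    ("NCD8", "nCMCD19"): 0.40,
    ("CMCD8", "NCD19"): 0.40,
}


def _corr_from_pairs(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    R = np.eye(12)
    for (a, b), r in pairs.items():
        i, j = _P.index(a), _P.index(b)
        R[i, j] = R[j, i] = r
    return nearest_correlation(R)


def study_params(seed: int = 0,
                      scheme: AgeGroupScheme = DEFAULT_SCHEME,
                      group_sizes: dict[str, tuple[int, int]] | None = None,
                      ) -> RhythmParams:
    """The 'study' preset: published group sizes, qualitative age
    rhythms, conserved cross-lineage axes plus adolescent-selective extras,
    and the two reported sex differences (NCD4 at 8-10Yrs, eEFCD8 at
    11-18Yrs)."""
    sizes = dict(STUDY_GROUP_SIZES) if group_sizes is None else dict(group_sizes)
    sigma = pd.Series({p: (0.50 if p.endswith("CD19") else 0.35) for p in _P})[_P]
    R_common = _corr_from_pairs(_COMMON_LATENT)
    R_adult = _corr_from_pairs({**_COMMON_LATENT, **_ADOLESCENT_LATENT})
    R = {g: R_common.copy() for g in scheme.labels}
    R[scheme.labels[-1]] = R_adult
    delta = {
        ("8-10Yrs", "male"): pd.Series({"NCD4": -0.15}),
        ("8-10Yrs", "female"): pd.Series({"NCD4": 0.15}),
        ("11-18Yrs", "male"): pd.Series({"eEFCD8": 0.15}),
        ("11-18Yrs", "female"): pd.Series({"eEFCD8": -0.15}),
    }
    return RhythmParams(scheme=scheme, mu=_mu_frame(_STUDY_MU, scheme),
                        sigma=sigma, R=R, sex_delta=delta,
                        group_sizes=sizes, seed=seed)


def null_params(seed: int = 0,
                scheme: AgeGroupScheme = DEFAULT_SCHEME,
                group_sizes: dict[str, tuple[int, int]] | None = None,
                ) -> RhythmParams:
    """Null preset: no age trends, no sex effects, identity latent
    correlation in every group.  Used for type-I-error calibration."""
    sizes = dict(STUDY_GROUP_SIZES) if group_sizes is None else dict(group_sizes)
    flat = {p: [float(np.mean(_STUDY_MU[p]))] * len(scheme.labels) for p in _P}
    sigma = pd.Series({p: (0.50 if p.endswith("CD19") else 0.35) for p in _P})[_P]
    R = {g: np.eye(12) for g in scheme.labels}
    return RhythmParams(scheme=scheme, mu=_mu_frame(flat, scheme),
                        sigma=sigma, R=R, sex_delta={},
                        group_sizes=sizes, seed=seed)


# ---------------------------------------------------------------------------
# Rank-correlation injection with Monte-Carlo calibration
# ---------------------------------------------------------------------------

@dataclass
class InjectionReport:
    pair: tuple[str, str]
    group: str
    rho_target: float
    latent_rho: float
    attained: float
    psd_shift: float  # |entry after PSD repair - requested latent entry|


def _coupling_pairs(pair: tuple[str, str]) -> list[tuple[str, str]]:
    """Latent entries used to realize a target correlation for ``pair``.

    Within a lineage only the pair's own entry can be used.  Across
    lineages the pair entry alone saturates well below |1| (the softmax
    mixes in noise from the other three components of each lineage), so
    the remaining components are coupled too, matched by panel slot
    order: the blocks then co-move and the pair's realized rank
    correlation can approach the target.
    """
    a, b = pair
    lin_a, lin_b = lineage_of(a), lineage_of(b)
    if lin_a == lin_b:
        return [pair]
    rest_a = [p for p in LINEAGES[lin_a] if p != a]
    rest_b = [p for p in LINEAGES[lin_b] if p != b]
    return [pair] + list(zip(rest_a, rest_b))


def _with_injection(params: RhythmParams, pair: tuple[str, str],
                    group: str, latent_rho: float) -> RhythmParams:
    out = params.copy()
    Rg = out.R[group].copy()
    lin_a, lin_b = lineage_of(pair[0]), lineage_of(pair[1])
    if lin_a != lin_b:
        # the bijection coupling must own the whole cross-block: stale
        # entries between the two lineages would fight it and be smeared
        # by the PSD repair
        for a in LINEAGES[lin_a]:
            for b in LINEAGES[lin_b]:
                i, j = _P.index(a), _P.index(b)
                Rg[i, j] = Rg[j, i] = 0.0
    for a, b in _coupling_pairs(pair):
        i, j = _P.index(a), _P.index(b)
        Rg[i, j] = Rg[j, i] = latent_rho
    out.R[group] = nearest_correlation(Rg)
    return out


def _realized_rank_corr(params: RhythmParams, pair: tuple[str, str],
                        group: str, latent_rho: float,
                        n: int = 4000, cal_seed: int = 1_234_567) -> float:
    """Empirical Spearman rho of the pair after applying the coupling."""
    p = _with_injection(params, pair, group, latent_rho)
    p.group_sizes = {g: ((n // 2, n - n // 2) if g == group else (0, 0))
                     for g in p.scheme.labels}
    cohort = generate_cohort(p, seed=cal_seed)
    x = cohort.data[pair[0]].to_numpy()
    y = cohort.data[pair[1]].to_numpy()
    return float(stats.spearmanr(x, y).statistic)


def inject_correlation(params: RhythmParams, pair: tuple[str, str],
                       group: str, rho_target: float,
                       cal_n: int = 4000,
                       ) -> tuple[RhythmParams, InjectionReport]:
    """Return params whose realized Spearman correlation for ``pair`` in
    ``group`` approximates ``rho_target``.

    The latent entry is chosen by inverting a Monte-Carlo lookup of the
    latent-to-realized map (the softmax attenuates correlations), then the
    matrix is repaired to the nearest valid correlation matrix.  If the
    target is unattainable (e.g. strong positive correlation between two
    components of the same closed lineage) or PSD repair moves the entry
    by more than 0.1, a warning reports the attained value.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [-1, 1]")
    for p in pair:
        if p not in _P:
            raise KeyError(f"unknown phenotype {p!r}")
    if group not in params.scheme.labels:
        raise KeyError(f"unknown group {group!r}")
    i, j = _P.index(pair[0]), _P.index(pair[1])

    if rho_target == 0.0:
        out = params.copy()
        rep = InjectionReport(pair, group, 0.0,
                              float(out.R[group][i, j]),
                              float(out.R[group][i, j]), 0.0)
        return out, rep

    sign = 1.0 if rho_target > 0 else -1.0
    grid = sign * np.array([0.0, 0.2, 0.4, 0.6, 0.8, 0.95, 0.995])
    realized = np.array([
        _realized_rank_corr(params, pair, group, g, n=cal_n) for g in grid
    ])
    order = np.argsort(realized)
    lo, hi = realized.min(), realized.max()
    if not lo - 0.05 <= rho_target <= hi + 0.05:
        nearest_idx = int(np.argmin(np.abs(realized - rho_target)))
        latent = float(grid[nearest_idx])
        warnings.warn(
            f"rho_target={rho_target:+.2f} for {pair} in {group} is outside "
            f"the attainable range [{lo:+.2f}, {hi:+.2f}] "
            f"(compositional closure); using latent {latent:+.2f} with "
            f"attained {realized[nearest_idx]:+.2f}",
            stacklevel=2)
    else:
        latent = float(np.interp(rho_target, realized[order], grid[order]))
        latent = float(np.clip(latent, -0.995, 0.995))

    out = _with_injection(params, pair, group, latent)
    psd_shift = abs(float(out.R[group][i, j]) - latent)
    if psd_shift > 0.1:
        warnings.warn(
            f"PSD repair moved latent correlation for {pair} in {group} by "
            f"{psd_shift:.2f} (to {out.R[group][i, j]:+.2f}); target "
            f"{rho_target:+.2f} may not be attained", stacklevel=2)
    attained = _realized_rank_corr(params, pair, group, latent, n=cal_n)
    return out, InjectionReport(pair, group, rho_target, latent,
                                attained, psd_shift)
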