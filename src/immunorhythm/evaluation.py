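"""Simulation benchmarks of the pipeline under known generating conditions.

These routines measure, by Monte-Carlo over freshly generated cohorts,
the operating characteristics the package is designed around:

- type-I calibration of the comparison stage and the false-positive
  behaviour of the network stage on null cohorts (no trends, identity
  latent correlation) — where compositional closure makes within-lineage
  pairs structurally correlated, the false-positive rate is read on the
  48 cross-lineage (truly null) pairs;
- recovery of a known logistic slope and predicted-probability curve;
- recovery of the qualitative age-rhythm pattern the study preset
  injects (naive-early / memory-late signatures, trend-sign agreement of
  all twelve fitted slopes, the adolescent connectivity peak).

Every routine takes a base seed and derives per-replicate seeds from it,
so results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import networks as net
from .cohort import write_cohort
from .panel import PHENOTYPES
from .probability import fit_logistic, fit_stratum, predicted_probability
from .rhythms import adjacent_comparisons, sex_matched_comparisons
from .signatures import signature_proportions
from .simulate import generate_cohort, null_params, study_params

__all__ = [
    "replicate_seeds",
    "type1_calibration",
    "logistic_recovery",
    "shape_recovery",
    "determinism_check",
]


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2^31) derived from one base seed."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=n)


def type1_calibration(n_replicates: int = 200, base_seed: int = 0,
                      alpha: float = 0.05) -> dict[str, float]:
    """False-positive behaviour on null cohorts at the published group sizes.

    Returns the rejection rate of the adjacent-age comparison stage, the
    per-pair false-positive rate of the network stage on cross-lineage
    (truly null) pairs with its per-66-pairs equivalent count, the mean
    number of structural within-lineage edges, and the mean count of
    significant sex-matched comparisons (of 72).
    """
    params = null_params()
    rej, fpr, within, sexsig = [], [], [], []
    for seed in replicate_seeds(base_seed, n_replicates):
        cohort = generate_cohort(params, seed=int(seed))
        res = adjacent_comparisons(cohort)
        rej.append(np.mean([r.p < alpha for r in res]))
        sexsig.append(sum(r.p < alpha for r in sex_matched_comparisons(cohort)))
        for g in cohort.scheme.labels:
            edges = net.build_group_network(cohort, g, alpha=alpha)
            cross = [e.significant for e in edges if e.cross_lineage]
            within.append(sum(e.significant for e in edges
                              if not e.cross_lineage))
            fpr.append(np.mean(cross))
    fpr_mean = float(np.mean(fpr))
    return {
        "adjacent_rejection_rate": float(np.mean(rej)),
        "cross_lineage_fpr": fpr_mean,
        "null_edges_per_66": fpr_mean * 66.0,
        "within_lineage_structural_edges": float(np.mean(within)),
        "sex_matched_significant_of_72": float(np.mean(sexsig)),
        "n_replicates": n_replicates,
    }


def logistic_recovery(n_seeds: int = 100, n: int = 800,
                      beta0: float = -2.0, beta1: float = 0.02,
                      base_seed: int = 0) -> dict[str, float]:
    """Recover a known logistic age trend from simulated binary labels.

    Ages are drawn uniformly over the cohort span (9-228 months), labels
    from logit(p) = beta0 + beta1 * age.  Reports the mean fitted slope,
    its absolute error, and the maximum pointwise deviation of the
    mean-over-seeds fitted curve from the generating curve.
    """
    grid = np.arange(9, 228, 3, dtype=float)
    true_curve = expit(beta0 + beta1 * grid)
    slopes, curves = [], []
    for seed in replicate_seeds(base_seed, n_seeds):
        rng = np.random.default_rng(int(seed))
        age = rng.uniform(9, 228, n)
        y = (rng.random(n) < expit(beta0 + beta1 * age)).astype(int)
        fit = fit_logistic(y, age)
        slopes.append(fit.beta1)
        curves.append(predicted_probability(fit, grid))
    slope_mean = float(np.mean(slopes))
    mean_curve = np.mean(curves, axis=0)
    return {
        "slope_mean": slope_mean,
        "slope_abs_error": abs(slope_mean - beta1),
        "curve_max_pointwise_error": float(np.max(np.abs(mean_curve
                                                         - true_curve))),
        "n_seeds": n_seeds,
        "n": n,
    }


def shape_recovery(n_seeds: int = 30, base_seed: int = 0) -> dict[str, float]:
    """Rate of seeds reproducing the qualitative pattern suite of the
    study preset at the published group sizes.

    Checks per seed: (1) signature highlights naive phenotypes in the
    first group and memory T phenotypes in the last, not vice versa;
    (2) the sign of all twelve fitted logistic slopes matches the
    preset's injected trend sign; (3) the selective-edge count peaks
    strictly at the adolescent group; (4) NCD4 group medians decline
    monotonically.
    """
    params = study_params()
    trend = params.trend_signs()[list(PHENOTYPES)].to_numpy()
    sig_ok = slope_ok = sel_ok = mono_ok = 0
    for seed in replicate_seeds(base_seed, n_seeds):
        cohort = generate_cohort(params, seed=int(seed))
        labels = cohort.scheme.labels
        first, last = labels[0], labels[-1]

        h = signature_proportions(cohort).highlight
        sig_ok += bool(
            h.loc[first, ["NCD4", "NCD8"]].all()
            and not h.loc[last, ["NCD4", "NCD8"]].any()
            and h.loc[last, ["CMCD4", "CMCD8", "EMCD4", "EMCD8"]].all()
            and not h.loc[first, ["CMCD4", "CMCD8", "EMCD4", "EMCD8"]].any())

        fits = fit_stratum(cohort, "ALL").set_index("phenotype")
        signs = np.sign(fits.loc[list(PHENOTYPES), "beta1"].to_numpy())
        slope_ok += bool((signs == trend).all())

        nets = {g: net.build_group_network(cohort, g) for g in labels}
        counts = net.classify_edges(nets).selective_counts
        sel_ok += counts[last] > max(v for g, v in counts.items() if g != last)

        med = cohort.data.groupby("age_group", observed=False)["NCD4"].median()
        mono_ok += bool((med.diff().dropna() < 0).all())
    return {
        "signature_pattern_rate": sig_ok / n_seeds,
        "slope_sign_match_rate": slope_ok / n_seeds,
        "selective_peak_rate": sel_ok / n_seeds,
        "ncd4_monotone_rate": mono_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def determinism_check(seed: int, tmpdir) -> bool:
    """Same params + seed must yield byte-identical cohort CSVs."""
    from pathlib import Path
    tmpdir = Path(tmpdir)
    params = study_params()
    contents = []
    for name in ("run1.csv", "run2.csv"):
        write_cohort(generate_cohort(params, seed=seed), tmpdir / name)
        contents.append((tmpdir / name).read_bytes())
    return contents[0] == contents[1]
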