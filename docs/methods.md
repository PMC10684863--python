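# Methods

## Data model and age binning

The pipeline's universal input is a subject-level table: subject id,
sex, age in months, and twelve phenotype frequencies (% of gated cells)
— the N/eEF/CM/EM fractions of CD4+ and CD8+ T cells and the
N/eEF/nCM/CM fractions of CD19+ B cells.  Within each lineage the four
fractions are compositional (they sum to 100%); readers tolerate a
±1.0 percentage-point deviation by default (gating round-off), flagging
violations in a validation report rather than failing, with a strict
mode that raises.

Ages are binned into six ordered, half-open month intervals:
[9, 24), [24, 36), [36, 60), [60, 96), [96, 132), [132, 228), labelled
9Mths–1Yr, 2Yrs, 3–4Yrs, 5–7Yrs, 8–10Yrs, 11–18Yrs.  Published group
labels of this kind do not state month boundaries; we take "2Yrs" to
mean age-two children (24–35 months), which forces the first group to
extend to 23 months and the last to end at 227 months.  This is a
documented convention, configurable via `AgeGroupScheme`.

## Synthetic cohort generator

Each subject in age group *g* of sex *s* draws a 12-dimensional latent
Gaussian z ~ N(μ·,g + δ·,g,s, diag(σ) R_g diag(σ)) and each lineage's
four latent coordinates map to frequencies by softmax × 100
(logistic-normal).  A Dirichlet cannot encode arbitrary cross-lineage
correlations, which the network stage requires; the logistic-normal
can, at the cost of a nonlinear latent-to-realized correlation map.
Ages are uniform integers within the group interval; group substreams
derive deterministically from one seed, so identical parameters and
seed give byte-identical output.

The **study preset** encodes, on the latent log-ratio scale, the
qualitative rhythms reported for healthy childhood cohorts: NCD4/NCD8
decline monotonically; CM/EM of both T lineages rise with waves at 2Yrs
and 8–10Yrs; NCD19 peaks in mid-childhood (3–7 years); CMCD19 is high
at both ends (infancy and adolescence); nCMCD19 peaks once at 2Yrs;
eEFCD19 is bimodal at 2Yrs and 8–10Yrs.  Latent standard deviations are
0.35 for T phenotypes and 0.50 for B phenotypes — B-cell frequencies
scatter much more widely between subjects than T-cell frequencies.
Since source studies publish group medians only graphically, the latent
means are tuned to reproduce these *shapes*, not any exact figure
values.  Group sizes default to the published counts
(135/147/129/133/140/128; male/female 62/73, 67/80, 67/62, 72/61,
71/69, 69/59).  Sex offsets are zero except the two reported
matching-age differences (NCD4 at 8–10Yrs, eEFCD8 at 11–18Yrs),
injected as ±0.15 latent offsets.

Latent correlation structure: four conserved cross-lineage axes
(NCD4–NCD8 0.75, CMCD4–CMCD8 0.70, EMCD4–EMCD8 0.70, NCD4–NCD19 0.45)
present in every group, plus eight extra axes carried only by the
adolescent group, all placed in the CD8 × CD19 cross-block.  The
placement matters: compositional closure gives every lineage's
components "shadow" correlations with whatever its dominant component
correlates with, so the conserved CD4–CD8 and CD4–CD19 axes induce
correlations among *other* CD4-involved pairs in every group; selective
axes in those blocks would not be selective.  The CD8 × CD19 block
carries no conserved axis and is latently independent elsewhere, so
axes injected there are significant only where injected.

### Correlation injection

`inject_correlation` targets a *realized* Spearman correlation for one
phenotype pair in one group.  The softmax attenuates latent
correlations nonlinearly — a single latent entry saturates near
realized |ρ| ≈ 0.4–0.55 for cross-lineage pairs because each output
mixes independent noise from its lineage's other three components — so
cross-lineage injection couples the remaining components too, matched
by panel slot order (overwriting that lineage-pair's cross-block), and
calibrates the single coupling scalar by inverting a Monte-Carlo lookup
(7-point latent grid, n = 4000 per point, fixed internal calibration
seed).  The attained value is always reported; targets outside the
attainable range (e.g. ρ → +1 within one closed lineage, capped by
closure) or entries moved > 0.1 by positive-semi-definite repair raise
warnings carrying the attained value.  PSD repair is eigenvalue
clipping followed by unit-diagonal rescaling.

### What the generator does and does not emulate

It reproduces: compositional closure (exact to floating round-off),
realistic between-subject scatter, age-group rhythms, sex offsets, and
arbitrary per-group cross-lineage dependence.  It does not emulate:
absolute cell counts, non-Gaussian latent tails, within-subject
longitudinal correlation, measurement/gating error models, or
covariates (infection history, nutrition, puberty staging).  Passing
tests therefore demonstrate that the *pipeline* recovers known
structure of this class; they cannot validate conclusions about any
real cohort.

## Rhythm statistics

Two-sided Mann–Whitney tests, U reported under the min(U_x, U_y)
convention with ties counted half.  The exact null distribution is used
when there are no ties and n_x·n_y ≤ 400; otherwise the tie-corrected
normal approximation with continuity correction.  Exact mode refuses
ties and falls back to the approximation with a note.  Degenerate input
(all values identical) returns p = 1.  Direction is the sign of the
later group's median minus the earlier one's, matching figures that
plot bars of medians.  No multiple-testing correction is applied by
default — these panels conventionally report per-test p-values — and a
Benjamini–Hochberg flag is provided.  One- vs two-sided is not always
stated in published panels; two-sided is assumed (the common default).
Groups with fewer than two subjects in the stratum are skipped with a
warning.

## Probability model

Percentiles use linear interpolation (type-7) — percentile dialects
differ across software, so this is stated.  "High" is strictly above
the cutoff; ties at the cutoff are low, keeping the high class at most
25% under heavy ties.  Cutoffs are computed within the stratum being
fitted (each data set's own empirical distribution), configurable to
shared cutoffs.  Strata (ALL, male, female) are fitted independently —
no sex × age interaction model, since per-stratum p-values are the
reported quantity.  Logistic fits are Newton/IRLS maximum likelihood
(statsmodels, ≤ 100 iterations); complete separation yields a flagged
non-converged fit rather than an exception.  Hosmer–Lemeshow uses ten
near-equal bins of subjects ranked by fitted probability,
χ² = Σ (O−E)²/E over both outcomes, df = bins − 2; bins collapsed by
tied probabilities are merged with a warning.

## Signatures

The global median is the per-phenotype median over *all* subjects of
the stratum (not per group); cells are the percentage of each group's
subjects strictly above it, so the subject-weighted column mean is ~50%
and Σ_g n_g·cell/100 equals the total count above the cutoff.  Strict
">" matches the probability model's convention.  Sex-stratified
signatures use sex-specific medians, configurable to shared ones.
"Equalized distribution" for the heatmap is not formally defined in the
figure tradition this mirrors; we implement per-phenotype min–max
rescaling across the six groups (each heatmap row uses its full color
range), with constant columns mapping to 0.5, plus a rank-based
alternative behind a flag.  The heatmap's 50th-percentile contour marks
cells at or above the column median.  Both conventions are
interpretations and are flagged as such.

## Networks

Spearman ρ is Pearson on midranks; p by the t-approximation
t = ρ√((n−2)/(1−ρ²)) (matching common software at these group sizes),
with exact permutation enumeration available for n ≤ 10.  All 66 pairs
are tested per group; edges with p < 0.05 are significant.  Strength
bands: strong at |ρ| ≥ 0.67, weak/moderate at 0.1 ≤ |ρ| < 0.67; edges
significant at large n with |ρ| < 0.1 are retained but flagged
"sub_threshold_weak".  "Common" requires significance in *all* groups
with the *same sign* (sign-flipping edges are not plausibly conserved;
a sign-agnostic option exists); "selective" means significant in
exactly one group.  Both are conventions for terms the figure tradition
leaves undefined, and they guarantee common ∩ selective = ∅.  No
multiple-testing correction across the 66 pairs by default (BH flag
available).  Compositional closure makes within-lineage pairs
structurally correlated even under an identity latent correlation —
negatively between the dominant naive component and the minor ones,
positively among minor components squeezed by the same dominant share —
so null false-positive calibration is read on the 48 cross-lineage
pairs (measured rate 0.049 ≈ α over 200 null cohorts; ~3.3 edges per 66
pairs equivalent).

## Verification problem sizes

The acceptance script and test suite use: enumeration oracles at all
n_x, n_y ≤ 8 (Mann–Whitney) and n ≤ 8 (Spearman permutations); 200 null
cohorts of 812 for type-I calibration; 100 simulations of n = 800 for
logistic recovery (true slope 0.02 log-odds/month; the mean-over-seeds
fitted curve is compared pointwise to the generating curve); 30 seeds
for the qualitative shape-recovery suite; 20 seeds for realized
injected correlations.  These sizes give Monte-Carlo standard errors
comfortably below the tolerances being checked while keeping a full run
in the low minutes on one core.

## Known limitations

- The generator's latent means are qualitative reconstructions; no
  claim is made of matching any published cohort's actual medians, and
  published network counts (which depend on request-only raw data) are
  not reproduction targets.
- The Hosmer–Lemeshow test has well-known power and binning
  sensitivities; it is provided because it is the conventional
  companion of this analysis, not as a definitive calibration check.
- Logistic fits model a dichotomized outcome; information is discarded
  relative to modelling the continuous frequencies.
- Network "connectivity" is marginal correlation; it is not partial
  correlation or any causal structure.
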