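# Methods

## Model

The package scores $n$ territorial units on $m$ indicators with the
Adjusted Mazziotta-Pareto Index (AMPI), a partially non-compensatory
composite. Three steps, in fixed order:

1. **Goalpost normalization.** Each indicator column $j$ is mapped by
   $r_{ij} = (x_{ij} - \mathrm{Min}_j)/(\mathrm{Max}_j - \mathrm{Min}_j)\cdot 60 + 70$.
   When the goalposts are the observed column min/max, every $r_{ij}$ lies
   in $[70, 130]$; the transformation is invariant to positive affine
   rescaling of a column together with its goalposts, so heterogeneous
   units of measure are irrelevant.
2. **Polarity.** Indicators whose relationship to the measured phenomenon
   is negative are reversed as $200 - r_{ij}$. The complement is applied to
   the *normalized* value, not to raw values before normalization: the two
   are equivalent only when goalposts are symmetric around the column
   midpoint, and the normalized-value formulation is the one taken as
   definitional here. The complement is an involution and maps
   $[70, 130]$ onto itself.
3. **Aggregation.** Per unit, $\mathrm{AMPI}_i = M_i - S_i^2/M_i$ with
   $M_i, S_i$ the mean and standard deviation of the unit's normalized
   values. The penalty $S_i^2/M_i \ge 0$ vanishes iff the unit's profile is
   perfectly balanced, so $\mathrm{AMPI}_i \le M_i$ always.

Hierarchical indexes (Quality from Effectiveness, Safety,
Responsiveness/Patient-centeredness) aggregate child *scores* directly with
the same mean-minus-penalty formula, without re-normalizing them: child
scores already live on the common [70, 130]-anchored scale, and this is the
variant that reproduces the published Quality column from its printed
sub-index columns (max deviation 0.006 over the internally consistent rows;
re-normalizing demonstrably does not reproduce it, so it is not offered).

## Parameters and defaults

- **sd_convention** (`sample` | `population`, default `sample`): the
  divisor ($n-1$ vs $n$) of $S_i$. The defining formula is silent; the
  choice is empirically pinned by recomposing the published Quality column
  from its three printed sub-index columns: the sample convention matches
  to within half a printed rounding unit, the population convention misses
  by up to 1.39 points. The package keeps `population` selectable because
  part of the composite-indicator literature uses it; the bundled negative
  control (test and acceptance quantity) demonstrates the choice is
  load-bearing.
- **goalpost_policy** (`observed_minmax` | `reference_delta`, default
  `observed_minmax`): observed per-column min/max is the only policy
  computable from a single cross-sectional panel; the reference variant
  ($\mathrm{Min/Max} = \text{cross-unit mean} \mp$ half the observed range)
  supports comparisons across panels sharing a reference and may produce
  values outside [70, 130], which are logged and never clipped.
- **Missing values**: hard error naming (unit, indicator). No imputation —
  the penalty depends on the full profile, so imputation would silently
  change scores. Units must number ≥ 2; an index must have ≥ 2 indicators
  (the cv-based penalty is meaningless for one) unless the explicit
  single-indicator bypass is set, in which case the score is the normalized
  value with zero penalty.

## Rankings and correlations

Units are ranked by descending score, rank 1 = best, tied scores sharing
the average rank; display order breaks residual ties alphabetically so
output is byte-stable. Cross-index association uses Spearman's rho on
average ranks (scipy), with two-tailed p-values from the t-approximation
$t = \rho\sqrt{(n-2)/(1-\rho^2)}$ and flags at 0.05/0.01. An exact
permutation p-value is available behind a flag for $n \le 10$ tie-free
columns (full enumeration of pairings; at $n$ near 10 it takes minutes and
is never on a default path). Constant columns yield undefined rho and are
reported as NA, not an error. Human-readable reports print 3-decimal
coefficients without leading zeros (".764", "−.758**"); CSV twins always
carry full-precision floats.

## Synthetic data generator

Each unit has a scalar latent quality $q_i$; the default profile is an
evenly spaced gradient over $[+1, -1]$ across 21 units, emulating a strong
territorial (North–South) quality gradient at the scale of the Italian
regional system. Indicator $j$ observes
$x_{ij} = \mathrm{offset}_j + \mathrm{scale}_j\, s_j (\lambda_j q_i + \varepsilon_{ij})$
with loading $\lambda_j \in [0,1]$, Gaussian noise
$\varepsilon_{ij} \sim N(0, \sigma_j)$ and $s_j = -1$ for negative-polarity
indicators, so adverse indicators correlate negatively with quality as a
mortality rate does. Defaults: 21 units, 5 indicators per index,
noise sd 0.25 against a latent range of 2 (informative but imperfect
indicators), and a 40% share of negative-polarity columns mirroring the
shipped catalog. Gaussian noise is a simplicity choice: the pipeline
consumes only ranks and bounded normalized values, so the noise family is
not critical and is not configurable.

What the generator does **not** emulate: realistic marginal distributions
of health indicators, cross-indicator correlation beyond the single latent
factor, spatial autocorrelation, or multi-year harmonization. Passing
recovery tests therefore show that the pipeline faithfully recovers a
monotone latent ordering under noise — not that real indicator panels have
this one-factor structure.

The recovery experiment draws `n_reps` panels (seeds `seed..seed+n_reps-1`),
scores each with the default pipeline, and summarizes Kendall tau between
AMPI scores and latent quality plus the penalty distribution. At zero noise
tau is exactly 1; tau is monotone non-increasing in noise (asserted over a
3-point grid at 200 replicates, allowing one inversion within two
Monte-Carlo standard errors); at zero loading tau is statistically zero.
These problem sizes (≤ 600 replicates of a 21 × 5 panel) keep the whole
suite and the acceptance script under a few seconds each.

## Numerical choices

- Internal computation is double precision throughout; 2-decimal rounding
  appears only in human-readable rank tables.
- Goalposts with max ≤ min are rejected up front, naming the indicator.
- Score/penalty identities are asserted at 1e−9; aggregation is checked in
  the tests against an independently written literal transcription of the
  mean-minus-penalty formula.
- Pipeline artifacts embed the package version and a SHA-256 prefix of the
  run configuration; identical config + input gives byte-identical output
  (no hidden randomness anywhere outside the synthetic generator).

## Known limitations

- The published top-level indexes (Accessibility, Cost/expenditure, Health
  status, Lifestyles) cannot be recomputed from raw data here: the raw
  indicator sources are external extracts and the goalposts used for them
  were never reported. Reproduction checks therefore cover the internally
  closed computations the published tables support: the Quality
  recomposition, the cross-index Spearman matrix, and ranking extremes.
- One published row (Piemonte in the Quality table: 98.17, 103.49, 111.83
  against a printed Quality of 104.19) is internally inconsistent — no sd
  convention recomposes it closer than 0.147, while all twenty other
  regions agree within ±0.006. The corresponding reproduction check is
  left failing by design and the row is documented rather than "corrected";
  an effectiveness value of ≈ 98.57 would reconcile it, suggesting a
  printed typo.
- The bundled Accessibility table contains a printed tie (Toscana and
  Emilia-Romagna at 102.84) that the unrounded source data presumably did
  not have, so Accessibility-involving correlation cells are checked
  loosely rather than pinned at 3 decimals.
- Whether published significance stars derive from the t-approximation or
  exact tables is unknowable from the tables alone; at n = 21 the two
  rarely disagree, and flags are reported but not pinned.
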