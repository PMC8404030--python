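# ampindex

Non-compensatory composite indexes of territorial health-system performance,
built on the Adjusted Mazziotta-Pareto Index (AMPI). The package is aimed at
health-policy analysts and quantitative social scientists who need to
benchmark territorial units (the shipped catalog covers the 21 Italian
regions and autonomous provinces) across heterogeneous indicators without
letting a surplus in one dimension silently compensate a deficit in another.

## The method

Given a panel $X = \{x_{ij}\}$ of $n$ units by $m$ indicators, each column
is rescaled between two *goalposts* $(\mathrm{Min}_j, \mathrm{Max}_j)$:

$$r_{ij} = \frac{x_{ij} - \mathrm{Min}_j}{\mathrm{Max}_j - \mathrm{Min}_j}\,60 + 70$$

so that values span a common scale anchored at $[70, 130]$. Indicators with
negative polarity (more is worse — mortality rates, caesarean-section
percentages) are reversed by the complement with respect to 200 of the
normalized value. Each unit is then scored as

$$\mathrm{AMPI}_i = M_i - S_i\,cv_i, \qquad cv_i = S_i / M_i$$

where $M_i$ and $S_i$ are the mean and standard deviation of the unit's
normalized values. The penalty $S_i\,cv_i = S_i^2/M_i$ punishes unbalanced
indicator profiles: of two units with equal mean, the one with the more
dispersed profile scores lower (partial non-compensability).

On top of this core the package provides:

- a declarative **index framework** — the shipped catalog defines
  Accessibility (4 indicators), Quality as the aggregation of three
  sub-indexes (Effectiveness 2, Safety 3, Responsiveness/Patient-centeredness
  3), Cost/expenditure (3), Health status (5) and Lifestyles (10), with
  per-indicator polarity; composite nodes aggregate their children's scores
  directly (no re-normalization);
- **rankings** (rank 1 = best, ties averaged) and the cross-index
  **Spearman correlation matrix** with two-tailed significance flags at
  0.05 (\*) and 0.01 (\*\*);
- a **synthetic panel generator** with a latent unit-quality gradient,
  per-indicator loadings, Gaussian noise and mixed polarities, plus a
  Monte-Carlo rank-recovery experiment (Kendall tau against the latent
  ordering);
- bundled fixtures transcribing the published score tables for the 21
  Italian regions, used by the reproduction checks.

## Worked example

Recompose the published Quality score of Trento from its three sub-index
scores (Effectiveness 94.13, Safety 108.13, Responsiveness 135.07):

```python
>>> import ampindex as ai
>>> res = ai.aggregate_ampi([94.13, 108.13, 135.07])
>>> print(f"mean={res.mean_level:.2f} penalty={res.penalty:.2f} score={res.score:.2f}")
mean=112.44 penalty=3.85 score=108.59
```

The mean of the three sub-indexes is 112.44, but Trento's profile is very
unbalanced (its Responsiveness is 41 points above its Effectiveness), so the
dispersion penalty of 3.85 points pulls the final Quality score down to
108.59 — exactly the published value.

The full published cross-index analysis is one command:

```sh
$ ampindex reproduce-table7
                 accessibility  effectiveness  safety  ...  lifestyles
accessibility            1.000          −.241    .327  ...      .702**
...
quality                   .425           .271  .821**  ...      .727**
cost_expenditure       −.552**          −.149 −.573**  ...     −.751**
health_status            .533*           .187   .488*  ...      .764**
* p < 0.05 (2-tailed)   ** p < 0.01 (2-tailed)

Quality recomposition from sub-index columns: max |deviation| = 0.1470
```

Health status and Lifestyles correlate strongly (rho = .764), Quality and
Cost/expenditure strongly negatively (rho = −.758): regions spending more
public money per capita tend to deliver measurably lower quality. The 0.147
maximum recomposition deviation is a single region (Piemonte) whose printed
row is internally inconsistent; every other region recomposes to within
±0.006 (see `docs/methods.md`).

Other subcommands: `compute` (score a panel CSV against a catalog), `rank`,
`correlate`, `simulate` (synthetic panel + ground-truth JSON). Library use
mirrors the CLI: `read_panel`, `compute_hierarchy`, `rank_units`,
`spearman_matrix`, `generate_panel`, `recovery_experiment`.

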