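# microcog

Gut microbiome / plasma metabolome **balance indices** for neurocognitive
status in small longitudinal HIV cohorts.

## The problem

In people with HIV, gut dysbiosis and circulating microbial metabolites have
repeatedly been associated with neurocognitive impairment. Cohorts in this
space are tiny and heavily unbalanced: a typical sub-study classifies
participants by a composite neuropsychological z-score (NPZ-6, the mean of
six standardized cognitive-domain scores) into a Lower (impaired, NPZ-6 ≤
−0.5) and a Higher group, often with as few as 3 vs 15 participants, and
follows them over three study visits (`bsl`, `post`, `final`).

`microcog` implements the full analysis such a study needs, built for exact
small-sample inference:

* **Descriptive group comparisons** — Pearson chi-square (no continuity
  correction) for categorical variables; exact two-sided Wilcoxon rank-sum
  (Mann–Whitney) by complete enumeration of all C(n₁+n₂, n₁) group
  assignments for continuous ones.
* **Discriminant feature selection** — LDA-effect-size screening of taxa
  (Kruskal–Wallis gate at α = 0.05, bootstrapped one-dimensional LDA,
  log₁₀ score > 2.0); sparse PLS-DA (cardinality keepX = 100 per component)
  followed by a rank-sum filter for metabolites; mean-abundance-gated
  pathway screening; signed PC1-loading extraction of the top discriminant
  metabolites; Ward/Euclidean hierarchical clustering for heatmaps.
* **Balance indices** — the core statistic. For disjoint feature sets N
  (enriched in Lower at baseline) and D (enriched in Higher),

  ```
  index(x) = ln gm(x_N) − ln gm(x_D)
  ```

  with `gm` the geometric mean. A microbial, a metabolome and a combined
  index are frozen at baseline and applied unchanged at later timepoints.
  The statistic is exactly invariant to per-sample rescaling and strictly
  monotone in each member feature.
* **Associations** — per-timepoint exact rank-sum comparisons of the
  indices, Spearman correlations with cognitive/functional outcomes with
  Benjamini–Hochberg adjustment per family, |ρ|-cutoff correlation
  networks, Bray–Curtis PERMANOVA, and hypergeometric over-representation
  of metabolite sets against a user-supplied GMT library.
* **A synthetic cohort generator** with planted ground truth (compositional
  species profiles, a 1300-metabolite panel with a 64-metabolite planted
  discriminant subset, six domain z-scores and five functional scales driven
  by one latent cognition factor, group effects attenuating over the three
  visits), so the whole pipeline is testable end to end without any data
  download.

Selection components are scikit-learn estimators (`LefseSelector`,
`SparsePLSDA`, `Pc1Selector`, `BalanceIndex`) and compose with sklearn
model selection; the statistical tests are plain functions.

## Worked example

```python
import microcog as mc

cohort = mc.simulate_cohort(mc.SimulationConfig(seed=1))
bsl = cohort.metadata.samples_at("bsl")
groups = bsl["npz6_group"].to_numpy()          # 3 Lower, 15 Higher

# learn the microbial index at baseline
definition = mc.build_microbial_index(cohort.species["bsl"], groups)
print(len(definition.numerator), len(definition.denominator))
# -> 5 11   (the 3 planted species on each side are recovered, plus a few
#            chance-significant species at alpha = 0.05)

# group separation at each visit with the frozen definition
for tp in ("bsl", "post", "final"):
    vals = mc.index_values(cohort.species[tp], definition)
    lower = groups == "Lower"
    u, p = mc.exact_rank_sum(vals[lower], vals[~lower])
    print(tp, round(p, 4))
# -> bsl 0.0025      (2/816: complete separation, the smallest level the
#                     exact test can reach at n = 3 vs 15)
# -> post 0.0025
# -> final 0.076     (the planted group effect is attenuated to 10% by the
#                     final visit, so the groups have largely converged)
```

The same flow is available from the shell:

```bash
microcog simulate --out fixture --seed 1
microcog run-all --config config.yaml      # all stages, results as TSV/JSON
```

`run-all` writes discriminant feature tables, the three index definitions
and per-sample values, longitudinal comparisons, BH-adjusted index–outcome
correlations, the correlation edge list, and the PERMANOVA summary to the
configured output directory, logging every threshold used.

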