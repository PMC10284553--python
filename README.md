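# ecoweave

**Research weaving for the ecological-complexity literature** — a tested,
reusable pipeline that quantifies how scientific articles use the features
typical of complex systems, and compares an "ecological complexity" article
group against a control group drawn from the wider ecological literature.

The package is aimed at researchers doing science-of-science / bibliometric
analyses of ecology: it combines lexicon-based full-text mining with
community-ecology statistics, network models and co-citation clustering, and
ships a synthetic corpus generator (with ground truth) so every stage can be
validated end to end without access to a proprietary article database.

## What it computes

Articles are screened for 23 named features of complex ecological systems
(self-organization, feedbacks, nonlinearity, hierarchy, …), each detected
through word-stem search strings that capture plurals and British/American
variants (`self-orga` matches *self-organisation*, *self-organizing*, …).
Counts are normalized to within-article relative frequencies
`rf(i, f) = count(i, f) / total words in article i`, and the analysis treats
features as "species" and articles as "sites":

- **Diversity** — per-article feature richness and the first-order Hill
  number `exp(−Σ_f p_f ln p_f)` (effective number of features), compared
  between groups by one-way ANOVA.
- **Uniqueness (PERMDISP)** — Bray-Curtis dissimilarities of relative
  frequencies are embedded by principal coordinates (keeping real and
  imaginary axes); each article's distance to its group's *spatial median*
  (geometric median), corrected as `d² = d²_real − d²_imag`, measures how
  unusual the article is within its group; group dispersions are compared
  by ANOVA.
- **Indicator features (IndVal)** — per feature, specificity × fidelity
  `max_g A_g·B_g` with a seeded group-label permutation test, in abundance
  or presence mode.
- **Topic-model post-processing** — LDA (batch variational EM); per topic,
  only words with per-topic probability β strictly above the upper limit of
  the 0.99 empirical highest-density interval are kept, and per-document
  feature probabilities `Σ_k γ_dk Σ_{w∈f} β_kw` are compared between groups.
- **Feature networks** — the bipartite article-feature network (edges
  weighted by relative usage) is projected to one mode; node strength,
  realized connectance `RC = L/[S(S−1)/2]` and the degree distribution are
  reported. Group structure is modeled with an exponential random graph
  model `Pr(Y=y) ∝ exp(θ′g(y))` with `edges`, `nodematch(group)` and
  `nodefactor(group)` terms; all three are dyadic-independent, so the MLE is
  solved exactly by Newton–Raphson on the equivalent Bernoulli dyad
  likelihood, with Fisher-information standard errors
  (`ErgmModel(...).fit()` returns an `ErgmResults` with `params`, `bse`,
  `zvalues`, `pvalues` and a `summary()` table).
- **Co-citation clustering** — references co-cited in article reference
  lists form a weighted network; the top-100 most co-cited references (by
  co-citation strength) are clustered with Louvain modularity maximization,
  with a robustness sweep over the subnetwork size scored by adjusted Rand
  index.
- **Metric catalogue** — standalone functions for Shannon entropy, mean
  information gain, fluctuation complexity, SVD entropy, mutual information
  and the coefficient of variation.

## Worked example

Generate a synthetic corpus at study scale (172 "complexity" + 180
"control" articles, calibrated so expected feature richness is ≈9 vs ≈6)
and run two stages:

```sh
$ ecoweave simulate --out demo --seed 2
wrote 352 articles to demo: {'complexity': 172, 'control': 180}

$ ecoweave diversity --metadata demo/metadata.tsv --out demo/div.tsv
richness ANOVA: F_1,350 = 181.52, p = 1.28e-33
PERMDISP: F_1,350 = 83.94, p = 4.39e-18; complexity: 0.470; control: 0.545

$ ecoweave ergm --metadata demo/metadata.tsv --out demo/ergm.tsv
Exponential random graph model (dyadic-independent MLE)
nodes: 352  dyads: 61776  edges: 59387
status: converged

term                              g(y)      coef   std err        z    P>|z|
edges                          59387.0    2.0396    0.0669    30.49   0.0000
nodematch.group                29369.0    0.3377    0.0669     5.05   0.0000
nodefactor.group.complexity    59272.0    1.4219    0.0581    24.45   0.0000
```

Reading the output: complexity articles mention significantly more features
(the richness ANOVA), are more similar to one another (smaller mean
distance to their group median, 0.470 vs 0.545), and are more likely to
form ties in the shared-feature article network (positive `nodefactor`
coefficient), while homophily (`nodematch`) is comparatively weak — the
qualitative pattern the pipeline is designed to detect.

`ecoweave run-all --seed 2 --out demo_run` executes every stage and writes
all intermediate tables plus a deterministic `report.json`. The library
surface mirrors the CLI: see `ecoweave.features`, `ecoweave.diversity`,
`ecoweave.topics`, `ecoweave.feature_network`, `ecoweave.cocitation`,
`ecoweave.metrics`, `ecoweave.synthetic`, `ecoweave.pipeline`.

Real corpora are consumed as plain text plus a TSV metadata table
(`article_id  group  year  text_file  references`, references
pipe-separated); see `docs/methods.md` for formats and modeling details.

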