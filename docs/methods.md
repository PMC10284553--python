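# Methods

This note documents the models and procedures implemented in `ecoweave`,
the assumptions behind them, the defaults that matter, and what the
synthetic corpus does and does not emulate.

## Lexicon matching

The built-in lexicon holds 23 features of complex ecological systems, each
with one or more *search stems*. Stems are lowercase word prefixes; a
two-part stem matches a pair of adjacent tokens. Matching rules:

- Tokens come from a tokenizer that lowercases, strips punctuation, keeps
  internal hyphens and retains numerals. It is idempotent on its own
  output.
- Unigram matching is hyphen-stripped on both sides, so the three dialect
  variants of a stem collapse onto two matchers: a joined unigram
  (`non-linear`, `nonlinear` → prefix `nonlinear`) and a spaced bigram
  (`non linear`). This reproduces British/American and
  hyphenated/spaced/joined spellings without triple counting.
- Within one feature a token position is counted at most once: at each
  position, two-part stems are tried before one-part stems, scanning left
  to right (first match wins, the bigram consumes both tokens). Whether a
  bigram match should also increment a unigram tally is not determined by
  the counting convention itself; first-match-wins was chosen because
  summing overlapping matchers would inflate frequencies.
- Prefix matching over-matches by construction ("musical scale" counts
  toward *scaling*). This is the price of stem-based retrieval and is
  documented rather than patched; exact-word matching would instead miss
  plurals and derived forms.

Relative frequencies divide counts by the article's **counting-tokenizer**
token total (not the topic-preprocessed total). Articles containing none
of the 23 features are excluded before any statistics, with a per-group
tally logged.

## Diversity, uniqueness and indicators

Richness is the number of distinct features in an article; the effective
feature number is the first-order Hill number `exp(H)` with `H` the
Shannon entropy of the article's feature-mention *proportions* (the row is
normalized before the entropy; an unnormalized variant would mix article
length into the diversity measure). `hill1 = richness` exactly when the
nonzero proportions are uniform, and `hill1 ≤ richness` always. Group
comparisons use one-way ANOVA.

Uniqueness uses the multivariate homogeneity-of-dispersions procedure
(PERMDISP) on Bray-Curtis dissimilarities `d(x,y) = Σ|x−y|/Σ(x+y)`.
Because Bray-Curtis is semi-metric, the principal-coordinates embedding
has negative eigenvalues; the implementation keeps both the real axes
(positive eigenvalues, scaled √λ) and the imaginary axes (negative
eigenvalues, scaled √−λ). Each group's spatial median is the geometric
median — computed by Weiszfeld iteration with the Vardi–Zhang adjustment
when an iterate lands on a data point, convergence 1e-14 — evaluated
separately in the real and imaginary subspaces, and member distances
combine the parts as `d_i² = d²_real − d²_imag`, floored at zero. On
Euclidean-embeddable input this reduces exactly to distances-to-median in
the original space (tested against a brute-force oracle at 1e-8).
Significance is by the ANOVA F on the distances, as the procedure's
standard form; a permutation F is not needed for the package's use and is
not implemented.

The indicator analysis uses the original IndVal statistic without
group-size equalization or square-root transform: specificity
`A_g = mean abundance in g / Σ_h mean abundance in h`, fidelity
`B_g = occurrence fraction in g`, statistic `max_g A_g·B_g ∈ [0,1]`. In
presence mode the occurrence indicator replaces abundance, covering the
"where does the feature occur" variant of the question. p-values come from
seeded permutations of group labels with the add-one convention
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)` (default 999 permutations); the
pipeline also reports Holm-adjusted p-values across the 23 features
alongside the raw ones. Note the statistic is label-symmetric, so the
smallest attainable p can exceed `1/(n_perm+1)` when a permutation
reproduces the complement of the true labeling. Features absent from every
article have no defined statistic and are flagged, not silently zeroed.

## Topic modeling

LDA is fitted with batch variational EM (scikit-learn backend) on
separately preprocessed text: stopwords removed (a fixed English list
shipped with the package — results of this stage depend on the list, which
is why it is versioned and configurable), hyphenated words joined, plurals
singularized by rule (`-ies→-y`, `-es→-e/-∅`, `-s→-∅`, with an
invariant-plural exception table). The topic count defaults to 100 for
real corpora; synthetic tests use small K, and β/γ rows are normalized to
sum to 1.

Top-word selection implements the highest-density-interval rule on the
discrete β values of each topic: the HDI is the shortest contiguous window
of the sorted values containing `ceil(0.99·V)` points (ties to the first
window), and only words strictly above its upper limit are selected — for
LDA's near-zero-mass bulk this isolates roughly the 0.5% most
characteristic words. A plain quantile selector (`top_frac`) and a pooled
(all-topics) threshold are exposed as alternatives, since "per topic vs
pooled" is a genuinely open choice; per-topic is the default. Selected
words get within-topic quartile labels Q1–Q4.

Feature-group comparison maps lexicon features into the vocabulary with
the same prefix rules as counting (on hyphen-joined forms; spaced bigram
surface forms are invisible to a bag-of-words vocabulary and are covered
by the joined variant). Topics are attributed to the group with the larger
γ-weighted share, and per-document feature probabilities
`Σ_k γ_dk Σ_{w∈f} β_kw` are averaged within groups.

## Feature networks and the ERGM

The bipartite article-feature network has one edge per nonzero
relative-frequency entry. Projections link two nodes of one mode iff they
share a neighbor, weighted either by the shared-neighbor count or by
`Σ_k min(w_uk, w_vk)` (`min_sum`), and report node strength, realized
connectance `RC = L/[S(S−1)/2]` and the degree distribution
`P(k) = N(k)/S`.

The ERGM is fitted on the **binarized article-article network**: two
articles are tied iff they share at least τ features (τ = 1 by default and
configurable, since any binarization threshold is an analysis choice, not
a property of the data). The model
`Pr(Y=y) = exp(θ′g(y))/k(θ)` uses `edges`, `nodematch(group)` and
`nodefactor(group)` statistics; the nodefactor covariate is the number of
dyad endpoints in the focal group (complexity), one non-reference level.
Because every term is dyadic-independent the likelihood factorizes over
dyads into independent Bernoulli terms with covariates (1, same-group,
focal-endpoint count); Newton–Raphson with the Fisher information gives
the exact MLE and standard errors — no MCMC is involved, and
dyadic-dependent terms (triangles, gwesp) are out of scope. Empty or
complete networks and perfect separation push the MLE to infinity; these
are reported via a non-convergence flag with a diagnostic, not an
exception. The solver is cross-checked in tests against an exhaustive
likelihood grid and an independent GLM fit.

## Co-citation clustering

Each article's reference list contributes +1 to every unordered pair of
its distinct citation keys (duplicates within one list count once). Keys
are normalized (case-fold, strip punctuation/whitespace) so the pipeline
is deterministic without bibliographic disambiguation. "Most co-cited"
ranks by total co-citation strength (weighted degree) — a flag switches to
raw citation counts — with lexicographic tie-breaking so the top-100
subnetwork is reproducible. Louvain modularity maximization (networkx,
seeded) supplies the partition and its weighted modularity
`Q = Σ_c (e_c/m − (d_c/2m)²)`; on small fixtures the returned Q is tested
against exhaustive enumeration over all partitions. The robustness sweep
reruns selection + clustering across subnetwork sizes and reports the
adjusted Rand index between consecutive partitions on their shared nodes.

## Metric catalogue

All metrics default to natural logarithms (base 2 available where it makes
sense). Block statistics (mean information gain) use overlapping *cyclic*
windows with plug-in frequencies and no bias correction: the cyclic
convention makes every block length see the same number of windows, so
strictly periodic sequences give exactly zero gain instead of a boundary
artifact. Fluctuation complexity is implemented in its standard
squared-log-ratio form `Σ_ij P_ij (ln(P_i/P_j))²` (the formula circulates
in typographically corrupted variants; the closed-form value
`2·0.8·0.2·(ln4)²` for independent pairs with state probabilities
(0.8, 0.2) pins down the intended definition). SVD entropy normalizes by
`ln k` over the k **nonzero singular values** with `J = 0` for rank-1
matrices, and is invariant under orthogonal rotations.

## Synthetic corpus

The generator emulates exactly the structure the analysis assumes:

- two groups (172 complexity, 180 control) with per-feature inclusion
  probabilities; the defaults decline linearly from 0.75 to 0.04 over the
  23 features for the complexity group (expected richness 9.1), and the
  control probabilities are the same profile scaled to expected richness
  6.0 — except five features (attractor, flow, memory, nonequilibrium,
  threshold) shared equally by both groups, because not every feature
  should discriminate;
- mention counts `1 + Poisson(λ−1)` per included feature, λ = 3 vs 2;
- log-normal article lengths (μ = 7.8, σ = 0.35 in log-tokens, mean ≈
  2,600 tokens — the scale of a full-text research article);
- feature mentions injected as surface forms the matcher must recognize
  (80% joined, 10% hyphenated, 10% spaced), so the ground-truth counts
  equal the matcher's output exactly (a tested round trip);
- Zipf-distributed filler vocabulary disjoint from all feature stems;
- reference lists drawn from a 150-key pool with three planted clusters
  (within/between sampling weights 12:1, 20 references per article).

What it does **not** emulate: real scientific prose (filler tokens carry
no syntax or semantics, so the topic stage sees planted lexical structure
only), citation metadata, OCR/PDF artifacts, section structure, or
correlated feature usage beyond what inclusion probabilities induce.
Passing tests therefore demonstrate that the statistical machinery
recovers known structure of the kinds listed above — not that the lexicon
itself is a valid instrument for real articles.

## Determinism and problem sizes

A single pipeline seed fans out to the stochastic stages by fixed offsets
(indval +1, topics +2, Louvain +3), so stages rerun standalone reproduce
the pipeline's results, and two runs with the same seed emit byte-identical
reports. The test suite and the acceptance script run the full pipeline at
the 172 + 180 study scale; the topic stage there uses K = 20 and the test
fixtures use smaller corpora and K, chosen as the smallest sizes at which
each property under test is informative.

## Known limitations

- The lexicon's prefix convention produces documented false positives
  ("musical scale") and cannot detect negated or quoted mentions.
- The "total number of words" denominator is the post-punctuation token
  count; other tokenizations shift relative frequencies by a constant
  factor per article.
- The HDI top-word rule on near-uniform topics selects nothing (by the
  strict-inequality tie rule); this is intended but means degenerate
  topics contribute no top words.
- The ERGM covers dyadic-independent terms only; adding structural terms
  would require MCMC-MLE and is deliberately out of scope.
- Louvain is a greedy heuristic; optimality is only guaranteed (and
  tested) on small fixtures, and partitions can vary with the seed on
  weakly structured networks.
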