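"""Topic modeling and lexicon-aware post-processing.

Latent Dirichlet allocation treats each document as a mixture of topics and
each topic as a distribution over words.  The model is fitted by batch
variational EM; the post-processing implements two analyses on the fitted
parameters:

* *top-word selection*: per topic, only words whose per-topic probability
  (beta) lies strictly above the upper limit of the 0.99 empirical highest
  density interval of that topic's beta values are retained (LDA puts
  near-zero mass on most of the vocabulary, so this isolates the ~0.5%
  most characteristic words); selected words get within-topic quartile
  ranks Q1..Q4;
* *feature-topic comparison*: lexicon features are mapped into the
  vocabulary with the same prefix rules as the counting stage, then
  summarized per article group by (a) the number of group-attributed
  topics whose top words contain a feature word and (b) the mean
  per-document feature probability ``sum_k gamma_dk * sum_{w in f} beta_kw``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from sklearn.decomposition import LatentDirichletAllocation

from .lexicon import FeatureLexicon

__all__ = [
    "TopicModel",
    "TopWordSelection",
    "fit_topics",
    "select_top_words",
    "compare_feature_topics",
    "feature_vocabulary_map",
]


@dataclass(frozen=True)
class TopicModel:
    """Fitted LDA: per-topic word probabilities and document mixtures."""

    K: int
    beta: np.ndarray  # (K, V), rows sum to 1
    gamma: np.ndarray  # (D, K), rows sum to 1
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.beta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("beta rows must sum to 1")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("gamma rows must sum to 1")


@dataclass(frozen=True)
class TopWordSelection:
    """Per-topic selected word sets with thresholds and quartile labels."""

    words: tuple[tuple[str, ...], ...]  # per topic, beta-descending
    thresholds: tuple[float, ...]
    quartiles: tuple[dict, ...]  # per topic: word -> "Q1".."Q4"
    hdi_mass: float


def _doc_term_matrix(docs: list[list[str]]) -> tuple[csr_matrix, tuple[str, ...]]:
    vocab: dict[str, int] = {}
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for doc in docs:
        counts: dict[int, int] = {}
        for tok in doc:
            j = vocab.setdefault(tok, len(vocab))
            counts[j] = counts.get(j, 0) + 1
        indices.extend(counts.keys())
        data.extend(counts.values())
        indptr.append(len(indices))
    if not vocab:
        raise ValueError("empty vocabulary: no tokens in any document")
    X = csr_matrix(
        (data, indices, indptr), shape=(len(docs), len(vocab)), dtype=np.float64
    )
    words = sorted(vocab)
    X = X[:, [vocab[w] for w in words]]
    return X, tuple(words)


def fit_topics(
    docs: list[list[str]],
    K: int,
    seed: int = 0,
    max_iter: int = 30,
    doc_topic_prior: float | None = None,
    topic_word_prior: float | None = None,
) -> TopicModel:
    """Fit LDA with batch variational EM; deterministic given ``seed``.

    ``docs`` are preprocessed token sequences (see
    :func:`ecoweave.corpus.preprocess_for_topics`).  Priors default to the
    usual 1/K symmetric Dirichlet parameters.
    """
    if len(docs) < 2:
        raise ValueError("need at least 2 documents")
    if K < 1:
        raise ValueError("K must be >= 1")
    X, words = _doc_term_matrix(docs)
    lda = LatentDirichletAllocation(
        n_components=K,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
        doc_topic_prior=doc_topic_prior,
        topic_word_prior=topic_word_prior,
    )
    gamma = lda.fit_transform(X)
    beta = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    return TopicModel(K=K, beta=beta, gamma=gamma, vocabulary=words)


def _hdi_upper(values: np.ndarray, mass: float) -> float:
    """Upper limit of the empirical highest-density interval.

    The HDI of a discrete sample is the shortest contiguous window of the
    sorted values containing ``ceil(mass * n)`` points; ties go to the
    first (lowest) such window, so a constant sample yields the common
    value and "strictly above" selects nothing.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    m = max(1, math.ceil(mass * n))
    if m >= n:
        return float(v[-1])
    widths = v[m - 1:] - v[: n - m + 1]
    i = int(np.argmin(widths))
    return float(v[i + m - 1])


def select_top_words(
    tm: TopicModel,
    hdi_mass: float = 0.99,
    top_frac: float = 0.005,
    selector: str = "hdi",
    pooled: bool = False,
) -> TopWordSelection:
    """Select each topic's characteristic words.

    ``selector="hdi"`` keeps words whose beta is strictly above the upper
    limit of the ``hdi_mass`` empirical HDI of beta values ("the highest
    0.5% of probabilities" under LDA's near-zero-mass bulk);
    ``selector="top_frac"`` keeps words strictly above the ``1 - top_frac``
    quantile instead.  ``pooled=True`` computes one threshold from all
    topics' beta values pooled rather than per topic.  Selected words are
    labeled with within-topic quartiles Q1 (lowest beta) .. Q4 (highest).
    """
    if selector not in ("hdi", "top_frac"):
        raise ValueError(f"unknown selector {selector!r}")

    def threshold_of(values: np.ndarray) -> float:
        if selector == "hdi":
            return _hdi_upper(values, hdi_mass)
        return float(np.quantile(values, 1.0 - top_frac))

    pooled_thr = threshold_of(tm.beta.ravel()) if pooled else None
    words_out: list[tuple[str, ...]] = []
    thresholds: list[float] = []
    quartiles: list[dict] = []
    vocab = np.array(tm.vocabulary)
    for k in range(tm.K):
        row = tm.beta[k]
        thr = pooled_thr if pooled else threshold_of(row)
        mask = row > thr
        order = np.argsort(-row[mask], kind="stable")
        sel = vocab[mask][order]
        betas = row[mask][order]
        qs: dict[str, str] = {}
        nsel = sel.size
        if nsel:
            # rank 1 = smallest beta; quartile = ceil(4 * rank / n)
            ranks = nsel - np.arange(nsel)
            qlab = np.ceil(4.0 * ranks / nsel).astype(int)
            qs = {w: f"Q{q}" for w, q in zip(sel, qlab)}
        words_out.append(tuple(sel))
        thresholds.append(float(thr))
        quartiles.append(qs)
    return TopWordSelection(
        words=tuple(words_out),
        thresholds=tuple(thresholds),
        quartiles=tuple(quartiles),
        hdi_mass=hdi_mass,
    )


def feature_vocabulary_map(
    lexicon: FeatureLexicon, vocabulary: tuple[str, ...]
) -> dict[str, list[int]]:
    """Map each feature to vocabulary indices via the counting prefix rules.

    A vocabulary word matches a feature if its hyphen-stripped form starts
    with any one-part stem or with the concatenation of a two-part stem
    (topic preprocessing joins hyphenated words, so "self-organizing"
    appears as "selforganizing").
    """
    out: dict[str, list[int]] = {}
    stripped = [w.replace("-", "") for w in vocabulary]
    for f in lexicon:
        prefixes = list(f.unigram_stems) + [a + b for a, b in f.bigram_stems]
        idx = [
            j
            for j, w in enumerate(stripped)
            if any(w.startswith(p) for p in prefixes)
        ]
        out[f.name] = idx
    return out


def compare_feature_topics(
    tm: TopicModel,
    sel: TopWordSelection,
    lexicon: FeatureLexicon,
    doc_groups,
) -> pd.DataFrame:
    """Summarize each feature's importance per article group.

    Per feature and group: ``topics_<g>`` counts the topics attributed to
    group g (by the topic's gamma-weighted group share) whose selected
    words include a feature-matching word, and ``prob_<g>`` is the group
    mean of the per-document feature probability
    ``sum_k gamma_dk * sum_{w in f} beta_kw``.  Features matching no
    vocabulary word are flagged ``absent``.
    """
    groups = np.asarray(doc_groups)
    if groups.shape[0] != tm.gamma.shape[0]:
        raise ValueError("doc_groups length must match the number of documents")
    labels = sorted(set(groups))
    fmap = feature_vocabulary_map(lexicon, tm.vocabulary)

    # attribute each topic to the group with the larger gamma share
    topic_mass = tm.gamma.sum(axis=0)
    shares = np.vstack(
        [tm.gamma[groups == g].sum(axis=0) / topic_mass for g in labels]
    )
    topic_group = np.array(labels, dtype=object)[shares.argmax(axis=0)]
    sel_sets = [set(w) for w in sel.words]

    rows = []
    for f in lexicon:
        idx = fmap[f.name]
        absent = len(idx) == 0
        row: dict = {"feature": f.name, "absent": absent}
        if absent:
            for g in labels:
                row[f"topics_{g}"] = 0
                row[f"prob_{g}"] = np.nan
            rows.append(row)
            continue
        fwords = {tm.vocabulary[j] for j in idx}
        has_word = np.array(
            [bool(fwords & sel_sets[k]) for k in range(tm.K)]
        )
        beta_f = tm.beta[:, idx].sum(axis=1)  # (K,)
        doc_prob = tm.gamma @ beta_f  # (D,)
        for g in labels:
            row[f"topics_{g}"] = int((has_word & (topic_group == g)).sum())
            row[f"prob_{g}"] = float(doc_prob[groups == g].mean())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    if len(labels) == 2:
        a, b = labels
        table["prob_diff"] = table[f"prob_{a}"] - table[f"prob_{b}"]
    return table
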