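"""Article × feature matrices.

Builds the count matrix by running the lexicon matcher over every article,
converts counts to within-article relative frequencies (count divided by the
article's total token count), and applies the exclusion rule that removes
articles mentioning none of the features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus, tokenize
from .lexicon import FeatureLexicon, count_features

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "RelFreqMatrix",
    "build_feature_matrix",
    "relative_frequency",
    "drop_featureless",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Integer article × feature counts with per-article totals and groups.

    ``counts`` is a DataFrame indexed by article id with feature-name
    columns; ``totals`` and ``groups`` are Series aligned to the same index.
    """

    counts: pd.DataFrame
    totals: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not (self.counts.index.equals(self.totals.index)
                and self.counts.index.equals(self.groups.index)):
            raise ValueError("counts, totals and groups must share one index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.to_numpy() > self.totals.to_numpy()[:, None]).any():
            raise ValueError("a count exceeds its article's total word count")

    @property
    def feature_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def article_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "group", self.groups)
        out.insert(1, "total_words", self.totals)
        out.to_csv(path, sep="\t", index_label="article_id")


@dataclass(frozen=True)
class RelFreqMatrix:
    """Per-article relative feature frequencies in [0, 1]."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("values and groups must share one index")
        arr = self.values.to_numpy()
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("relative frequencies must lie in [0, 1]")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def article_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="article_id")


def build_feature_matrix(corpus: Corpus, lexicon: FeatureLexicon) -> FeatureMatrix:
    """Count feature mentions for every article in the corpus.

    Rows follow corpus order; columns follow lexicon order.  Deterministic:
    the same corpus and lexicon always produce the identical matrix.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    rows = []
    totals = []
    for article in corpus:
        vec = count_features(tokenize(article.read_text()), lexicon)
        rows.append(vec.counts)
        totals.append(vec.total_words)
    ids = pd.Index(corpus.ids, name="article_id")
    return FeatureMatrix(
        counts=pd.DataFrame(np.vstack(rows), index=ids, columns=lexicon.names),
        totals=pd.Series(totals, index=ids, name="total_words"),
        groups=pd.Series(corpus.groups, index=ids, name="group"),
    )


def relative_frequency(m: FeatureMatrix) -> RelFreqMatrix:
    """Divide each article's counts by its total word count.

    Raises
    ------
    ValueError
        If any article has a zero total word count; such articles carry no
        usable signal and should be removed with :func:`drop_featureless`.
    """
    totals = m.totals.to_numpy()
    if (totals <= 0).any():
        bad = list(m.totals.index[totals <= 0])
        raise ValueError(
            f"articles with zero total words: {bad}; apply drop_featureless first"
        )
    values = m.counts.div(m.totals, axis=0)
    return RelFreqMatrix(values=values, groups=m.groups)


def drop_featureless(m: FeatureMatrix) -> FeatureMatrix:
    """Remove articles whose feature counts are all zero.

    Mirrors the analysis convention of excluding articles that mention none
    of the lexicon features; the removed ids and a per-group tally are
    logged (e.g. ``control = 1, complexity = 0``).
    """
    zero = m.counts.sum(axis=1).to_numpy() == 0
    if zero.all():
        raise ValueError("every article is featureless; nothing left to analyze")
    if zero.any():
        dropped = m.groups[zero]
        tally = ", ".join(
            f"{g} = {int((dropped == g).sum())}" for g in ("control", "complexity")
        )
        logger.info(
            "dropped %d featureless article(s) (%s): %s",
            int(zero.sum()), tally, list(dropped.index),
        )
    keep = ~zero
    return FeatureMatrix(
        counts=m.counts.loc[keep],
        totals=m.totals.loc[keep],
        groups=m.groups.loc[keep],
    )
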