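import numpy as np
import pandas as pd
import pytest

from ecoweave.features import FeatureMatrix, RelFreqMatrix
from ecoweave.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


def make_relfreq(values, groups, columns=None, ids=None) -> RelFreqMatrix:
    """Assemble a RelFreqMatrix from raw arrays for direct statistical tests."""
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    ids = pd.Index(ids or [f"a{i}" for i in range(n)], name="article_id")
    columns = columns or [f"feat{j}" for j in range(f)]
    return RelFreqMatrix(
        values=pd.DataFrame(values, index=ids, columns=columns),
        groups=pd.Series(list(groups), index=ids, name="group"),
    )


def make_counts(counts, totals, groups, columns=None, ids=None) -> FeatureMatrix:
    counts = np.asarray(counts, dtype=np.int64)
    n, f = counts.shape
    ids = pd.Index(ids or [f"a{i}" for i in range(n)], name="article_id")
    columns = columns or [f"feat{j}" for j in range(f)]
    return FeatureMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=columns),
        totals=pd.Series(list(totals), index=ids, name="total_words"),
        groups=pd.Series(list(groups), index=ids, name="group"),
    )


def write_corpus(tmp_path, articles):
    """Write a corpus fixture: articles = [(id, group, year, text, refs), ...]."""
    text_dir = tmp_path / "texts"
    text_dir.mkdir(exist_ok=True)
    lines = ["article_id\tgroup\tyear\ttext_file\treferences"]
    for aid, group, year, text, refs in articles:
        (text_dir / f"{aid}.txt").write_text(text)
        lines.append(f"{aid}\t{group}\t{year}\ttexts/{aid}.txt\t{'|'.join(refs)}")
    meta = tmp_path / "metadata.tsv"
    meta.write_text("\n".join(lines) + "\n")
    return meta
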