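"""Corpus reading, tokenization and topic-model preprocessing.

Articles are consumed as plain text (one file per article) plus a metadata
table.  Two tokenizations are used downstream:

* :func:`tokenize` feeds the feature counter: lowercase, punctuation
  stripped, internal hyphens kept so hyphenated forms ("non-linear") stay
  one token, numerals retained.
* :func:`preprocess_for_topics` feeds the topic model: stopwords removed,
  hyphenated words joined, plurals singularized by rule.

Metadata format: TSV with header
``article_id<TAB>group<TAB>year<TAB>text_file<TAB>references``; references
are pipe-separated citation keys (possibly empty).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleRecord",
    "TokenizedArticle",
    "Corpus",
    "read_corpus",
    "tokenize",
    "preprocess_for_topics",
    "STOPWORDS",
    "GROUP_COMPLEXITY",
    "GROUP_CONTROL",
]

GROUP_COMPLEXITY = "complexity"
GROUP_CONTROL = "control"
_GROUPS = (GROUP_COMPLEXITY, GROUP_CONTROL)


class CorpusError(ValueError):
    """Raised for malformed corpus metadata or missing files."""


@dataclass(frozen=True)
class ArticleRecord:
    id: str
    group: str
    year: int
    text_ref: Path
    references: tuple[str, ...] = ()

    def read_text(self) -> str:
        return Path(self.text_ref).read_text(encoding="utf-8")


@dataclass(frozen=True)
class TokenizedArticle:
    id: str
    tokens: tuple[str, ...]

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of article records with unique ids."""

    articles: tuple[ArticleRecord, ...]

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self):
        return iter(self.articles)

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.articles]

    @property
    def groups(self) -> list[str]:
        return [a.group for a in self.articles]

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for a in self.articles:
            sizes[a.group] = sizes.get(a.group, 0) + 1
        return sizes


def _normalize_key(key: str) -> str:
    """Normalize a citation key: case-fold, strip punctuation and whitespace."""
    return re.sub(r"[^0-9a-z]+", "", key.lower())


def read_corpus(metadata_path: str | Path, text_dir: str | Path | None = None) -> Corpus:
    """Read corpus metadata and validate it against the text directory.

    ``text_file`` entries are resolved relative to ``text_dir`` (default:
    the metadata file's directory).  Group labels are case-folded to the
    canonical ``complexity`` / ``control`` with a warning; unknown labels,
    duplicate ids and missing text files raise :class:`CorpusError` naming
    the record.
    """
    metadata_path = Path(metadata_path)
    base = Path(text_dir) if text_dir is not None else metadata_path.parent
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    with metadata_path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"article_id", "group", "year", "text_file"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CorpusError(
                f"{metadata_path}: header must contain {sorted(required)}"
            )
        for row in reader:
            aid = row["article_id"].strip()
            if not aid:
                raise CorpusError(f"{metadata_path}: empty article_id")
            if aid in seen:
                raise CorpusError(f"duplicate article id {aid!r}")
            seen.add(aid)
            group = row["group"].strip()
            folded = group.lower()
            if folded not in _GROUPS:
                raise CorpusError(f"article {aid!r}: unknown group label {group!r}")
            if folded != group:
                logger.warning(
                    "article %r: group label %r normalized to %r", aid, group, folded
                )
            text_path = base / row["text_file"].strip()
            if not text_path.is_file():
                raise CorpusError(f"article {aid!r}: missing text file {text_path}")
            refs_field = (row.get("references") or "").strip()
            refs = tuple(
                dict.fromkeys(
                    _normalize_key(r) for r in refs_field.split("|") if r.strip()
                )
            )
            records.append(
                ArticleRecord(
                    id=aid,
                    group=folded,
                    year=int(row["year"]),
                    text_ref=text_path,
                    references=refs,
                )
            )
    corpus = Corpus(tuple(records))
    logger.info("read %d articles: %s", len(corpus), corpus.group_sizes())
    return corpus


# Word tokens: alphanumeric runs, optionally joined by internal hyphens.
_TOKEN_RE = re.compile(r"[0-9a-z]+(?:-[0-9a-z]+)*")


def tokenize(raw_text: str) -> list[str]:
    """Lowercase word tokens with punctuation stripped, internal hyphens kept.

    Idempotent on its own output joined by spaces.  Numerals are retained
    as tokens; an empty or punctuation-only input yields an empty list.
    """
    return _TOKEN_RE.findall(raw_text.lower())


#: Fixed, versioned English stopword list shipped with the package.
STOPWORDS: frozenset[str] = frozenset(
    """
    a about above after again against all also am an and any are as at be
    because been before being below between both but by can cannot could did
    do does doing down during each et few for from further had has have
    having he her here hers herself him himself his how i if in into is it
    its itself just may me might more most must my myself no nor not now of
    off on once only or other our ours ourselves out over own same shall she
    should so some such than that the their theirs them themselves then
    there these they this those through to too under until up upon very was
    we were what when where which while who whom why will with within would
    you your yours yourself yourselves
    al fig figs eg ie etc vs versus per
    """.split()
)

#: Plural forms left unchanged by the rule singularizer.
_INVARIANT_PLURALS: frozenset[str] = frozenset(
    {
        "species", "series", "analysis", "hypothesis", "basis", "axis",
        "this", "thus", "is", "as", "its", "us", "bias", "chaos",
        "data", "media", "criteria", "phenomena", "taxa", "genus",
        "homeostasis", "emphasis", "synthesis",
    }
)


def _singularize(word: str) -> str:
    if word in _INVARIANT_PLURALS or len(word) <= 3:
        return word
    if word.endswith("ies"):
        return word[:-3] + "y"
    if word.endswith(("xes", "ches", "shes", "sses", "zes", "oes")):
        return word[:-2]
    if word.endswith("ss") or word.endswith("us") or word.endswith("is"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def preprocess_for_topics(
    tokens: Iterable[str], stopwords: frozenset[str] | set[str] = STOPWORDS
) -> list[str]:
    """Prepare counting tokens for topic modeling.

    Drops stopwords, joins hyphenated words ("non-linear" -> "nonlinear"),
    and singularizes plurals by rule (-ies -> -y, -es -> -e/-, -s -> -, with
    an invariant-plural exception list).  Purely numeric tokens are dropped
    (they carry no topical content).
    """
    out: list[str] = []
    for tok in tokens:
        if tok in stopwords:
            continue
        joined = tok.replace("-", "")
        if not joined or joined.isdigit():
            continue
        word = _singularize(joined)
        if word in stopwords:
            continue
        out.append(word)
    return out
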