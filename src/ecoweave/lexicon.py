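"""Feature lexicon and token matching.

The package quantifies how often articles discuss features typical of complex
ecological systems (self-organization, feedbacks, nonlinearity, ...).  Each
feature is detected through one or more *search stems*: lowercase word
prefixes chosen to capture plurals, derived forms and both British and
American spellings (e.g. the stem ``self-orga`` matches "self-organization",
"self-organising", "self-organized").

Matching rules
--------------
* A one-part stem matches a token if the token, with internal hyphens
  removed, starts with the stem (hyphens are likewise removed from the stem,
  so ``self-orga`` and ``selforga`` are the same matcher).
* A two-part stem matches a pair of adjacent tokens whose hyphen-stripped
  forms start with the respective parts ("self organization" matches
  ``self orga``).
* Within one feature, a token position is counted at most once: two-part
  stems are tried first at each position, scanning left to right.

Prefix matching deliberately over-matches in rare cases ("musical scale"
counts toward *scaling*); this mirrors the stem convention of the lexicon
and is documented rather than patched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureDef",
    "FeatureLexicon",
    "FeatureCountVector",
    "load_lexicon",
    "count_features",
    "DEFAULT",
]

#: Sentinel accepted by :func:`load_lexicon` for the built-in 23-feature set.
DEFAULT = "default"


class LexiconError(ValueError):
    """Raised when a lexicon file or definition violates an invariant."""


def _strip_hyphens(token: str) -> str:
    return token.replace("-", "")


@dataclass(frozen=True)
class FeatureDef:
    """One named feature with its match stems.

    Parameters
    ----------
    name
        Feature label, e.g. ``"self-organization"``.
    stems
        Match patterns.  Each stem is a tuple of 1 or 2 lowercase word
        prefixes; one-part stems match single (hyphen-stripped) tokens,
        two-part stems match adjacent token pairs.
    related
        Free-text related-concept tags (informational only).
    """

    name: str
    stems: tuple[tuple[str, ...], ...]
    related: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise LexiconError("feature name must be nonempty")
        if not self.stems:
            raise LexiconError(f"feature {self.name!r} has no stems")
        for stem in self.stems:
            if len(stem) not in (1, 2) or any(not p for p in stem):
                raise LexiconError(
                    f"feature {self.name!r}: stem {stem!r} must have 1 or 2 "
                    "nonempty parts"
                )
            for part in stem:
                if part != part.lower():
                    raise LexiconError(
                        f"feature {self.name!r}: stem part {part!r} must be lowercase"
                    )

    @property
    def unigram_stems(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.stems if len(s) == 1)

    @property
    def bigram_stems(self) -> tuple[tuple[str, str], ...]:
        return tuple((s[0], s[1]) for s in self.stems if len(s) == 2)


def _parse_stems(spec: str) -> tuple[tuple[str, ...], ...]:
    """Parse a plus-separated stem column into normalized matchers.

    A hyphenated variant ("non-linear") collapses onto the joined unigram
    ("nonlinear") because unigram matching is hyphen-stripped on both sides;
    a spaced variant becomes a two-part stem.  Duplicates after
    normalization are dropped, preserving order.
    """
    out: list[tuple[str, ...]] = []
    for raw in spec.split("+"):
        raw = raw.strip().lower()
        if not raw:
            raise LexiconError(f"empty stem in {spec!r}")
        parts = raw.split()
        if len(parts) == 1:
            stem: tuple[str, ...] = (_strip_hyphens(parts[0]),)
        elif len(parts) == 2:
            stem = (_strip_hyphens(parts[0]), _strip_hyphens(parts[1]))
        else:
            raise LexiconError(f"stem {raw!r} has more than 2 parts")
        if any(not p for p in stem):
            raise LexiconError(f"stem {raw!r} reduces to an empty part")
        if stem not in out:
            out.append(stem)
    return tuple(out)


@dataclass(frozen=True)
class FeatureLexicon:
    """Ordered collection of :class:`FeatureDef` with unique names."""

    features: tuple[FeatureDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LexiconError(f"duplicate feature names: {dupes}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def index(self, name: str) -> int:
        return self.names.index(name)


# The built-in lexicon: 23 features typical of complex ecological systems,
# each with its search-string stems and related concepts.
_DEFAULT_ROWS: tuple[tuple[str, str, str], ...] = (
    ("adaptation", "adapt", "evolution, niche, plasticity, phenological shifts"),
    ("aggregation", "aggregat", "consortia, superstructures"),
    ("attractor", "attractor", "criticality, hysteresis, tipping points, stable states"),
    ("chaos", "chaos + chaotic", "sensitivity, phase space divergence"),
    ("diversity", "diversit", "entropy, heterogeneity, information, variation"),
    ("dynamicity", "dynamic", "evolution, stasis, transformation"),
    ("emergence", "emergen", "collective intelligence, gestalt principles"),
    ("feedback", "feedback", "reinforcement, top-down causation"),
    ("flow", "flow", "information, linkages"),
    ("fractality", "fractal", "regularity, scale invariance"),
    ("hierarchy", "hierarch", "levels, nestedness, scales"),
    ("homeostasis", "homeosta", "control, robustness"),
    ("interaction", "interact", "competition, dependence, parasitism, mutualism, synergy"),
    ("memory", "memory + memories", "lagged responses, Markov processes"),
    ("modularity", "modul", "cluster, connectivity, stability"),
    ("network", "network", "food webs, feedbacks, nodes"),
    ("nonequilibrium", "non-equilib + non equilib + nonequilib",
     "balance, disturbance, multiple stable states, instability"),
    ("nonlinearity", "non-linear + non linear + nonlinear", "higher-order effects"),
    ("resilience", "resilien", "brittleness, robustness, stability"),
    ("scaling", "scal + scale-depend + scale depend", "discrete hierarchy, grain, levels"),
    ("self-organization", "self-orga + self orga + selforga",
     "evolution, emergence, multicellularity, pattern formation"),
    ("stability", "stabilit", "invasibility, persistence, resistance, robustness"),
    ("threshold", "thresho", "criticality, tipping point"),
)


def default_lexicon() -> FeatureLexicon:
    """The built-in 23-feature lexicon."""
    return FeatureLexicon(
        tuple(
            FeatureDef(name, _parse_stems(stems), related)
            for name, stems, related in _DEFAULT_ROWS
        )
    )


def load_lexicon(path_or_default: str | Path = DEFAULT) -> FeatureLexicon:
    """Load a feature lexicon from a TSV file, or return the built-in set.

    The file format is tab-separated with a header row
    ``name<TAB>stems<TAB>related``; the ``stems`` column is plus-separated
    (``"chaos + chaotic"``).  Passing the sentinel ``"default"`` (or omitting
    the argument) returns the built-in 23-feature lexicon.

    Raises
    ------
    LexiconError
        On a malformed row, duplicate name or empty stem, naming the
        offending row.
    """
    if path_or_default == DEFAULT:
        return default_lexicon()
    path = Path(path_or_default)
    features: list[FeatureDef] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["name", "stems"]:
            raise LexiconError(f"{path}: expected header 'name\\tstems\\trelated'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise LexiconError(f"{path}:{lineno}: expected at least 2 columns")
            name = row[0].strip()
            if not name:
                raise LexiconError(f"{path}:{lineno}: empty feature name")
            related = row[2].strip() if len(row) > 2 else ""
            try:
                stems = _parse_stems(row[1])
            except LexiconError as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
            features.append(FeatureDef(name, stems, related))
    try:
        return FeatureLexicon(tuple(features))
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class FeatureCountVector:
    """Per-feature counts for one article plus its total token count."""

    counts: np.ndarray
    total_words: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.total_words < 0:
            raise ValueError("total_words must be nonnegative")
        if self.total_words and (counts > self.total_words).any():
            raise ValueError("a count exceeds total_words")


class _Matcher:
    """Compiled matcher for a lexicon with per-token memoization.

    Filler vocabulary dominates real articles, so match results for each
    distinct (hyphen-stripped) token are cached: ``_uni[token]`` holds the
    feature indices whose one-part stems prefix-match it, ``_big[token]``
    the ``(feature, second_part)`` candidates whose two-part stems start
    with it.
    """

    def __init__(self, lexicon: FeatureLexicon):
        self.lexicon = lexicon
        self._uni_stems = [
            [(i, s) for i, f in enumerate(lexicon) for s in f.unigram_stems]
        ][0]
        self._big_stems = [
            (i, a, b) for i, f in enumerate(lexicon) for a, b in f.bigram_stems
        ]
        self._uni: dict[str, tuple[int, ...]] = {}
        self._big: dict[str, tuple[tuple[int, str], ...]] = {}

    def _lookup(self, token: str) -> tuple[tuple[int, ...], tuple[tuple[int, str], ...]]:
        uni = self._uni.get(token)
        if uni is None:
            uni = tuple(
                dict.fromkeys(i for i, s in self._uni_stems if token.startswith(s))
            )
            big = tuple((i, b) for i, a, b in self._big_stems if token.startswith(a))
            self._uni[token] = uni
            self._big[token] = big
        return uni, self._big[token]

    def count(self, tokens: Sequence[str]) -> FeatureCountVector:
        n = len(tokens)
        stripped = [_strip_hyphens(t) for t in tokens]
        counts = np.zeros(len(self.lexicon), dtype=np.int64)
        # next position at which each feature may match again (first-match-wins)
        next_free = np.zeros(len(self.lexicon), dtype=np.int64)
        for i, tok in enumerate(stripped):
            uni, big = self._lookup(tok)
            for feat, second in big:
                if i >= next_free[feat] and i + 1 < n and stripped[i + 1].startswith(second):
                    counts[feat] += 1
                    next_free[feat] = i + 2
            for feat in uni:
                if i >= next_free[feat]:
                    counts[feat] += 1
                    next_free[feat] = i + 1
        return FeatureCountVector(counts=counts, total_words=n)


_MATCHER_CACHE: dict[int, _Matcher] = {}


def count_features(tokens: Iterable[str], lexicon: FeatureLexicon) -> FeatureCountVector:
    """Count feature mentions in a tokenized article.

    ``tokens`` must already be lowercase with punctuation stripped (see
    :func:`ecoweave.corpus.tokenize`); internal hyphens may remain and are
    removed before matching.  An empty token sequence yields a zero vector
    with ``total_words = 0`` (flagged downstream by the featureless-article
    drop rule).
    """
    matcher = _MATCHER_CACHE.get(id(lexicon))
    if matcher is None or matcher.lexicon is not lexicon:
        matcher = _Matcher(lexicon)
        _MATCHER_CACHE[id(lexicon)] = matcher
    return matcher.count(list(tokens))
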