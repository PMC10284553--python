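"""Synthetic corpus generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: two
article groups ("complexity" and "control") with group-specific per-feature
inclusion probabilities and mention intensities, log-normal article lengths,
Zipf-distributed filler vocabulary, and reference lists drawn from a
citation pool with planted cluster structure.  Every simulated corpus is
accompanied by a :class:`SyntheticTruth` carrying the generating parameters,
the realized per-article feature counts and the planted reference clusters,
so recovery can be tested end to end.

Feature mentions are injected as surface strings the lexicon matcher must
recognize: 80% joined/base forms ("nonlinear..."), 10% hyphenated
("non-linear...") and 10% spaced two-word forms ("non linear..."),
exercising every matcher branch.  Filler tokens ("x123...") are disjoint
from all feature stems, so realized counts in the truth table equal what
the matcher recovers from the emitted text exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Corpus, read_corpus
from .lexicon import FeatureLexicon, default_lexicon

__all__ = ["SimConfig", "SyntheticTruth", "default_config", "simulate_corpus"]

_VARIANT_PROBS = (0.8, 0.1, 0.1)  # joined, hyphenated, spaced


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic corpus.

    ``inclusion[g][f]`` is the probability that an article of group g
    mentions feature f at all; given inclusion, the mention count is
    ``1 + Poisson(intensity[g][f] - 1)``.  Article token counts are
    log-normal with parameters ``length_mu``/``length_sigma``.  Reference
    lists of length ``refs_per_article`` are drawn from a pool of
    ``ref_pool_size`` keys split evenly into ``n_ref_clusters`` planted
    clusters: an article picks a home cluster and samples references with
    weight ``w_in`` for home-cluster members and ``w_out`` otherwise.
    """

    n_complexity: int = 172
    n_control: int = 180
    length_mu: float = 7.8
    length_sigma: float = 0.35
    inclusion: dict = field(default_factory=dict)  # group -> array of len(lexicon)
    intensity: dict = field(default_factory=dict)  # group -> array of len(lexicon)
    filler_vocab_size: int = 5000
    zipf_exponent: float = 1.05
    ref_pool_size: int = 150
    n_ref_clusters: int = 3
    w_in: float = 12.0
    w_out: float = 1.0
    refs_per_article: int = 20
    seed: int = 0

    def validate(self, n_features: int) -> None:
        for name in ("n_complexity", "n_control", "filler_vocab_size",
                     "ref_pool_size", "n_ref_clusters", "refs_per_article"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not (self.w_in >= self.w_out > 0):
            raise ValueError("config fields must satisfy w_in >= w_out > 0")
        if self.length_sigma < 0:
            raise ValueError("config field 'length_sigma' must be nonnegative")
        if self.refs_per_article > self.ref_pool_size:
            raise ValueError(
                "config field 'refs_per_article' exceeds 'ref_pool_size'"
            )
        for g in ("complexity", "control"):
            if g not in self.inclusion or g not in self.intensity:
                raise ValueError(f"config field 'inclusion'/'intensity' missing group {g!r}")
            p = np.asarray(self.inclusion[g], dtype=float)
            lam = np.asarray(self.intensity[g], dtype=float)
            if p.shape != (n_features,) or lam.shape != (n_features,):
                raise ValueError(
                    f"config field 'inclusion'/'intensity' for {g!r} must have "
                    f"length {n_features}"
                )
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"config field 'inclusion[{g}]' must lie in [0, 1]")
            if (lam < 1).any():
                raise ValueError(f"config field 'intensity[{g}]' must be >= 1")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["inclusion"] = {g: list(map(float, v)) for g, v in self.inclusion.items()}
        d["intensity"] = {g: list(map(float, v)) for g, v in self.intensity.items()}
        return d


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside a simulated corpus."""

    config: SimConfig
    feature_counts: pd.DataFrame  # realized mention counts, article x feature
    ref_clusters: dict  # reference key -> planted cluster id

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_jsonable(),
            "feature_counts": {
                aid: [int(c) for c in row]
                for aid, row in zip(self.feature_counts.index,
                                    self.feature_counts.to_numpy())
            },
            "feature_names": list(self.feature_counts.columns),
            "ref_clusters": {k: int(v) for k, v in sorted(self.ref_clusters.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def default_config(seed: int = 0, lexicon: FeatureLexicon | None = None) -> SimConfig:
    """Study-scale defaults: 172 + 180 articles, mean richness ~9 vs ~6.

    Complexity-group inclusion probabilities decline linearly from 0.75 to
    0.04 across the 23 features (expected richness 9.1).  Five features
    ("attractor", "flow", "memory", "nonequilibrium", "threshold") are
    shared equally by both groups — not every feature should discriminate —
    and the remaining control probabilities are the complexity ones scaled
    so the control expected richness is 6.0.  Mention intensities are 3.0
    (complexity) vs 2.0 (control) expected mentions per included feature.
    """
    lexicon = lexicon or default_lexicon()
    F = len(lexicon)
    p_cx = np.linspace(0.75, 0.04, F)
    shared_names = {"attractor", "flow", "memory", "nonequilibrium", "threshold"}
    shared = np.array([f.name in shared_names for f in lexicon])
    target_control = 6.0
    scale = (target_control - p_cx[shared].sum()) / p_cx[~shared].sum()
    p_ct = np.where(shared, p_cx, p_cx * scale)
    return SimConfig(
        inclusion={"complexity": p_cx, "control": p_ct},
        intensity={
            "complexity": np.full(F, 3.0),
            "control": np.full(F, 2.0),
        },
        seed=seed,
    )


def _surface_forms(lexicon: FeatureLexicon) -> list[dict]:
    """Joined / hyphenated / spaced surface realizations per feature."""
    forms = []
    for f in lexicon:
        uni = f.unigram_stems[0]
        big = f.bigram_stems[0] if f.bigram_stems else None
        forms.append(
            {
                "joined": [uni],
                "hyphenated": [f"{big[0]}-{big[1]}"] if big else [uni],
                "spaced": list(big) if big else [uni],
            }
        )
    return forms


def simulate_corpus(
    cfg: SimConfig,
    out_dir: str | Path,
    lexicon: FeatureLexicon | None = None,
) -> tuple[Corpus, SyntheticTruth]:
    """Write a synthetic corpus (metadata, texts, truth.json) and load it back.

    Deterministic: the same config (including its seed) produces
    byte-identical files.  Returns the corpus read through the standard
    reader plus the ground truth.
    """
    lexicon = lexicon or default_lexicon()
    cfg.validate(len(lexicon))
    out_dir = Path(out_dir)
    text_dir = out_dir / "texts"
    text_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    filler_vocab = np.array([f"x{i}" for i in range(cfg.filler_vocab_size)])
    zipf_w = 1.0 / np.arange(1, cfg.filler_vocab_size + 1) ** cfg.zipf_exponent
    zipf_p = zipf_w / zipf_w.sum()
    forms = _surface_forms(lexicon)

    pool = [f"ref{i:04d}" for i in range(cfg.ref_pool_size)]
    clusters = {
        ref: i % cfg.n_ref_clusters for i, ref in enumerate(pool)
    }
    cluster_ids = np.array([clusters[r] for r in pool])

    n_total = cfg.n_complexity + cfg.n_control
    groups = ["complexity"] * cfg.n_complexity + ["control"] * cfg.n_control
    ids = [f"a{i:04d}" for i in range(n_total)]
    meta_rows = []
    counts_rows = []
    variants = np.array(["joined", "hyphenated", "spaced"])
    for aid, group in zip(ids, groups):
        p = np.asarray(cfg.inclusion[group], dtype=float)
        lam = np.asarray(cfg.intensity[group], dtype=float)
        included = rng.random(len(p)) < p
        counts = np.zeros(len(p), dtype=np.int64)
        counts[included] = 1 + rng.poisson(lam[included] - 1.0)
        units: list[list[str]] = []
        for f_idx in np.nonzero(counts)[0]:
            for _ in range(counts[f_idx]):
                variant = rng.choice(variants, p=_VARIANT_PROBS)
                units.append(forms[f_idx][variant])
        n_tokens = max(50, int(round(rng.lognormal(cfg.length_mu, cfg.length_sigma))))
        n_mention_tokens = sum(len(u) for u in units)
        n_filler = max(0, n_tokens - n_mention_tokens)
        filler = filler_vocab[
            rng.choice(cfg.filler_vocab_size, size=n_filler, p=zipf_p)
        ].tolist()
        # scatter mention units among the filler, preserving unit adjacency
        slots = np.sort(rng.integers(0, n_filler + 1, size=len(units)))
        tokens: list[str] = []
        prev = 0
        for slot, unit in zip(slots, units):
            tokens.extend(filler[prev:slot])
            tokens.extend(unit)
            prev = slot
        tokens.extend(filler[prev:])
        (text_dir / f"{aid}.txt").write_text(" ".join(tokens) + "\n")

        home = int(rng.integers(cfg.n_ref_clusters))
        w = np.where(cluster_ids == home, cfg.w_in, cfg.w_out)
        refs = rng.choice(
            cfg.ref_pool_size, size=cfg.refs_per_article, replace=False,
            p=w / w.sum(),
        )
        ref_keys = [pool[j] for j in sorted(refs)]
        year = int(rng.integers(1990, 2022))
        meta_rows.append(
            (aid, group, year, f"texts/{aid}.txt", "|".join(ref_keys))
        )
        counts_rows.append(counts)

    meta_path = out_dir / "metadata.tsv"
    with meta_path.open("w", encoding="utf-8") as fh:
        fh.write("article_id\tgroup\tyear\ttext_file\treferences\n")
        for row in meta_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    truth = SyntheticTruth(
        config=cfg,
        feature_counts=pd.DataFrame(
            np.vstack(counts_rows),
            index=pd.Index(ids, name="article_id"),
            columns=lexicon.names,
        ),
        ref_clusters=clusters,
    )
    truth.to_json(out_dir / "truth.json")
    corpus = read_corpus(meta_path, out_dir)
    return corpus, truth
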