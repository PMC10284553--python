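"""End-to-end orchestration of the research-weaving analysis.

Runs the full chain — feature counting, diversity/dispersion/indicator
statistics, optional topic modeling, feature co-occurrence networks with
the ERGM, and co-citation clustering — from a single configuration, writing
every intermediate table plus a machine-readable JSON report.  The run is
fully deterministic given the configured seed, which fans out to the
stochastic stages by fixed offsets (indval: seed+1, topics: seed+2,
louvain: seed+3) so each stage is reproducible standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cocitation import build_cocitation, louvain, robustness_sweep, top_n_subgraph
from .corpus import preprocess_for_topics, read_corpus, tokenize
from .diversity import anova_compare, bray_curtis, dispersion_test, diversity_profile, indval
from .feature_network import (
    binarize_article_graph,
    build_bipartite,
    ergm_fit,
    network_summary,
    project,
)
from .features import build_feature_matrix, drop_featureless, relative_frequency
from .lexicon import load_lexicon
from .synthetic import default_config, simulate_corpus
from .topics import compare_feature_topics, fit_topics, select_top_words

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass
class RunConfig:
    """Configuration for :func:`run_all` (YAML-loadable)."""

    output_dir: str = "ecoweave_out"
    metadata: str | None = None  # existing corpus; None -> simulate
    text_dir: str | None = None
    lexicon: str = "default"
    seed: int = 0
    n_perm: int = 999
    run_topics: bool = True
    k_topics: int = 100
    top_n: int = 100
    tau: int = 1
    robustness_n: tuple[int, ...] = (60, 80, 100)
    holm: bool = True
    #: overrides applied to the synthetic generator's default configuration
    #: (e.g. {"n_complexity": 25}); ignored when a real corpus is given
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "robustness_n" in data:
            data["robustness_n"] = tuple(data["robustness_n"])
        return cls(**data)


@dataclass(frozen=True)
class RunReport:
    """Machine-readable summary of one pipeline run."""

    payload: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.payload, indent=1, sort_keys=True) + "\n"
        )


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv)
    adj = np.maximum.accumulate((m - np.arange(m)) * pv[order])
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def run_all(config: RunConfig | str | Path) -> RunReport:
    """Run the whole analysis; returns the report and writes all outputs.

    Stages: corpus (read or simulate) -> feature counting and exclusion ->
    diversity + dispersion + indicator analysis -> topic modeling (optional)
    -> feature networks + ERGM -> co-citation clustering + robustness.
    Any stage failure aborts with the stage name attached.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "versions": {"ecoweave": __version__},
    }
    stage = "setup"
    try:
        stage = "corpus"
        lexicon = load_lexicon(config.lexicon)
        if config.metadata is None:
            sim_cfg = default_config(seed=config.seed)
            if config.sim:
                sim_cfg = dataclasses.replace(sim_cfg, **config.sim)
            corpus, _truth = simulate_corpus(sim_cfg, out / "synthetic", lexicon)
            report["corpus"] = {"source": "synthetic"}
        else:
            corpus = read_corpus(config.metadata, config.text_dir)
            report["corpus"] = {"source": str(config.metadata)}
        report["corpus"]["group_sizes"] = corpus.group_sizes()

        stage = "count"
        fm = build_feature_matrix(corpus, lexicon)
        fm = drop_featureless(fm)
        rf = relative_frequency(fm)
        fm.to_tsv(out / "feature_counts.tsv")
        rf.to_tsv(out / "feature_relfreq.tsv")
        report["after_exclusion"] = {
            g: int(n) for g, n in rf.groups.value_counts().items()
        }

        stage = "diversity"
        prof = diversity_profile(rf)
        prof.table.to_csv(out / "diversity.tsv", sep="\t")
        rich = anova_compare(prof.table["richness"], prof.table["group"])
        hill = anova_compare(prof.table["hill1"], prof.table["group"])
        gm = prof.table.groupby("group")[["richness", "hill1"]].mean()
        report["diversity"] = {
            "mean_richness": {g: float(v) for g, v in gm["richness"].items()},
            "mean_hill1": {g: float(v) for g, v in gm["hill1"].items()},
            "anova_richness": rich,
            "anova_hill1": hill,
        }

        stage = "dispersion"
        d = bray_curtis(rf)
        disp = dispersion_test(
            pd.DataFrame(d, index=rf.values.index, columns=rf.values.index),
            rf.groups,
        )
        pd.DataFrame(
            {"group": disp.groups, "dist_to_median": disp.distances}
        ).to_csv(out / "dispersion.tsv", sep="\t")
        report["dispersion"] = {
            "group_mean": {g: float(v) for g, v in disp.group_stats["mean"].items()},
            "group_sd": {g: float(v) for g, v in disp.group_stats["sd"].items()},
            "F": disp.F, "df1": disp.df1, "df2": disp.df2, "p": disp.p,
        }

        stage = "indval"
        iv = indval(rf.values, rf.groups, mode="abundance",
                    n_perm=config.n_perm, seed=config.seed + 1)
        table = iv.table.copy()
        if config.holm:
            table["p_holm"] = _holm(table["p"].to_numpy())
        table.to_csv(out / "indval.tsv", sep="\t")
        sig = table[(table["p"] <= 0.05) & table["present"]]
        report["indval"] = {
            "n_significant_raw": int(len(sig)),
            "n_significant_complexity": int((sig["group"] == "complexity").sum()),
            "n_features": int(table["present"].sum()),
        }
        if config.holm:
            report["indval"]["n_significant_holm"] = int(
                (table["p_holm"] <= 0.05).sum()
            )

        if config.run_topics:
            stage = "topics"
            docs = [
                preprocess_for_topics(tokenize(a.read_text()))
                for a in corpus
                if a.id in set(rf.values.index)
            ]
            doc_groups = rf.groups.to_numpy()
            tm = fit_topics(docs, K=config.k_topics, seed=config.seed + 2)
            sel = select_top_words(tm)
            cmp_table = compare_feature_topics(tm, sel, lexicon, doc_groups)
            cmp_table.to_csv(out / "topic_feature_summary.tsv", sep="\t")
            with (out / "topics_beta.tsv").open("w") as fh:
                fh.write("topic\tword\tbeta\tquartile\n")
                for k, ws in enumerate(sel.words):
                    for w in ws:
                        j = tm.vocabulary.index(w)
                        fh.write(
                            f"{k}\t{w}\t{tm.beta[k, j]:.8g}\t{sel.quartiles[k][w]}\n"
                        )
            report["topics"] = {
                "K": tm.K,
                "mean_prob_diff": float(cmp_table["prob_diff"].mean(skipna=True))
                if "prob_diff" in cmp_table else None,
                "n_features_absent": int(cmp_table["absent"].sum()),
            }

        stage = "feature_network"
        bip = build_bipartite(rf)
        feat_net = project(bip, side="feature", weight_mode="count")
        summary = network_summary(feat_net)
        nx.write_graphml(feat_net.graph, out / "feature_projection.graphml")
        nx.to_pandas_edgelist(feat_net.graph).to_csv(
            out / "feature_projection_edges.tsv", sep="\t", index=False
        )
        report["feature_network"] = {
            "connectance": summary["connectance"],
            "n_features": feat_net.graph.number_of_nodes(),
            "n_links": feat_net.graph.number_of_edges(),
            "top_strength": dict(
                sorted(summary["strength"].items(), key=lambda kv: -kv[1])[:3]
            ),
        }

        stage = "ergm"
        art_graph = binarize_article_graph(rf, tau=config.tau)
        res = ergm_fit(art_graph, focal_group="complexity")
        res.to_frame().to_csv(out / "ergm.tsv", sep="\t")
        (out / "ergm_summary.txt").write_text(res.summary() + "\n")
        report["ergm"] = {
            "converged": bool(res.converged),
            "coef": {k: float(v) for k, v in res.params.items()},
            "se": {k: float(v) for k, v in res.bse.items()},
            "z": {k: float(v) for k, v in res.zvalues.items()},
            "p": {k: float(v) for k, v in res.pvalues.items()},
        }

        stage = "cocitation"
        cocite = build_cocitation(corpus, group="complexity")
        sub = top_n_subgraph(cocite, n=config.top_n)
        clust = louvain(sub, seed=config.seed + 3)
        nx.write_graphml(sub.graph, out / "cocitation.graphml")
        strengths = sub.strengths
        with (out / "clusters.tsv").open("w") as fh:
            fh.write("node\tcommunity\tstrength\n")
            for node in sorted(clust.communities):
                fh.write(
                    f"{node}\t{clust.communities[node]}\t{strengths[node]:g}\n"
                )
        sweep = robustness_sweep(cocite, list(config.robustness_n),
                                 seed=config.seed + 3)
        sweep.to_csv(out / "robustness.tsv", sep="\t", index=False)
        report["cocitation"] = {
            "n_references": cocite.graph.number_of_nodes(),
            "top_n": sub.graph.number_of_nodes(),
            "n_clusters": clust.n_communities,
            "modularity": clust.Q,
            "cluster_sizes": clust.sizes().tolist(),
            "robustness_min_ari": float(np.nanmin(sweep["ari_vs_previous"]))
            if sweep["ari_vs_previous"].notna().any() else None,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    rep = RunReport(payload=report)
    rep.to_json(out / "report.json")
    return rep
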