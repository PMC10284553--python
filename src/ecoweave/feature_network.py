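"""Article-feature networks and the exponential random graph model.

The relative-frequency matrix defines a bipartite network linking articles
to the features they mention, with edge weights equal to the within-article
relative usage.  The bipartite network is projected to a unipartite network
on either side (features sharing articles, or articles sharing features);
summaries include node strength, realized connectance and the degree
distribution.

Group structure among articles is modeled with an exponential random graph
model (ERGM), Pr(Y = y) = exp(theta' g(y)) / k(theta), over the binarized
article-article network with statistics

* ``edges``      — number of ties,
* ``nodematch``  — number of ties whose endpoints share a group (homophily),
* ``nodefactor`` — number of tie endpoints in the focal group.

All three terms are dyadic-independent, so the maximum-likelihood estimate
coincides with a Bernoulli (logistic) likelihood over dyads with covariates
(1, same-group indicator, focal-endpoint count); it is solved here by
Newton-Raphson with Fisher-information standard errors, which is exact for
this model class.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .features import RelFreqMatrix

__all__ = [
    "BipartiteGraph",
    "ProjectedGraph",
    "ErgmModel",
    "ErgmResults",
    "build_bipartite",
    "project",
    "network_summary",
    "binarize_article_graph",
    "ergm_fit",
]


@dataclass(frozen=True)
class BipartiteGraph:
    """Two-mode article-feature network with positive edge weights."""

    graph: nx.Graph
    article_nodes: tuple[str, ...]
    feature_nodes: tuple[str, ...]

    def group_of(self, article: str) -> str:
        return self.graph.nodes[article]["group"]


@dataclass(frozen=True)
class ProjectedGraph:
    """One-mode projection with per-node strength (sum of incident weights)."""

    graph: nx.Graph
    side: str

    @property
    def strengths(self) -> dict:
        return {
            v: float(sum(d["weight"] for _, _, d in self.graph.edges(v, data=True)))
            for v in self.graph.nodes
        }


def build_bipartite(rf: RelFreqMatrix) -> BipartiteGraph:
    """One edge per nonzero matrix entry, weighted by relative frequency."""
    X = rf.values
    if (X.sum(axis=1).to_numpy() <= 0).any():
        raise ValueError("all-zero rows present; apply drop_featureless first")
    g = nx.Graph()
    for aid, grp in rf.groups.items():
        g.add_node(aid, bipartite="article", group=grp)
    for feat in X.columns:
        g.add_node(feat, bipartite="feature")
    arr = X.to_numpy()
    ids = list(X.index)
    feats = list(X.columns)
    for i, j in zip(*np.nonzero(arr)):
        g.add_edge(ids[i], feats[j], weight=float(arr[i, j]))
    return BipartiteGraph(
        graph=g, article_nodes=tuple(ids), feature_nodes=tuple(feats)
    )


def project(
    b: BipartiteGraph, side: str = "feature", weight_mode: str = "count"
) -> ProjectedGraph:
    """Collapse the bipartite network onto one node type.

    Two nodes are linked iff they share at least one neighbor on the other
    side.  ``weight_mode="count"`` weights the link by the number of shared
    neighbors; ``"min_sum"`` by ``sum_k min(w_uk, w_vk)`` over shared
    neighbors k (a conservative shared-usage weight).  Direction of the
    original article->feature links is lost in the projection.
    """
    if side not in ("feature", "article"):
        raise ValueError(f"unknown side {side!r}")
    if weight_mode not in ("count", "min_sum"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    nodes = b.feature_nodes if side == "feature" else b.article_nodes
    g = b.graph
    out = nx.Graph()
    for v in nodes:
        out.add_node(v, **g.nodes[v])
    nodes = list(nodes)
    neigh = {v: set(g.neighbors(v)) for v in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            shared = neigh[u] & neigh[v]
            if not shared:
                continue
            if weight_mode == "count":
                w = float(len(shared))
            else:
                w = float(
                    sum(
                        min(g[u][k]["weight"], g[v][k]["weight"])
                        for k in shared
                    )
                )
            out.add_edge(u, v, weight=w)
    return ProjectedGraph(graph=out, side=side)


def network_summary(g: ProjectedGraph | nx.Graph) -> dict:
    """Realized connectance, per-node strength and the degree distribution.

    Connectance RC = L / [S(S-1)/2], the fraction of possible undirected
    links realized; degree distribution P(k) = N(k)/S.
    """
    graph = g.graph if isinstance(g, ProjectedGraph) else g
    S = graph.number_of_nodes()
    if S < 2:
        raise ValueError("need at least 2 nodes")
    L = graph.number_of_edges()
    rc = L / (S * (S - 1) / 2)
    strength = {
        v: float(sum(d.get("weight", 1.0) for _, _, d in graph.edges(v, data=True)))
        for v in graph.nodes
    }
    degs = [d for _, d in graph.degree()]
    dist = {int(k): degs.count(k) / S for k in sorted(set(degs))}
    return {"connectance": float(rc), "strength": strength, "degree_distribution": dist}


def binarize_article_graph(rf: RelFreqMatrix, tau: int = 1) -> nx.Graph:
    """Article-article graph: tie iff the two articles share >= tau features."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    occ = (rf.values.to_numpy() > 0).astype(np.int64)
    shared = occ @ occ.T
    ids = list(rf.values.index)
    g = nx.Graph()
    for aid, grp in rf.groups.items():
        g.add_node(aid, group=grp)
    n = len(ids)
    ii, jj = np.nonzero(np.triu(shared >= tau, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j])
    return g


_TERMS = ("edges", "nodematch", "nodefactor")


class ErgmModel:
    """Dyadic-independent ERGM over a binary undirected network.

    Parameters
    ----------
    graph
        Undirected :class:`networkx.Graph`; ties are the response.
    groups
        Mapping (or Series) node -> group label.  Omitted nodes default to
        the graph's ``group`` node attribute.
    focal_group
        Level whose endpoints the ``nodefactor`` statistic counts.
    terms
        Subset of ``("edges", "nodematch", "nodefactor")``; ``edges`` is
        always required (the intercept).
    """

    def __init__(
        self,
        graph: nx.Graph,
        groups=None,
        focal_group: str = "complexity",
        terms: tuple[str, ...] = _TERMS,
    ):
        if graph.number_of_nodes() < 4:
            raise ValueError("need at least 4 nodes")
        unknown = set(terms) - set(_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")
        if "edges" not in terms:
            raise ValueError("the 'edges' term is required")
        self.terms = tuple(t for t in _TERMS if t in terms)
        self.focal_group = focal_group
        nodes = list(graph.nodes)
        if groups is None:
            grp = {v: graph.nodes[v].get("group") for v in nodes}
        elif isinstance(groups, pd.Series):
            grp = groups.to_dict()
        else:
            grp = dict(groups)
        self.nodes = nodes
        self.group = np.array([grp[v] for v in nodes], dtype=object)
        if len(self.terms) > 1 and len(set(self.group)) < 2:
            raise ValueError("both groups must be present")

        n = len(nodes)
        iu, ju = np.triu_indices(n, k=1)
        adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
        self.y = adj[iu, ju]
        cols = []
        for t in self.terms:
            if t == "edges":
                cols.append(np.ones(iu.size))
            elif t == "nodematch":
                cols.append((self.group[iu] == self.group[ju]).astype(float))
            else:
                cols.append(
                    (self.group[iu] == focal_group).astype(float)
                    + (self.group[ju] == focal_group).astype(float)
                )
        self.X = np.column_stack(cols)

    # -- likelihood machinery ------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Bernoulli log-likelihood over dyads (equals the ERGM likelihood)."""
        eta = self.X @ np.asarray(params, dtype=float)
        # log(1 + e^eta) computed stably
        return float((self.y * eta).sum() - np.logaddexp(0.0, eta).sum())

    def observed_statistics(self) -> pd.Series:
        """The sufficient statistics g(y) of the observed network."""
        return pd.Series(self.X.T @ self.y, index=self._param_names(), name="g(y)")

    def _param_names(self) -> list[str]:
        names = []
        for t in self.terms:
            if t == "edges":
                names.append("edges")
            elif t == "nodematch":
                names.append("nodematch.group")
            else:
                names.append(f"nodefactor.group.{self.focal_group}")
        return names

    def fit(self, tol: float = 1e-10, max_iter: int = 100) -> "ErgmResults":
        """Newton-Raphson MLE with Fisher-information standard errors.

        An empty or complete network, or perfect separation on a covariate
        pattern, pushes the MLE to infinity; this is reported through
        ``converged=False`` with a diagnostic message rather than an error.
        """
        X, y = self.X, self.y
        k = X.shape[1]
        theta = np.zeros(k)
        message = "converged"
        converged = False
        degenerate = y.sum() == 0 or y.sum() == y.size
        if degenerate:
            message = (
                "non-convergence: network is empty or complete (edges MLE at "
                "infinity)"
            )
        for _ in range(0 if degenerate else max_iter):
            eta = X @ theta
            mu = expit(eta)
            grad = X.T @ (y - mu)
            W = mu * (1.0 - mu)
            info = (X * W[:, None]).T @ X
            if np.linalg.cond(info) > 1e12 or np.abs(theta).max() > 30:
                message = (
                    "non-convergence: degenerate network or perfect separation "
                    "(MLE diverges)"
                )
                break
            step = np.linalg.solve(info, grad)
            theta = theta + step
            if np.abs(grad).max() < tol or np.abs(step).max() < tol:
                if np.abs(theta).max() > 15:
                    message = (
                        "non-convergence: perfect separation on a covariate "
                        "pattern (coefficient diverges)"
                    )
                else:
                    converged = True
                break
        else:
            if not degenerate:
                message = "non-convergence: iteration limit reached"
        if converged:
            eta = X @ theta
            mu = expit(eta)
            W = mu * (1.0 - mu)
            info = (X * W[:, None]).T @ X
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.diag(cov))
        else:
            cov = np.full((k, k), np.nan)
            bse = np.full(k, np.nan)
        names = self._param_names()
        return ErgmResults(
            model=self,
            params=pd.Series(theta, index=names),
            bse=pd.Series(bse, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            converged=converged,
            message=message,
        )


@dataclass(frozen=True)
class ErgmResults:
    """Fitted ERGM: coefficients, uncertainties and diagnostics."""

    model: ErgmModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    converged: bool
    message: str

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index,
        )

    @property
    def llf(self) -> float:
        return self.model.loglike(self.params.to_numpy())

    def summary(self) -> str:
        gy = self.model.observed_statistics()
        lines = [
            "Exponential random graph model (dyadic-independent MLE)",
            f"nodes: {len(self.model.nodes)}  dyads: {self.model.y.size}  "
            f"edges: {int(self.model.y.sum())}",
            f"status: {self.message}",
            "",
            f"{'term':<28}{'g(y)':>10}{'coef':>10}{'std err':>10}"
            f"{'z':>9}{'P>|z|':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<28}{gy[name]:>10.1f}{self.params[name]:>10.4f}"
                f"{self.bse[name]:>10.4f}{self.zvalues[name]:>9.2f}"
                f"{self.pvalues[name]:>9.4f}"
            )
        lines.append("")
        lines.append(f"log-likelihood: {self.llf:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


def ergm_fit(
    graph: nx.Graph,
    groups=None,
    focal_group: str = "complexity",
    terms: tuple[str, ...] = _TERMS,
) -> ErgmResults:
    """Convenience wrapper: build :class:`ErgmModel` and fit it."""
    return ErgmModel(graph, groups=groups, focal_group=focal_group, terms=terms).fit()
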