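"""Co-occurrence networks: construction, modules, node roles, stability.

Networks are built from Pearson correlations between feature relative
abundances, after the standard prevalence/abundance filter (mean relative
abundance above 0.01% and presence in at least 25% of samples), keeping
edges with |r| > 0.7 and P < .01.  Node roles follow the within-module
degree z-score (Zi) / among-module connectivity (Pi) scheme with the
2.5 / 0.62 thresholds; "network hubs" are the top 5% of nodes by the mean
of z-scored degree and betweenness centrality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .core import CommunityTable

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_network(table: CommunityTable, prevalence_min: float = 0.25,
                  abundance_min: float = 1e-4, r_min: float = 0.7,
                  p_max: float = 0.01, positive_only: bool = False,
                  bh_correct: bool = False) -> nx.Graph:
    """Correlation network on filtered relative abundances.

    Defaults mirror the standard co-occurrence recipe: mean relative
    abundance > 0.01% (1e-4 as a proportion), prevalence >= 25%,
    |r| > 0.7, raw P < .01 (``bh_correct=True`` switches to
    Benjamini-Hochberg adjusted P; ``positive_only`` keeps r > r_min
    edges only).
    """
    if table.n_samples < 10:
        raise ValueError("network construction needs at least 10 samples")
    counts = table.counts.astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_abund = rel.mean(axis=0)
    prevalence = (counts > 0).mean(axis=0)
    keep = (mean_abund > abundance_min) & (prevalence >= prevalence_min)
    if keep.sum() < 3:
        raise ValueError(
            f"only {int(keep.sum())} features pass the abundance/prevalence "
            "filters; need at least 3"
        )
    feats = [f for f, k in zip(table.feature_ids, keep) if k]
    x = rel[:, keep]
    n = x.shape[0]

    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    iu = np.triu_indices(len(feats), k=1)
    pvals = p[iu]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
    rvals = r[iu]
    strong = rvals > r_min if positive_only else np.abs(rvals) > r_min
    mask = strong & (pvals < p_max)

    g = nx.Graph()
    g.graph.update(
        prevalence_min=prevalence_min, abundance_min=abundance_min,
        r_min=r_min, p_max=p_max, positive_only=positive_only,
        bh_correct=bh_correct, n_samples=n,
    )
    for f, a in zip(feats, mean_abund[keep]):
        g.add_node(f, mean_abundance=float(a))
    for i, j, rv, pv, m in zip(iu[0], iu[1], rvals, pvals, mask):
        if m:
            g.add_edge(feats[i], feats[j], r=float(rv), p=float(pv),
                       sign=1 if rv > 0 else -1)
    return g


# ---------------------------------------------------------------------------
# Modules and roles
# ---------------------------------------------------------------------------

def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Greedy modularity-maximizing partition; module ids by size rank.

    Deterministic (the greedy agglomeration has no randomness; ``seed`` is
    accepted for interface symmetry).  Module assignments are also stored
    as the ``module`` node attribute.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("cannot detect modules on an edgeless graph")
    comms = nx.community.greedy_modularity_communities(graph)
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))))
    assignment = {}
    for mid, comm in enumerate(comms):
        for node in comm:
            assignment[node] = mid
    nx.set_node_attributes(graph, assignment, "module")
    return assignment


def zi_pi(graph: nx.Graph, modules: dict | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi standardizes a node's within-module degree against its module
    (population SD; modules with zero SD get Zi = 0, logged).  Pi = 1 -
    sum_s (k_is/k_i)^2 over modules s.  Roles use the 2.5 / 0.62
    thresholds: module hub (Zi > 2.5, Pi < 0.62), connector (Zi <= 2.5,
    Pi > 0.62), network hub (both exceeded), else peripheral.
    """
    if modules is None:
        modules = nx.get_node_attributes(graph, "module")
        if len(modules) != graph.number_of_nodes():
            raise ValueError("module assignment missing; run detect_modules")
    nodes = list(graph.nodes)
    within = {u: 0 for u in nodes}
    permod = {u: {} for u in nodes}
    for u, v in graph.edges:
        mu, mv = modules[u], modules[v]
        if mu == mv:
            within[u] += 1
            within[v] += 1
        permod[u][mv] = permod[u].get(mv, 0) + 1
        permod[v][mu] = permod[v].get(mu, 0) + 1

    zi = {}
    for mid in set(modules.values()):
        members = [u for u in nodes if modules[u] == mid]
        kin = np.array([within[u] for u in members], dtype=float)
        sd = kin.std()
        if sd == 0:
            logger.warning("zi_pi: module %s has zero within-degree SD; Zi=0", mid)
            for u in members:
                zi[u] = 0.0
        else:
            mean = kin.mean()
            for u, k in zip(members, kin):
                zi[u] = (k - mean) / sd

    rows = []
    for u in nodes:
        k = graph.degree(u)
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((ks / k) ** 2 for ks in permod[u].values())
        z = zi[u]
        if z > ZI_THRESHOLD and pi > PI_THRESHOLD:
            role = "network_hub"
        elif z > ZI_THRESHOLD:
            role = "module_hub"
        elif pi > PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": u, "module": modules[u], "degree": k,
                     "within_degree": within[u], "zi": z, "pi": pi,
                     "role": role})
    df = pd.DataFrame(rows).set_index("node")
    for col in ("zi", "pi", "role"):
        nx.set_node_attributes(graph, df[col].to_dict(), col)
    return df


def _hub_scores(graph: nx.Graph) -> pd.Series:
    nodes = list(graph.nodes)
    deg = np.array([graph.degree(u) for u in nodes], dtype=float)
    btw_map = nx.betweenness_centrality(graph)
    btw = np.array([btw_map[u] for u in nodes], dtype=float)

    def zscore(x):
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd

    score = (zscore(deg) + zscore(btw)) / 2.0
    return pd.Series(score, index=nodes, name="hub_score")


def find_network_hubs(graph: nx.Graph, top_frac: float = 0.05) -> list:
    """Top fraction (ceiling) of nodes by mean z-scored degree and
    betweenness centrality."""
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    scores = _hub_scores(graph)
    k = math.ceil(top_frac * len(scores))
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    ranked = ranked.loc[sorted(ranked.index, key=str)].sort_values(
        ascending=False, kind="mergesort")
    return list(ranked.index[:k])


def hub_nodes(graph: nx.Graph, roles: pd.DataFrame | None = None,
              top_frac: float = 0.05) -> set:
    """Union of ranking-based network hubs and Zi/Pi module hubs."""
    if roles is None:
        roles = zi_pi(graph)
    module_hubs = set(roles.index[roles["role"].isin(["module_hub", "network_hub"])])
    return module_hubs | set(find_network_hubs(graph, top_frac))


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    removal: str
    f_grid: np.ndarray
    robustness: np.ndarray
    robustness_auc: float
    vulnerability: float
    natural_connectivity: np.ndarray     # value after removing 0..k nodes
    nodes_removed: list = field(default_factory=list)


def natural_connectivity(graph: nx.Graph) -> float:
    """ln((1/n) sum_i e^{lambda_i}) over adjacency eigenvalues."""
    n = graph.number_of_nodes()
    if n == 0:
        return float("nan")
    lam = np.linalg.eigvalsh(nx.to_numpy_array(graph))
    return float(logsumexp(lam) - np.log(n))


def vulnerability(graph: nx.Graph) -> float:
    """max_i (Eff - Eff_-i)/Eff with Eff the global efficiency of the
    largest connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comp = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(comp).copy()
    eff = nx.global_efficiency(sub)
    if eff == 0:
        return 0.0
    worst = 0.0
    for u in list(sub.nodes):
        reduced = sub.copy()
        reduced.remove_node(u)
        drop = (eff - nx.global_efficiency(reduced)) / eff
        worst = max(worst, drop)
    return float(worst)


def _robustness_after(graph: nx.Graph, order: list, n_remove: int) -> float:
    remaining = graph.copy()
    remaining.remove_nodes_from(order[:n_remove])
    if remaining.number_of_nodes() == 0:
        return 0.0
    linked = sum(1 for _, d in remaining.degree if d >= 1)
    return linked / remaining.number_of_nodes()


def stability(graph: nx.Graph, removal: str = "random",
              f_grid=None, n_rep: int = 20,
              seed: int | None = None) -> StabilityReport:
    """Robustness/vulnerability/natural-connectivity under node removal.

    Robustness at fraction f is the fraction of remaining nodes that keep
    at least one link after removing round(f*n) nodes — averaged over
    ``n_rep`` random orders, or from the single hub-score order when
    ``removal='hubs'``.  The natural-connectivity curve tracks the same
    removal order step by step.
    """
    if removal not in ("random", "hubs"):
        raise ValueError(f"unknown removal scheme {removal!r}")
    if f_grid is None:
        f_grid = np.arange(0.05, 0.85, 0.05)
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(f_grid >= 1.0) or np.any(f_grid < 0.0):
        raise ValueError("removal fractions must lie in [0, 1)")
    if not any(len(c) > 1 for c in nx.connected_components(graph)):
        raise ValueError("graph has no connected component with an edge")
    n = graph.number_of_nodes()
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)

    if removal == "hubs":
        scores = _hub_scores(graph)
        orders = [list(scores.sort_values(ascending=False, kind="mergesort").index)]
    else:
        orders = [list(rng.permutation(nodes)) for _ in range(n_rep)]

    robustness = np.zeros(f_grid.size)
    for order in orders:
        for k, f in enumerate(f_grid):
            robustness[k] += _robustness_after(graph, order, round(f * n))
    robustness /= len(orders)

    nc_order = orders[0]
    max_remove = round(f_grid.max() * n)
    nc = np.empty(max_remove + 1)
    cur = graph.copy()
    nc[0] = natural_connectivity(cur)
    for k in range(1, max_remove + 1):
        cur.remove_node(nc_order[k - 1])
        nc[k] = natural_connectivity(cur)

    return StabilityReport(
        removal=removal,
        f_grid=f_grid,
        robustness=robustness,
        robustness_auc=float(np.trapezoid(robustness, f_grid)),
        vulnerability=vulnerability(graph),
        natural_connectivity=nc,
        nodes_removed=nc_order[:max_remove],
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "r": d.get("r"), "p": d.get("p"),
         "sign": d.get("sign")}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(
        path, sep="\t", index=False)


def write_node_attributes(graph: nx.Graph, path) -> None:
    rows = []
    for u, d in graph.nodes(data=True):
        rows.append({"node": u, **{k: d.get(k) for k in
                     ("mean_abundance", "module", "zi", "pi", "role")}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
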