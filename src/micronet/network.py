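"""Spearman co-occurrence networks: RMT threshold, topology, nulls, matching.

The similarity threshold is chosen by random-matrix theory: as the cutoff
rises, the nearest-neighbour spacing distribution (NNSD) of the unfolded
eigenvalue spectrum transitions from Wigner–Dyson (correlated noise) to
Poisson (real, sparse modular structure); the chosen threshold is the
smallest cutoff whose NNSD is consistent with the exponential (Poisson) law.
Random nulls preserve the degree sequence by edge rewiring, reproducing the
empirical-versus-random topology contrast used to argue non-random assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from scipy.interpolate import UnivariateSpline

from micronet.core import ValidationError


def spearman_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected Spearman correlation between columns (OTUs).

    Returns (rho, constant_mask): columns with zero variance get rho 0
    against everything (diagonal stays 1) and are flagged in the mask.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 4:
        raise ValidationError("Spearman network needs at least 4 samples")
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    safe = ranks.copy()
    safe[:, constant] = np.arange(x.shape[0])[:, None]  # placeholder, zeroed below
    rho = np.corrcoef(safe, rowvar=False)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho, constant


# ---------------------------------------------------------------------------
# random matrix theory threshold selection


def _unfolded_spacings(eigvals: np.ndarray) -> np.ndarray:
    """Nearest-neighbour spacings of the spline-unfolded spectrum.

    Duplicate eigenvalues (mass points from isolated nodes) are collapsed
    before unfolding, the standard treatment for sparse thresholded matrices.
    """
    ev = np.sort(eigvals)
    keep = [ev[0]]
    for v in ev[1:]:
        if v - keep[-1] > 1e-8:
            keep.append(v)
    ev = np.asarray(keep)
    n = len(ev)
    if n < 20:
        raise ValidationError("too few distinct eigenvalues to unfold")
    cumulative = np.arange(1, n + 1, dtype=float)
    k = min(3, n - 1)
    spline = UnivariateSpline(ev, cumulative, k=k, s=n)
    unfolded = spline(ev)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    return spacings / spacings.mean()


def nnsd_poisson_pvalue(spacings: np.ndarray) -> float:
    """Chi-square goodness of fit of spacings against the exponential law.

    Uses sqrt(n) equal-probability bins of Exp(1); large p means the NNSD is
    Poisson-like (uncorrelated eigenvalues, i.e. real sparse structure).
    """
    n = len(spacings)
    n_bins = max(int(np.sqrt(n)), 3)
    edges = np.append(-np.log(1.0 - np.arange(n_bins) / n_bins), np.inf)
    observed, _ = np.histogram(spacings, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, n_bins - 1))


def rmt_threshold_scan(
    corr: np.ndarray,
    s_min: float = 0.5,
    s_max: float = 0.95,
    step: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Scan candidate cutoffs; pick the smallest with a Poisson-like NNSD.

    For each candidate s the correlation matrix is hard-thresholded
    (|rho| < s zeroed, unit diagonal), its spectrum unfolded, and the NNSD
    tested against the exponential distribution. Returns the chosen
    threshold and the per-candidate diagnostics; if no candidate passes the
    scan returns s_max with a warning flag.
    """
    if corr.shape[0] < 20:
        raise ValidationError("RMT scan needs a matrix of at least 20 OTUs")
    scan = []
    chosen = None
    candidates = np.arange(s_min, s_max + step / 2, step)
    for s in candidates:
        a = np.where(np.abs(corr) >= s, corr, 0.0)
        np.fill_diagonal(a, 1.0)
        eigvals = np.linalg.eigvalsh(a)
        try:
            spacings = _unfolded_spacings(eigvals)
            p = nnsd_poisson_pvalue(spacings)
        except ValidationError:
            p = float("nan")
        n_edges = int((np.abs(np.triu(a, 1)) > 0).sum())
        scan.append({"s": round(float(s), 6), "poisson_p": p, "n_edges": n_edges})
        if chosen is None and not np.isnan(p) and p > alpha:
            chosen = float(s)
    return {
        "threshold": chosen if chosen is not None else float(s_max),
        "converged": chosen is not None,
        "scan": scan,
    }


# ---------------------------------------------------------------------------
# graph construction and topology


@dataclass(frozen=True)
class CorrelationNetwork:
    graph: nx.Graph
    threshold: float
    module_of: dict[str, int]


def build_network(
    corr: np.ndarray,
    threshold: float,
    node_ids: Sequence[str],
    taxonomy: Mapping[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a signed co-occurrence network.

    Edges keep their Spearman rho and sign; isolated nodes are dropped;
    modules come from greedy (CNM) modularity maximization on the unsigned
    graph.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    n = corr.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            rho = corr[i, j]
            if abs(rho) >= threshold:
                g.add_edge(
                    node_ids[i],
                    node_ids[j],
                    rho=float(rho),
                    sign=1 if rho > 0 else -1,
                )
    if g.number_of_edges() == 0:
        raise ValidationError(
            f"no edge survives |rho| >= {threshold}; lower the threshold"
        )
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    module_of = {}
    for mid, comm in enumerate(communities):
        for node in comm:
            module_of[node] = mid
    nx.set_node_attributes(g, module_of, "module")
    if taxonomy:
        for node in g.nodes:
            if node in taxonomy:
                g.nodes[node]["taxonomy"] = ";".join(taxonomy[node])
    return CorrelationNetwork(graph=g, threshold=float(threshold), module_of=module_of)


@dataclass(frozen=True)
class NetworkTopology:
    n_nodes: int
    n_edges: int
    pct_positive: float
    pct_negative: float
    avg_degree: float
    avg_clustering: float
    n_modules: int
    modularity: float
    avg_path_distance: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _mean_shortest_path(g: nx.Graph) -> float:
    """Mean shortest-path length over connected pairs only."""
    total, pairs = 0.0, 0
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        if len(sub) < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    if pairs == 0:
        return float("nan")
    return total / pairs  # each unordered pair counted twice, cancels


def topology(network: CorrelationNetwork) -> NetworkTopology:
    """Topology summary: N, E, sign percentages, avgK, avgCC, modules, M, GD."""
    g = network.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValidationError("empty network")
    signs = [d.get("sign", 1) for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    partition: dict[int, set] = {}
    for node, mid in network.module_of.items():
        partition.setdefault(mid, set()).add(node)
    communities = list(partition.values())
    mod = nx.algorithms.community.modularity(g, communities) if communities else 0.0
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        pct_positive=100.0 * n_pos / e if e else 0.0,
        pct_negative=100.0 * (e - n_pos) / e if e else 0.0,
        avg_degree=2.0 * e / n,
        avg_clustering=float(nx.average_clustering(g)),
        n_modules=len(communities),
        modularity=float(mod),
        avg_path_distance=_mean_shortest_path(g),
    )


@dataclass(frozen=True)
class RandomNullSummary:
    metrics: dict[str, dict[str, float]]  # metric -> mean, sd, empirical, z
    n_random: int
    values: dict[str, list[float]]  # per-replicate metric values


def random_null(
    network: CorrelationNetwork, n_random: int = 100, seed: int = 0
) -> RandomNullSummary:
    """Degree-preserving rewiring null for avgCC, modularity and GD.

    Each replicate applies >= 10 x E double-edge swaps, re-detects modules,
    and recomputes the metrics; reported as mean ± sd with empirical-vs-null
    z-scores. The degree sequence of every replicate equals the original.
    """
    if n_random < 10:
        raise ValidationError("use at least 10 random networks")
    g = network.graph
    e = g.number_of_edges()
    if e < 2:
        raise ValidationError("graph too small to rewire")
    emp = topology(network)
    rng = np.random.default_rng(seed)
    records = {"avg_clustering": [], "modularity": [], "avg_path_distance": []}
    for _ in range(n_random):
        r = g.copy()
        try:
            nx.double_edge_swap(
                r,
                nswap=10 * e,
                max_tries=200 * e,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # max_tries hit; r is still a valid partial rewiring
        comms = nx.algorithms.community.greedy_modularity_communities(r)
        rnet = CorrelationNetwork(
            graph=r,
            threshold=network.threshold,
            module_of={n_: i for i, c in enumerate(comms) for n_ in c},
        )
        t = topology(rnet)
        records["avg_clustering"].append(t.avg_clustering)
        records["modularity"].append(t.modularity)
        records["avg_path_distance"].append(t.avg_path_distance)
    out: dict[str, dict[str, float]] = {}
    for metric, values in records.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        empirical = float(getattr(emp, metric))
        z = (empirical - mean) / sd if sd > 0 else float("inf")
        out[metric] = {"mean": mean, "sd": sd, "empirical": empirical, "z": float(z)}
    return RandomNullSummary(metrics=out, n_random=n_random, values=records)


# ---------------------------------------------------------------------------
# cross-network module matching


@dataclass(frozen=True)
class ModuleMatch:
    pairs: list[dict]
    n_pairs: int
    n_matched: int
    clusters: list[set[tuple[int, int]]]
    singletons: list[tuple[int, int]]


def match_modules(
    networks: Sequence[CorrelationNetwork],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> ModuleMatch:
    """Fisher-exact module matching across networks over a shared universe.

    Every cross-network module pair is tested with a one-sided 2x2 Fisher
    exact test on membership overlap; pairs with p < alpha are linked, and
    clusters are the connected components of the resulting similarity graph.
    Modules in no significant pair are singletons.
    """
    if len(networks) < 2:
        raise ValidationError("module matching needs >= 2 networks")
    universe_set = set(universe)
    n_u = len(universe_set)
    modules: list[tuple[tuple[int, int], set[str]]] = []
    for ni, net in enumerate(networks):
        bymod: dict[int, set[str]] = {}
        for node, mid in net.module_of.items():
            if node in universe_set:
                bymod.setdefault(mid, set()).add(node)
        for mid, members in sorted(bymod.items()):
            modules.append(((ni, mid), members))
    pairs = []
    sim = nx.Graph()
    sim.add_nodes_from(key for key, _ in modules)
    for i, (key_a, a) in enumerate(modules):
        for key_b, b in modules[i + 1:]:
            if key_a[0] == key_b[0]:
                continue  # same network
            overlap = len(a & b)
            table = [
                [overlap, len(a) - overlap],
                [len(b) - overlap, n_u - len(a | b)],
            ]
            _, p = stats.fisher_exact(table, alternative="greater")
            matched = p < alpha
            pairs.append(
                {"a": key_a, "b": key_b, "overlap": overlap, "p": float(p),
                 "matched": bool(matched)}
            )
            if matched:
                sim.add_edge(key_a, key_b)
    clusters = [set(c) for c in nx.connected_components(sim) if len(c) > 1]
    singletons = [key for key, _ in modules if sim.degree(key) == 0]
    return ModuleMatch(
        pairs=pairs,
        n_pairs=len(pairs),
        n_matched=sum(1 for p in pairs if p["matched"]),
        clusters=clusters,
        singletons=singletons,
    )
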