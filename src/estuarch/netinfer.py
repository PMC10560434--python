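"""Constraint-based direct co-occurrence networks and node topology.

Marginal correlation networks on sequencing counts are riddled with
indirect edges: two taxa tracking the same third taxon, or the same
environmental gradient, correlate without interacting.  This module
infers *direct* association networks in the spirit of local-to-global
learning: counts are clr-transformed (centered log-ratio, the standard
compositional transform), environmental covariates are z-scored and
entered as ordinary nodes, candidate edges come from pairwise
correlation tests, and an edge is removed whenever some conditioning set
of up to ``max_k`` other measured variables renders the pair
conditionally independent (Fisher-z test on the partial correlation at
level ``alpha``).  Surviving edges are considered direct; taxon-env
edges are kept and reported separately so environmental drivers are
visible rather than confounding.

Downstream topology: greedy-modularity module detection, within-module
connectivity Zi and among-module connectivity (participation
coefficient) Pi, and the four-way node-role classification at the
conventional thresholds Zi = 2.5 and Pi = 0.62 (peripherals, connectors,
module hubs, network hubs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from estuarch.tables import FeatureTable, TaxonomyMap


@dataclass(frozen=True)
class NetworkConfig:
    """Settings of the direct-association inference.

    alpha:
        Significance level of the (partial) correlation tests; edges must
        stay significant under every admissible conditioning set.
    n_obs_min:
        Minimum number of samples in which both taxa of a pair are
        nonzero for the pair to be testable; sparser pairs get no edge.
    max_k:
        Largest conditioning-set size searched during pruning.
    env_names:
        Environmental covariates entered as nodes (no missing values
        allowed).
    pseudocount:
        Added to counts before the clr transform.
    and_rule:
        Symmetrize neighborhoods with the conservative AND rule; the OR
        rule keeps an edge supported from either endpoint.
    """

    alpha: float = 0.001
    n_obs_min: int = 10
    max_k: int = 3
    env_names: tuple[str, ...] = ()
    pseudocount: float = 1.0
    and_rule: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_k < 0:
            raise ValueError("max_k must be >= 0")


@dataclass
class AssociationNetwork:
    """Signed weighted undirected graph over taxon and env nodes."""

    graph: nx.Graph
    config: NetworkConfig
    modules: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, attrs in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, attrs["weight"], attrs["sign"], attrs.get("edge_class", "")))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sign", "edge_class"]).sort_values(
            ["node_a", "node_b"]
        ).reset_index(drop=True)

    def node_frame(self) -> pd.DataFrame:
        rows = []
        for node, attrs in sorted(self.graph.nodes(data=True)):
            rows.append(
                (
                    node,
                    attrs.get("kind", "taxon"),
                    attrs.get("domain", ""),
                    self.modules.get(node, -1),
                    attrs.get("Zi", np.nan),
                    attrs.get("Pi", np.nan),
                    attrs.get("role", ""),
                    self.graph.degree(node),
                )
            )
        return pd.DataFrame(
            rows, columns=["id", "kind", "domain", "module", "Zi", "Pi", "role", "degree"]
        )

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for node, mod in self.modules.items():
            g.nodes[node]["module"] = mod
        nx.write_graphml(g, path)


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> FeatureTable:
    """Centered log-ratio transform: log((c + pc) / gmean(c + pc)) per
    sample.  Rows sum to zero; the transform removes the per-sample
    total-count constraint that induces spurious negative correlations."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if table.normalized not in ("raw", "rarefied"):
        raise ValueError("clr_transform expects raw counts")
    x = table.values.astype(float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return FeatureTable(
        pd.DataFrame(clr, index=table.data.index, columns=table.data.columns), "clr"
    )


# ---------------------------------------------------------------------------
# conditional-independence machinery
# ---------------------------------------------------------------------------

def _fisher_z_p(r: float, n: int, k: int) -> float:
    """Two-sided Fisher-z p-value for a (partial) correlation ``r`` on
    ``n`` samples conditioning on ``k`` variables."""
    df = n - k - 3
    if df <= 0:
        return 1.0
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.sqrt(df) * np.arctanh(r)
    return float(2.0 * stats.norm.sf(abs(z)))


def _partial_corr(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0:
        return 0.0
    return float(-prec[0, 1] / denom)


def infer_direct_network(
    table: FeatureTable,
    env_table: pd.DataFrame | None = None,
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
    taxonomy: TaxonomyMap | None = None,
) -> AssociationNetwork:
    """Infer a direct (conditional-independence-filtered) association
    network over taxa and environmental covariates.

    The candidate graph links every pair whose pairwise correlation (clr
    values for taxa, z-scores for env) is significant at ``alpha``; a
    taxon-taxon pair additionally needs >= ``n_obs_min`` co-nonzero
    samples to be testable.  Candidate edges are then pruned level by
    level (PC-stable schedule): at conditioning size k each surviving
    edge (i, j) is tested against every subset S of size k drawn from
    the current neighborhoods of i and of j; one insignificant partial
    correlation removes the edge.  Pruning at each level uses the
    adjacency frozen at the start of the level, so the result does not
    depend on edge visiting order.  Edge weight and sign come from the
    pairwise clr correlation.

    ``seed`` only fixes tie-break ordering (nodes are processed in
    sorted order, making the procedure deterministic outright).
    """
    if table.normalized == "clr":
        clr = table
    else:
        clr = clr_transform(table, config.pseudocount)
    n = clr.n_samples
    if n < config.n_obs_min:
        raise ValueError(
            f"{n} samples < n_obs_min={config.n_obs_min}; too few observations"
        )

    taxa = list(clr.feature_ids)
    env_names = list(config.env_names)
    if env_names:
        if env_table is None:
            raise ValueError("env_names configured but no env_table given")
        missing_cols = [c for c in env_names if c not in env_table.columns]
        if missing_cols:
            raise ValueError(f"env_table missing columns: {missing_cols}")
        env = env_table.loc[clr.sample_ids, env_names]
        if env.isna().any().any():
            bad = env.columns[env.isna().any()].tolist()
            raise ValueError(
                f"missing environmental values are not supported: {bad}"
            )
        env_z = (env - env.mean()) / env.std(ddof=1).replace(0, 1.0)
        data = np.column_stack([clr.values, env_z.to_numpy(dtype=float)])
    else:
        data = clr.values

    names = taxa + env_names
    p_vars = len(names)
    corr = np.corrcoef(data, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)

    raw_counts = table.values if table.normalized != "clr" else None
    n_taxa = len(taxa)

    # level 0: pairwise tests (+ co-occurrence requirement for taxon pairs)
    adj: dict[int, set[int]] = {i: set() for i in range(p_vars)}
    for i in range(p_vars):
        for j in range(i + 1, p_vars):
            if raw_counts is not None and i < n_taxa and j < n_taxa:
                co = int(np.sum((raw_counts[:, i] > 0) & (raw_counts[:, j] > 0)))
                if co < config.n_obs_min:
                    continue
            if _fisher_z_p(corr[i, j], n, 0) < config.alpha:
                adj[i].add(j)
                adj[j].add(i)

    # levels 1..max_k: PC-stable pruning
    for k in range(1, config.max_k + 1):
        frozen = {i: tuple(sorted(adj[i])) for i in adj}
        edges = [(i, j) for i in range(p_vars) for j in frozen[i] if j > i]
        for i, j in edges:
            removed = False
            # AND rule: a separating set found from either endpoint's
            # neighborhood removes the edge (conservative); the OR rule
            # only searches the first endpoint's neighborhood
            pools = [tuple(x for x in frozen[i] if x != j)]
            if config.and_rule:
                pools.append(tuple(x for x in frozen[j] if x != i))
            seen: set[tuple[int, ...]] = set()
            for pool in pools:
                if len(pool) < k:
                    continue
                for S in itertools.combinations(pool, k):
                    if S in seen:
                        continue
                    seen.add(S)
                    r = _partial_corr(corr, i, j, S)
                    if _fisher_z_p(r, n, k) >= config.alpha:
                        removed = True
                        break
                if removed:
                    break
            if removed:
                adj[i].discard(j)
                adj[j].discard(i)

    graph = nx.Graph()
    mean_rel = None
    if raw_counts is not None:
        totals = raw_counts.sum(axis=1, keepdims=True).astype(float)
        totals[totals == 0] = 1.0
        mean_rel = (raw_counts / totals).mean(axis=0)
    arch_flag = taxonomy.is_archaeon if taxonomy is not None else None
    phyto_flag = taxonomy.is_phytoplankton if taxonomy is not None else None
    bact_flag = taxonomy.is_bacterium if taxonomy is not None else None
    for idx, name in enumerate(names):
        if idx < n_taxa:
            domain = ""
            if taxonomy is not None and name in taxonomy.df.index:
                if bool(arch_flag.loc[name]):
                    domain = "archaea"
                elif bool(phyto_flag.loc[name]):
                    domain = "phytoplankton"
                elif bool(bact_flag.loc[name]):
                    domain = "bacteria"
            graph.add_node(
                name,
                kind="taxon",
                domain=domain,
                mean_rel_abundance=float(mean_rel[idx]) if mean_rel is not None else np.nan,
            )
        else:
            graph.add_node(name, kind="env", domain="", mean_rel_abundance=np.nan)
    for i in range(p_vars):
        for j in adj[i]:
            if j > i:
                w = float(corr[i, j])
                graph.add_edge(
                    names[i],
                    names[j],
                    weight=w,
                    abs_weight=abs(w),
                    sign="+" if w >= 0 else "-",
                )
    _annotate_edge_classes(graph, taxonomy)
    return AssociationNetwork(graph=graph, config=config)


def _annotate_edge_classes(graph: nx.Graph, taxonomy: TaxonomyMap | None) -> None:
    for u, v, attrs in graph.edges(data=True):
        ku = graph.nodes[u].get("kind", "taxon")
        kv = graph.nodes[v].get("kind", "taxon")
        if "env" in (ku, kv):
            attrs["edge_class"] = "taxon-env"
            continue
        du = graph.nodes[u].get("domain", "")
        dv = graph.nodes[v].get("domain", "")
        pair = {du, dv}
        if pair == {"archaea"}:
            attrs["edge_class"] = "archaea-archaea"
        elif pair == {"archaea", "bacteria"}:
            attrs["edge_class"] = "archaea-bacteria"
        elif pair == {"archaea", "phytoplankton"}:
            attrs["edge_class"] = "archaea-phytoplankton"
        else:
            attrs["edge_class"] = "other"


# ---------------------------------------------------------------------------
# modules, Zi/Pi, roles
# ---------------------------------------------------------------------------

def detect_modules(network: AssociationNetwork, seed: int = 0) -> dict[str, int]:
    """Non-overlapping modules by greedy modularity maximization on
    absolute edge weights.  Deterministic: communities are relabelled by
    their lowest node id, and isolated nodes form singleton modules."""
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        comms: list[set[str]] = [{n} for n in g.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g, weight="abs_weight")]
    comms.sort(key=lambda c: min(c))
    modules = {node: i for i, comm in enumerate(comms) for node in comm}
    network.modules = modules
    return modules


def zi_pi(
    network: AssociationNetwork, modules: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Within-module connectivity Zi and participation coefficient Pi.

    With k_is the number of edges from node i to module s (unweighted),
    k_i its total degree and s_i its own module:

        Zi = (k_{i,s_i} - mean_{j in s_i} k_{j,s_j}) / sd_{j in s_i}
        Pi = 1 - sum_s (k_is / k_i)^2

    Zi := 0 when the module's sd is zero, Pi := 0 for isolated nodes.
    """
    g = network.graph
    modules = dict(modules) if modules is not None else network.modules
    missing = [v for v in g.nodes if v not in modules]
    if missing:
        raise KeyError(f"nodes without module assignment: {missing[:10]}")

    within: dict[str, int] = {}
    pi: dict[str, float] = {}
    for node in g.nodes:
        k_total = g.degree(node)
        per_mod: dict[int, int] = {}
        for nb in g.neighbors(node):
            per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
        within[node] = per_mod.get(modules[node], 0)
        if k_total == 0:
            pi[node] = 0.0
        else:
            pi[node] = 1.0 - sum((c / k_total) ** 2 for c in per_mod.values())

    zi: dict[str, float] = {}
    by_module: dict[int, list[str]] = {}
    for node, mod in modules.items():
        if node in g.nodes:
            by_module.setdefault(mod, []).append(node)
    for mod, members in by_module.items():
        ks = np.array([within[m] for m in members], dtype=float)
        mu, sd = ks.mean(), ks.std(ddof=0)
        for m in members:
            zi[m] = 0.0 if sd == 0 else (within[m] - mu) / sd

    df = pd.DataFrame(
        {
            "id": sorted(g.nodes),
        }
    )
    df["module"] = [modules[v] for v in df["id"]]
    df["Zi"] = [zi[v] for v in df["id"]]
    df["Pi"] = [pi[v] for v in df["id"]]
    for _, row in df.iterrows():
        g.nodes[row["id"]]["Zi"] = float(row["Zi"])
        g.nodes[row["id"]]["Pi"] = float(row["Pi"])
    return df.set_index("id")


def classify_roles(zipi: pd.DataFrame) -> pd.Series:
    """Four-way topological role per node from (Zi, Pi).

    peripherals: Zi <= 2.5 and Pi <= 0.62; connectors: Zi <= 2.5 and
    Pi > 0.62; module hubs: Zi > 2.5 and Pi <= 0.62; network hubs:
    Zi > 2.5 and Pi > 0.62.  Both boundaries are inclusive on the
    peripheral side."""
    roles = []
    for _, row in zipi.iterrows():
        hub = row["Zi"] > 2.5
        conn = row["Pi"] > 0.62
        if hub and conn:
            roles.append("network_hub")
        elif hub:
            roles.append("module_hub")
        elif conn:
            roles.append("connector")
        else:
            roles.append("peripheral")
    return pd.Series(roles, index=zipi.index, name="role")


def summarize_cross_domain(
    network: AssociationNetwork, taxonomy: TaxonomyMap
) -> dict[str, pd.DataFrame]:
    """Edge-class and per-genus association summaries.

    Returns ``{"edge_classes": ..., "archaeal_genera": ...}``:
    per edge class (archaea-archaea, archaea-bacteria,
    archaea-phytoplankton, taxon-env, other) the edge count and percent
    of positive edges, plus overall node/edge counts; per archaeal genus
    its total degree and cross-domain degree (edges to non-archaeal
    taxa), for abundance-vs-connectivity comparisons.
    """
    g = network.graph
    _annotate_edge_classes(g, taxonomy)

    classes = ["archaea-archaea", "archaea-bacteria", "archaea-phytoplankton", "taxon-env", "other"]
    counts = {c: 0 for c in classes}
    positives = {c: 0 for c in classes}
    for _, _, attrs in g.edges(data=True):
        c = attrs.get("edge_class", "other")
        counts[c] += 1
        if attrs["sign"] == "+":
            positives[c] += 1
    rows = []
    for c in classes:
        pct = 100.0 * positives[c] / counts[c] if counts[c] else np.nan
        rows.append((c, counts[c], pct))
    total_edges = g.number_of_edges()
    total_pos = sum(positives.values())
    rows.append(
        ("all", total_edges, 100.0 * total_pos / total_edges if total_edges else np.nan)
    )
    edge_df = pd.DataFrame(rows, columns=["edge_class", "n_edges", "pct_positive"])
    edge_df.attrs["n_nodes"] = g.number_of_nodes()

    arch = taxonomy.is_archaeon
    genus_rows = []
    for node, attrs in g.nodes(data=True):
        if attrs.get("kind") != "taxon" or node not in taxonomy.df.index:
            continue
        if not bool(arch.loc[node]):
            continue
        genus = str(taxonomy.df.loc[node, "genus"])
        degree = g.degree(node)
        cross = sum(
            1
            for nb in g.neighbors(node)
            if g.nodes[nb].get("kind") == "taxon"
            and g.nodes[nb].get("domain") not in ("archaea", "")
        )
        genus_rows.append((genus, node, degree, cross, attrs.get("mean_rel_abundance", np.nan)))
    genus_df = pd.DataFrame(
        genus_rows, columns=["genus", "taxon_id", "degree", "cross_domain_degree", "mean_rel_abundance"]
    )
    if not genus_df.empty:
        genus_df = (
            genus_df.groupby("genus")
            .agg(
                n_taxa=("taxon_id", "count"),
                degree=("degree", "sum"),
                cross_domain_degree=("cross_domain_degree", "sum"),
                mean_rel_abundance=("mean_rel_abundance", "mean"),
            )
            .reset_index()
        )
    return {"edge_classes": edge_df, "archaeal_genera": genus_df}
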