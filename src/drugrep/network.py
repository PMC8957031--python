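"""Network-proximity drug repositioning.

The proximity of a drug signature A to a query gene set B on a gene network
is the mean, over drug genes a, of the shortest-path distance to the
nearest query gene:

    d(B, A) = (1/|A|) * sum_{a in A} min_{b in B} dist(a, b)

Significance is assessed against a degree-matched permutation null: each
replicate redraws both gene sets preserving their node-degree profiles so
that hub bias does not inflate apparent proximity, and the observed
distance is standardized to a z-score. More negative z = closer than
chance; the conventional cutoff is z < -2.33 (one-sided 0.01).

Distances are unweighted shortest paths on the undirected projection of
the input network: proximity, not causality, is being measured. A directed
mode is available for loading but scoring always projects.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import MIN_SIGNATURE_GENES, N_PERMUTATIONS, Z_CUTOFF
from .signatures import GeneSet, GeneSignature, SignatureLibrary, _upper


@dataclass
class GeneNetwork:
    """A gene network with degree and connected-component indices built on
    the undirected projection."""

    graph: nx.Graph
    digraph: nx.DiGraph | None = None
    n_self_loops_removed: int = 0
    n_duplicates_collapsed: int = 0

    def __post_init__(self):
        self.degree_index: dict[str, int] = dict(self.graph.degree())
        self.components: dict[str, int] = {}
        for cid, comp in enumerate(
            sorted(nx.connected_components(self.graph), key=lambda c: (-len(c), min(c)))
        ):
            for node in comp:
                self.components[node] = cid

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def restrict(self, genes: Iterable[str]) -> list[str]:
        """Uppercased genes present in the network, input order, deduplicated."""
        seen: list[str] = []
        have: set[str] = set()
        for g in genes:
            u = str(g).upper()
            if u in self.graph and u not in have:
                seen.append(u)
                have.add(u)
        return seen

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], directed: bool = False) -> "GeneNetwork":
        """Build from (source, target[, weight]) tuples; symbols are
        uppercased, self-loops dropped (counted), duplicates collapsed."""
        digraph = nx.DiGraph() if directed else None
        graph = nx.Graph()
        loops = 0
        dups = 0
        for edge in edges:
            src, tgt = str(edge[0]).strip().upper(), str(edge[1]).strip().upper()
            weight = float(edge[2]) if len(edge) > 2 and edge[2] is not None else 1.0
            if not src or not tgt:
                raise ValueError(f"empty symbol in edge {edge!r}")
            if src == tgt:
                loops += 1
                continue
            if graph.has_edge(src, tgt):
                dups += 1
            graph.add_edge(src, tgt, weight=weight)
            if digraph is not None:
                digraph.add_edge(src, tgt, weight=weight)
        if graph.number_of_edges() == 0:
            raise ValueError("edge list is empty")
        return cls(graph=graph, digraph=digraph,
                   n_self_loops_removed=loops, n_duplicates_collapsed=dups)


def load_network(path: str | Path, directed: bool = False) -> GeneNetwork:
    """Load a 2-3 column (source, target[, weight]) edge-list TSV.

    Lines starting with ``#`` and a recognizable header row are skipped;
    malformed rows raise with their line number.
    """
    path = Path(path)
    edges: list[tuple] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) < 2 or len(parts) > 3 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {raw!r}")
        if lineno == 1 and parts[0].lower() in {"source", "from", "node1"}:
            continue
        if len(parts) == 3:
            try:
                weight = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            edges.append((parts[0], parts[1], weight))
        else:
            edges.append((parts[0], parts[1]))
    if not edges:
        raise ValueError(f"{path}: edge list is empty")
    return GeneNetwork.from_edges(edges, directed=directed)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    rows = sorted((u, v) if u <= v else (v, u) for u, v in net.graph.edges)
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Proximity scoring


def _multi_source_bfs(graph: nx.Graph, sources: Sequence[str]) -> dict[str, int]:
    """Unweighted shortest-path distance from the nearest source."""
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    adj = graph.adj
    while queue:
        node = queue.popleft()
        d = dist[node] + 1
        for nbr in adj[node]:
            if nbr not in dist:
                dist[nbr] = d
                queue.append(nbr)
    return dist


@dataclass
class MeanDistanceResult:
    d_obs: float
    n_drug_used: int
    n_drug_dropped: int
    n_query_used: int


def mean_min_distance(
    drug_genes,
    query_genes,
    net: GeneNetwork,
    min_drug_size: int = MIN_SIGNATURE_GENES,
) -> MeanDistanceResult:
    """Mean over drug genes of the shortest distance to the nearest query
    gene (unweighted, undirected projection).

    Drug genes with no finite path to any query gene are excluded from the
    mean and counted. ``min_drug_size`` enforces the strictly-more-than-10
    size filter; pass 0 to override.
    """
    drug = net.restrict(drug_genes)
    query = net.restrict(query_genes)
    if not drug:
        raise ValueError("no drug gene is present in the network")
    if not query:
        raise ValueError("no query gene is present in the network")
    if min_drug_size and len(drug) <= min_drug_size:
        raise ValueError(
            f"drug set has {len(drug)} genes in the network; needs more than {min_drug_size}"
        )
    dist = _multi_source_bfs(net.graph, query)
    finite = [dist[g] for g in drug if g in dist]
    dropped = len(drug) - len(finite)
    if not finite:
        raise ValueError("no drug gene is connected to the query set")
    return MeanDistanceResult(
        d_obs=float(np.mean(finite)),
        n_drug_used=len(finite),
        n_drug_dropped=dropped,
        n_query_used=len(query),
    )


def _degree_pools(net: GeneNetwork, min_pool: int = 10) -> dict[int, list[str]]:
    """Candidate node pools per degree; pools with fewer than ``min_pool``
    nodes are merged with nearest-degree pools (so the null never has to
    resample the original genes deterministically)."""
    by_degree: dict[int, list[str]] = {}
    for node in sorted(net.graph.nodes):
        by_degree.setdefault(net.degree_index[node], []).append(node)
    degrees = sorted(by_degree)
    pools: dict[int, list[str]] = {}
    for d in degrees:
        pool = list(by_degree[d])
        if len(pool) < min_pool:
            # widen symmetrically over neighboring degree values
            for other in sorted(degrees, key=lambda x: (abs(x - d), x)):
                if other == d:
                    continue
                pool.extend(by_degree[other])
                if len(pool) >= min_pool:
                    break
        if not pool:
            raise ValueError(f"no candidates for degree {d}")
        pools[d] = sorted(set(pool))
    return pools


def sample_degree_matched(
    genes: Sequence[str],
    net: GeneNetwork,
    rng: np.random.Generator,
    pools: dict[int, list[str]] | None = None,
) -> list[str]:
    """Draw a random gene set matching the degree profile of ``genes``.

    Samples are distinct within the returned set; drawing is deterministic
    under a fixed generator state.
    """
    if pools is None:
        pools = _degree_pools(net)
    chosen: list[str] = []
    used: set[str] = set()
    for gene in genes:
        pool = pools[net.degree_index[gene]]
        pick = pool[int(rng.integers(len(pool)))]
        attempts = 0
        while pick in used:
            attempts += 1
            if attempts > 1000:
                remaining = [g for g in pool if g not in used]
                if not remaining:
                    raise ValueError("degree pool exhausted during sampling")
                pick = remaining[int(rng.integers(len(remaining)))]
                break
            pick = pool[int(rng.integers(len(pool)))]
        chosen.append(pick)
        used.add(pick)
    return chosen


def degree_matched_null(
    drug_genes,
    query_genes,
    net: GeneNetwork,
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    permute_query: bool = True,
) -> np.ndarray:
    """Null sample of mean-min-distances from degree-matched redraws.

    Each replicate redraws the drug set (and by default the query set too)
    preserving the degree profile of the originals and recomputes the mean
    shortest distance. Reproducible under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drug = net.restrict(drug_genes)
    query = net.restrict(query_genes)
    if not drug or not query:
        raise ValueError("drug and query sets must intersect the network")
    pools = _degree_pools(net)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        d_perm = sample_degree_matched(drug, net, rng, pools)
        q_perm = sample_degree_matched(query, net, rng, pools) if permute_query else query
        null[i] = mean_min_distance(d_perm, q_perm, net, min_drug_size=0).d_obs
    return null


@dataclass
class ProximityResult:
    drug_id: str
    d_obs: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_drug_used: int
    n_drug_dropped: int
    n_query_used: int
    n_permutations: int
    significant: bool = False
    species: str = ""
    tissue: str = ""
    dose: str = ""
    duration: str = ""
    rank: int = 0
    percentile: float = 0.0


def proximity_z(
    drug,
    query,
    net: GeneNetwork,
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    permute_query: bool = True,
    z_cutoff: float = Z_CUTOFF,
    min_drug_size: int = MIN_SIGNATURE_GENES,
) -> ProximityResult:
    """Observed proximity, degree-matched null, z-score, and empirical p.

    ``z = (d_obs - null_mean) / null_sd`` where the null statistics come
    from the permutation sample; the empirical p uses the +1 correction
    ``(1 + #{null <= d_obs}) / (1 + n_perm)``. Significance at z < -2.33.
    """
    drug_id = drug.id if isinstance(drug, (GeneSignature, GeneSet)) else ""
    drug_genes = drug.all_genes if isinstance(drug, GeneSignature) else (
        drug.genes if isinstance(drug, GeneSet) else list(drug))
    query_genes = query.genes if isinstance(query, GeneSet) else (
        query.all_genes if isinstance(query, GeneSignature) else list(query))

    obs = mean_min_distance(drug_genes, query_genes, net, min_drug_size=min_drug_size)
    null = degree_matched_null(drug_genes, query_genes, net, n_perm=n_perm,
                               seed=seed, permute_query=permute_query)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if null_sd > 0:
        z = (obs.d_obs - null_mean) / null_sd
    else:
        z = 0.0 if obs.d_obs == null_mean else float(np.sign(obs.d_obs - null_mean) * np.inf)
    p_emp = (1 + int((null <= obs.d_obs).sum())) / (1 + n_perm)
    result = ProximityResult(
        drug_id=drug_id, d_obs=obs.d_obs, null_mean=null_mean, null_sd=null_sd,
        z=float(z), p_empirical=p_emp, n_drug_used=obs.n_drug_used,
        n_drug_dropped=obs.n_drug_dropped, n_query_used=obs.n_query_used,
        n_permutations=n_perm, significant=bool(z < z_cutoff),
    )
    if isinstance(drug, GeneSignature):
        result.species, result.tissue = drug.species, drug.tissue
        result.dose, result.duration = drug.dose or "", drug.duration or ""
    return result


def rank_drugs_by_proximity(
    library: SignatureLibrary,
    query,
    net: GeneNetwork,
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    permute_query: bool = True,
    z_cutoff: float = Z_CUTOFF,
    min_drug_size: int = MIN_SIGNATURE_GENES,
) -> list[ProximityResult]:
    """Proximity z-scores for every eligible library signature, ascending z.

    Signatures failing the size filter or absent from the network are
    skipped. Each drug gets an independent child seed derived from ``seed``
    (stable under library ordering), a rank, and a percentile = fraction of
    competitor drugs with strictly worse (higher) z; a single drug gets
    percentile 1.0 by convention.
    """
    if len(library) == 0:
        raise ValueError("signature library is empty")
    sigs = library.sorted()
    children = np.random.SeedSequence(seed).spawn(len(sigs))
    results: list[ProximityResult] = []
    for sig, child in zip(sigs, children):
        try:
            res = proximity_z(
                sig, query, net, n_perm=n_perm, seed=np.random.default_rng(child),
                permute_query=permute_query, z_cutoff=z_cutoff,
                min_drug_size=min_drug_size,
            )
        except ValueError:
            continue
        results.append(res)
    if not results:
        raise ValueError("every signature was filtered out (size or network coverage)")
    results.sort(key=lambda r: (r.z, r.drug_id, r.species, r.tissue, r.dose, r.duration))
    n = len(results)
    for i, res in enumerate(results, start=1):
        res.rank = i
        worse = sum(1 for other in results if other.z > res.z)
        res.percentile = 1.0 if n == 1 else worse / (n - 1)
    return results


def proximity_results_frame(results: list[ProximityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            [r.drug_id, r.species, r.tissue, r.dose, r.duration, r.d_obs,
             r.null_mean, r.null_sd, r.z, r.p_empirical, r.significant,
             r.n_drug_used, r.n_drug_dropped, r.n_query_used, r.rank, r.percentile]
            for r in results
        ],
        columns=["drug_id", "species", "tissue", "dose", "duration", "d_obs",
                 "null_mean", "null_sd", "z", "p_empirical", "significant",
                 "n_drug_used", "n_drug_dropped", "n_query_used", "rank", "percentile"],
    )


# ---------------------------------------------------------------------------
# First-neighbor subnetwork export


def first_neighbor_subnetwork(
    drug,
    query,
    net: GeneNetwork,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlap genes plus one-edge extensions between drug and query genes.

    Node roles: ``overlap`` (gene in both sets), ``drug_adjacent_to_query``
    (drug gene with a direct edge to a query gene), ``query_adjacent_to_drug``
    (query gene with a direct edge to a drug gene). Edges are restricted to
    pairs within the selected nodes. Tables are Cytoscape-importable TSVs.
    """
    drug_genes = drug.all_genes if isinstance(drug, GeneSignature) else (
        drug.genes if isinstance(drug, GeneSet) else list(drug))
    query_genes = query.genes if isinstance(query, GeneSet) else list(query)
    d = set(net.restrict(drug_genes))
    q = set(net.restrict(query_genes))
    overlap = d & q
    adj = net.graph.adj
    drug_adj = {g for g in d - q if any(nbr in q for nbr in adj[g])}
    query_adj = {g for g in q - d if any(nbr in d for nbr in adj[g])}
    selected = overlap | drug_adj | query_adj
    node_rows = []
    for node in sorted(selected):
        if node in overlap:
            role = "overlap"
        elif node in drug_adj:
            role = "drug_adjacent_to_query"
        else:
            role = "query_adjacent_to_drug"
        node_rows.append([node, role])
    edge_rows = sorted(
        (u, v) if u <= v else (v, u)
        for u, v in net.graph.edges(selected)
        if u in selected and v in selected
    )
    nodes = pd.DataFrame(node_rows, columns=["name", "role"])
    edges = pd.DataFrame(edge_rows, columns=["source", "target"]).drop_duplicates()
    return nodes, edges.reset_index(drop=True)
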