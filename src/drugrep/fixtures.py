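"""Seeded synthetic fixtures: networks with planted disease modules and
drug signatures of controlled proximity, plus ranked gene lists with
planted consensus genes.

These generators emulate the statistical structure the scoring assumes —
scale-free degree heterogeneity (which is what makes degree-matched nulls
non-trivial), a connected disease module, and positive drugs whose genes
concentrate in the module and its first neighbors — so every pipeline
stage is testable without external data. All generators are pure functions
of (spec, seed) and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .meta import RankedList
from .network import GeneNetwork, sample_degree_matched
from .signatures import GeneSet, GeneSignature, SignatureLibrary, write_signatures


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic benchmark.

    ``proximity_level`` is the fraction of each positive drug's genes drawn
    from the disease module or its first neighbors; the remainder (the
    noise fraction) is drawn uniformly from the rest of the network.
    ``noise_level`` is the rank-score noise sd used by the ranked-list
    generator.
    """

    n_nodes: int = 200
    attachment_degree: int = 2
    module_size: int = 30
    n_drugs: int = 20
    n_positive_drugs: int = 5
    drug_size: int = 30
    proximity_level: float = 0.8
    noise_level: float = 1.0
    seed: int = 0
    topology: str = "scale_free"

    def __post_init__(self):
        if self.n_nodes < 50:
            raise ValueError("n_nodes must be at least 50")
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if self.n_positive_drugs > self.n_drugs:
            raise ValueError("n_positive_drugs cannot exceed n_drugs")
        if self.drug_size <= 10:
            raise ValueError("drug_size must exceed 10 to pass the size filter")
        if not (0.0 <= self.proximity_level <= 1.0):
            raise ValueError("proximity_level must lie in [0, 1]")
        if self.topology not in {"scale_free", "erdos_renyi"}:
            raise ValueError(f"unknown topology {self.topology!r}")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def make_network(spec: FixtureSpec) -> GeneNetwork:
    """Connected random graph with synthetic gene symbols.

    ``scale_free`` uses preferential attachment (heavy-tailed degrees,
    always connected); ``erdos_renyi`` retries up to 10 times for a
    connected draw and then errors.
    """
    if spec.topology == "scale_free":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment_degree, seed=spec.seed)
    else:
        p = 2.0 * spec.attachment_degree / spec.n_nodes
        g = None
        for attempt in range(10):
            candidate = nx.gnp_random_graph(spec.n_nodes, p, seed=spec.seed + attempt)
            if nx.is_connected(candidate):
                g = candidate
                break
        if g is None:
            raise ValueError("could not generate a connected random graph in 10 attempts")
    edges = [(_node_name(u), _node_name(v)) for u, v in sorted(g.edges)]
    return GeneNetwork.from_edges(edges)


@dataclass
class BenchmarkFixture:
    spec: FixtureSpec
    network: GeneNetwork
    disease: GeneSet
    library: SignatureLibrary
    labels: dict[str, bool] = field(default_factory=dict)


def make_benchmark(spec: FixtureSpec) -> BenchmarkFixture:
    """Network + connected disease module + labeled drug signatures.

    Positive drugs draw ``proximity_level`` of their genes from the module
    first (spilling into its first neighbors once the module is exhausted)
    and the rest uniformly from the whole network; negative drugs are
    degree-matched redraws of the positives' degree profiles, so retrieval
    cannot ride on a degree confound.
    """
    net = make_network(spec)
    rng = np.random.default_rng(spec.seed)
    nodes = sorted(net.graph.nodes)

    # connected module: BFS from a random start until module_size nodes
    start = nodes[int(rng.integers(len(nodes)))]
    module: list[str] = []
    seen = {start}
    queue = [start]
    while queue and len(module) < spec.module_size:
        node = queue.pop(0)
        module.append(node)
        for nbr in sorted(net.graph.adj[node]):
            if nbr not in seen:
                seen.add(nbr)
                queue.append(nbr)
    if len(module) < spec.module_size:
        raise ValueError("network too small for the requested module size")
    module_set = set(module)
    disease = GeneSet(id="disease_module", genes=sorted(module))

    neighborhood = set(module)
    for gene in module:
        neighborhood.update(net.graph.adj[gene])
    pool_module = sorted(module_set)
    pool_fringe = sorted(neighborhood - module_set)

    n_prox = int(round(spec.proximity_level * spec.drug_size))
    library = SignatureLibrary()
    labels: dict[str, bool] = {}
    positives: list[list[str]] = []
    for i in range(spec.n_positive_drugs):
        n_from_module = min(n_prox, len(pool_module))
        near = list(rng.choice(pool_module, size=n_from_module, replace=False))
        if n_prox > n_from_module:
            near += list(rng.choice(pool_fringe, size=n_prox - n_from_module,
                                    replace=False))
        n_rest = spec.drug_size - len(near)
        rest_pool = sorted(set(nodes) - set(near))
        rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        genes = sorted(set(near + rest))
        positives.append(genes)
        sig_id = f"drugpos{i + 1:02d}"
        library.add(_make_signature(sig_id, genes, rng))
        labels[sig_id] = True
    for i in range(spec.n_drugs - spec.n_positive_drugs):
        template = positives[i % len(positives)] if positives else sorted(
            rng.choice(nodes, size=spec.drug_size, replace=False))
        genes = sorted(set(sample_degree_matched(template, net, rng)))
        sig_id = f"drugneg{i + 1:02d}"
        library.add(_make_signature(sig_id, genes, rng))
        labels[sig_id] = False
    return BenchmarkFixture(spec=spec, network=net, disease=disease,
                            library=library, labels=labels)


def _make_signature(sig_id: str, genes: Sequence[str], rng: np.random.Generator) -> GeneSignature:
    half = len(genes) // 2
    stats = {g: float(s) for g, s in zip(genes, rng.uniform(1e-6, 0.05, size=len(genes)))}
    return GeneSignature(
        id=sig_id, species="mouse", tissue="liver", dose="1", duration="24h",
        up_genes=tuple(genes[:half]) or tuple(genes), down_genes=tuple(genes[half:]),
        ranking_stat=stats, source="synthetic",
    )


def make_ranked_lists(
    n_datasets: int,
    n_genes: int,
    planted_genes: Sequence[str] | int,
    effect: float,
    seed: int = 0,
    direction: str = "up",
    noise_sd: float = 1.0,
) -> list[RankedList]:
    """Per-dataset normalized ranks with planted genes biased toward the top.

    Each dataset draws a Gaussian score per gene (sd ``noise_sd``) and adds
    ``effect`` to the planted genes; genes are then ranked descending.
    ``effect = 0`` yields uniform random ranks; in the large-effect limit
    the planted genes occupy the top ranks.
    """
    if effect < 0:
        raise ValueError("effect must be non-negative")
    if n_datasets < 1 or n_genes < 2:
        raise ValueError("need at least 1 dataset and 2 genes")
    roster = [_node_name(i) for i in range(n_genes)]
    if isinstance(planted_genes, int):
        if planted_genes > n_genes:
            raise ValueError("more planted genes than roster genes")
        planted = set(roster[:planted_genes])
    else:
        planted = {str(g).upper() for g in planted_genes}
        if not planted <= set(roster):
            raise ValueError("planted genes must be a subset of the roster")
    rng = np.random.default_rng(seed)
    planted_mask = np.array([g in planted for g in roster])
    lists: list[RankedList] = []
    for d in range(n_datasets):
        score = rng.normal(0.0, noise_sd, size=n_genes)
        score[planted_mask] += effect
        order = sorted(range(n_genes), key=lambda i: (-score[i], roster[i]))
        ranks = {roster[i]: (pos + 1) / n_genes for pos, i in enumerate(order)}
        lists.append(RankedList(dataset_id=f"ds{d + 1:02d}", direction=direction,
                                ranks=ranks))
    return lists


def write_benchmark(fixture: BenchmarkFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the pipeline's own formats plus a truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network_edges.tsv",
        "signatures": outdir / "drug_signatures.tsv",
        "disease": outdir / "disease_genes.txt",
        "manifest": outdir / "manifest.json",
    }
    from .network import write_network  # local import avoids a cycle at module load

    write_network(fixture.network, paths["network"])
    write_signatures(fixture.library, paths["signatures"], format="tsv")
    paths["disease"].write_text("\n".join(fixture.disease.genes) + "\n")
    manifest = {
        "spec": asdict(fixture.spec),
        "labels": fixture.labels,
        "module_genes": list(fixture.disease.genes),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
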