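"""Toxicity scoring against an injury gene set, whole-network and
per-subnetwork.

A large curated toxicity gene set (e.g. a liver-injury signature) typically
spans several mechanisms. The induced subgraph on the toxicity genes is
split by Louvain modularity optimization into communities; communities with
fewer than 10 genes are discarded, and each retained subnetwork serves as
an independent query for overlap- or network-proximity drug scoring, which
can resolve mechanism-specific toxicity signals that the whole set dilutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .config import MIN_SUBNETWORK_GENES, N_PERMUTATIONS
from .network import GeneNetwork, rank_drugs_by_proximity
from .overlap import rank_drugs_by_overlap
from .signatures import GeneSet, SignatureLibrary


@dataclass(frozen=True)
class ToxicitySubnetwork:
    id: int
    genes: tuple[str, ...]
    parent: str
    modularity_run_seed: int

    def as_gene_set(self) -> GeneSet:
        return GeneSet(id=f"{self.parent}_subnet{self.id}", genes=self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DecompositionResult:
    subnetworks: list[ToxicitySubnetwork]
    filtered_genes: tuple[str, ...]
    n_filtered_communities: int

    @property
    def retained_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for sub in self.subnetworks:
            out |= set(sub.genes)
        return frozenset(out)


def decompose_toxicity_network(
    tox: GeneSet,
    net: GeneNetwork,
    seed: int = 0,
    min_size: int = MIN_SUBNETWORK_GENES,
    resolution: float = 1.0,
) -> DecompositionResult:
    """Partition the toxicity genes present in the network into modularity
    communities (Louvain, seed-controlled, resolution 1.0 by default);
    communities with fewer than ``min_size`` genes are dropped and counted.
    """
    members = net.restrict(tox.genes)
    if not members:
        raise ValueError("no toxicity gene is present in the network")
    induced = net.graph.subgraph(members)
    communities = nx.community.louvain_communities(induced, resolution=resolution,
                                                   seed=int(seed))
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    subnetworks: list[ToxicitySubnetwork] = []
    filtered: list[str] = []
    n_filtered = 0
    next_id = 1
    for comm in communities:
        if len(comm) < min_size:
            n_filtered += 1
            filtered.extend(sorted(comm))
            continue
        subnetworks.append(ToxicitySubnetwork(
            id=next_id, genes=tuple(sorted(comm)), parent=tox.id,
            modularity_run_seed=int(seed),
        ))
        next_id += 1
    return DecompositionResult(
        subnetworks=subnetworks,
        filtered_genes=tuple(sorted(filtered)),
        n_filtered_communities=n_filtered,
    )


def score_toxicity(
    library: SignatureLibrary,
    tox,
    net: GeneNetwork,
    mode: str = "network",
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    universe: int | None = None,
):
    """Rank every library drug against a toxicity gene set or subnetwork.

    ``mode='network'`` delegates to proximity scoring (ascending z, lower =
    more toxic-like); ``mode='overlap'`` to Jaccard overlap scoring.
    """
    query = tox.as_gene_set() if isinstance(tox, ToxicitySubnetwork) else tox
    if mode == "network":
        return rank_drugs_by_proximity(library, query, net, n_perm=n_perm, seed=seed)
    if mode == "overlap":
        return rank_drugs_by_overlap(library, query, universe=universe, method="jaccard")
    raise ValueError(f"unknown mode {mode!r}")


def score_toxicity_subnetworks(
    library: SignatureLibrary,
    decomposition: DecompositionResult,
    net: GeneNetwork,
    mode: str = "network",
    n_perm: int = N_PERMUTATIONS,
    seed=None,
    universe: int | None = None,
) -> dict[int, list]:
    """One ranked score vector per retained subnetwork, keyed by its id."""
    return {
        sub.id: score_toxicity(library, sub, net, mode=mode, n_perm=n_perm,
                               seed=seed, universe=universe)
        for sub in decomposition.subnetworks
    }


def membership_frame(decomposition: DecompositionResult) -> pd.DataFrame:
    """Gene-to-subnetwork membership table for TSV export."""
    rows = [[gene, sub.id] for sub in decomposition.subnetworks for gene in sub.genes]
    rows += [[gene, 0] for gene in decomposition.filtered_genes]
    return pd.DataFrame(rows, columns=["gene", "subnetwork_id"])
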