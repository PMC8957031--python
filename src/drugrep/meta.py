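"""Consensus meta-signatures by robust rank aggregation (RRA).

Per-dataset differential-expression results are reduced to normalized gene
ranks in (0, 1] (rank / roster size). For one gene observed at ranks
r_(1) <= ... <= r_(k) across k lists, the RRA score is the order-statistic
bound

    rho = min_j  P( Beta(j, k - j + 1) <= r_(j) )

i.e. the smallest probability that the j-th smallest of k uniform ranks
would be at least this extreme. The per-gene p bound is min(k * rho, 1)
(Bonferroni over the k order statistics), and the gene-wise call applies a
further Bonferroni factor for the number of genes tested, at the 0.01
threshold. Up- and downregulated genes are aggregated separately; genes
absent from a list carry the worst rank 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .config import META_THRESHOLD
from .signatures import GeneSignature


@dataclass
class RankedList:
    """One dataset's ranked genes for one direction.

    ``ranks`` maps gene symbol (case-normalized on construction) to
    normalized rank in (0, 1].
    """

    dataset_id: str
    direction: str
    ranks: dict[str, float]
    tissue: str = ""

    def __post_init__(self):
        if self.direction not in {"up", "down"}:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        normalized: dict[str, float] = {}
        for gene, r in self.ranks.items():
            r = float(r)
            if not (0.0 < r <= 1.0):
                raise ValueError(f"rank for {gene!r} outside (0, 1]: {r}")
            normalized[str(gene).upper()] = r
        self.ranks = normalized


def default_ranker(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    dataset_id: str = "dataset",
    tissue: str = "",
) -> tuple[RankedList, RankedList]:
    """Rank genes by a standardized mean difference between groups.

    A documented stand-in for any external multivariate ranker: the
    statistic is (mean_treated - mean_control) / pooled sd. Genes are
    ranked descending for the up list and ascending for the down list,
    ties broken by symbol order; normalized rank = position / n_genes.
    Any ranker producing normalized ranks can be plugged in instead.
    """
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    genes = treated.index
    if not genes.equals(control.index):
        raise ValueError("treated and control must share the same gene index")
    mt = treated.mean(axis=1).to_numpy()
    mc = control.mean(axis=1).to_numpy()
    vt = treated.var(axis=1, ddof=1).to_numpy()
    vc = control.var(axis=1, ddof=1).to_numpy()
    pooled = np.sqrt((vt + vc) / 2.0)
    stat = (mt - mc) / np.where(pooled > 0, pooled, 1e-12)
    n = len(genes)
    order_up = sorted(range(n), key=lambda i: (-stat[i], str(genes[i]).upper()))
    order_down = sorted(range(n), key=lambda i: (stat[i], str(genes[i]).upper()))
    up = {str(genes[i]): (pos + 1) / n for pos, i in enumerate(order_up)}
    down = {str(genes[i]): (pos + 1) / n for pos, i in enumerate(order_down)}
    return (
        RankedList(dataset_id=dataset_id, direction="up", ranks=up, tissue=tissue),
        RankedList(dataset_id=dataset_id, direction="down", ranks=down, tissue=tissue),
    )


def rra_score(ranks: Sequence[float], k: int | None = None) -> tuple[float, float]:
    """RRA rho score and its per-gene p bound for one gene's rank vector.

    ``ranks`` are the gene's normalized ranks across k lists (the caller
    fills missing lists with the worst rank 1.0). Returns (rho, min(k*rho, 1)).
    For k = 1 the p bound equals the rank itself (Beta(1,1) is uniform).
    """
    r = np.asarray(ranks, dtype=float)
    if r.size == 0:
        raise ValueError("empty rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("ranks must lie in (0, 1]")
    k = int(k) if k is not None else r.size
    if k < r.size:
        raise ValueError("k smaller than the number of supplied ranks")
    full = np.ones(k)
    full[: r.size] = np.sort(r)
    full.sort()
    j = np.arange(1, k + 1)
    rho = float(np.min(beta.cdf(full, j, k - j + 1)))
    return rho, min(k * rho, 1.0)


@dataclass
class MetaSignature:
    """Consensus up/down genes with corrected RRA p-values."""

    drug_id: str
    species: str = "other"
    tissue: str = ""
    up: dict[str, float] = field(default_factory=dict)
    down: dict[str, float] = field(default_factory=dict)
    ambiguous: frozenset[str] = frozenset()
    n_lists: int = 0
    threshold: float = META_THRESHOLD

    @property
    def up_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.up))

    @property
    def down_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.down))

    def to_gene_signature(self) -> GeneSignature:
        stats = {**self.up, **self.down}
        return GeneSignature(
            id=self.drug_id, species=self.species, tissue=self.tissue,
            up_genes=self.up_genes, down_genes=self.down_genes,
            ranking_stat=stats, source="meta",
        )


def _aggregate_direction(lists: Sequence[RankedList], threshold: float) -> dict[str, float]:
    """Corrected p per significant gene for one direction's lists."""
    if not lists:
        return {}
    k = len(lists)
    roster: set[str] = set()
    for rl in lists:
        roster |= set(rl.ranks)
    n_genes = len(roster)
    out: dict[str, float] = {}
    for gene in sorted(roster):
        ranks = [rl.ranks.get(gene, 1.0) for rl in lists]
        _, p = rra_score(ranks, k)
        corrected = min(p * n_genes, 1.0)
        if corrected < threshold:
            out[gene] = corrected
    return out


def aggregate_meta_signature(
    lists: Iterable[RankedList],
    threshold: float = META_THRESHOLD,
    drug_id: str = "meta",
    species: str = "other",
    tissue: str = "",
) -> MetaSignature:
    """Aggregate ranked lists into a consensus signature, per direction.

    A gene significant in both directions is assigned to the direction with
    the smaller corrected p and flagged ambiguous.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("no ranked lists supplied")
    up = _aggregate_direction([rl for rl in lists if rl.direction == "up"], threshold)
    down = _aggregate_direction([rl for rl in lists if rl.direction == "down"], threshold)
    ambiguous = frozenset(set(up) & set(down))
    for gene in ambiguous:
        if up[gene] <= down[gene]:
            del down[gene]
        else:
            del up[gene]
    return MetaSignature(
        drug_id=drug_id, species=species, tissue=tissue, up=up, down=down,
        ambiguous=ambiguous, n_lists=len(lists), threshold=threshold,
    )


def aggregate_species_level(
    lists: Iterable[RankedList],
    threshold: float = META_THRESHOLD,
    drug_id: str = "meta",
    species: str = "other",
    mode: str = "pooled",
) -> MetaSignature:
    """Species-level consensus across all tissues of one drug.

    ``pooled`` (default) reruns RRA over every list regardless of tissue;
    ``union`` aggregates per tissue first and unions the calls, keeping the
    smallest corrected p per gene (conflicting directions flagged ambiguous).
    """
    lists = list(lists)
    if not lists:
        raise ValueError("no ranked lists supplied")
    if mode == "pooled":
        return aggregate_meta_signature(lists, threshold, drug_id, species, tissue="all")
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    tissues = sorted({rl.tissue for rl in lists})
    up: dict[str, float] = {}
    down: dict[str, float] = {}
    ambiguous: set[str] = set()
    for tis in tissues:
        part = aggregate_meta_signature(
            [rl for rl in lists if rl.tissue == tis], threshold, drug_id, species, tis)
        ambiguous |= set(part.ambiguous)
        for gene, p in part.up.items():
            up[gene] = min(p, up.get(gene, 1.0))
        for gene, p in part.down.items():
            down[gene] = min(p, down.get(gene, 1.0))
    for gene in set(up) & set(down):
        ambiguous.add(gene)
        if up[gene] <= down[gene]:
            del down[gene]
        else:
            del up[gene]
    return MetaSignature(
        drug_id=drug_id, species=species, tissue="all", up=up, down=down,
        ambiguous=frozenset(ambiguous), n_lists=len(lists), threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Ranked list I/O (TSV: dataset_id, direction, gene, rank, n_genes)


def read_ranked_lists(path: str | Path) -> list[RankedList]:
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "direction": str, "gene": str})
    required = {"dataset_id", "direction", "gene", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: list[RankedList] = []
    keys = ["dataset_id", "direction"] + (["tissue"] if "tissue" in df.columns else [])
    if "tissue" in df.columns:
        df["tissue"] = df["tissue"].fillna("")
    for key, grp in df.groupby(keys, sort=True, dropna=False):
        dataset_id, direction = key[0], key[1]
        tissue = key[2] if len(key) > 2 else ""
        ranks = dict(zip(grp["gene"], grp["rank"].astype(float)))
        out.append(RankedList(dataset_id=dataset_id, direction=direction,
                              ranks=ranks, tissue=tissue))
    return out


def write_ranked_lists(lists: Sequence[RankedList], path: str | Path) -> None:
    rows = []
    for rl in lists:
        n = len(rl.ranks)
        for gene, r in sorted(rl.ranks.items(), key=lambda kv: (kv[1], kv[0])):
            rows.append([rl.dataset_id, rl.direction, gene, r, n, rl.tissue])
    pd.DataFrame(rows, columns=["dataset_id", "direction", "gene", "rank", "n_genes",
                                "tissue"]).to_csv(path, sep="\t", index=False)
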