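"""Gene-overlap drug repositioning.

Scores a drug signature against a query (disease/ADR) gene set by direct
set overlap: Jaccard index, direction-aware signed Jaccard, fold
enrichment, and a one-sided Fisher's exact test, with Benjamini-Hochberg
control across the drugs scored in one run.

The signed Jaccard score for drug halves (a1 up, a2 down) versus query
halves (b1 up, b2 down) is

    J(a1,b1) + J(a2,b2) - J(a1,b2) - J(a2,b1)

and lies in [-2, 2]: +2 for identical direction-split signatures, negative
when the drug opposes the query's directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import BH_ALPHA
from .signatures import GeneSet, GeneSignature, SignatureLibrary, _upper


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B| on case-normalized symbol sets."""
    a, b = _upper(a), _upper(b)
    union = a | b
    if not union:
        raise ValueError("both sets are empty")
    return len(a & b) / len(union)


def _jaccard_or_zero(a: frozenset, b: frozenset) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def signed_jaccard(a1, a2, b1, b2) -> float:
    """Direction-aware similarity J(a1,b1)+J(a2,b2)-J(a1,b2)-J(a2,b1).

    Terms with an empty union contribute 0, so the score degrades
    gracefully for one-directional signatures.
    """
    a1, a2, b1, b2 = _upper(a1), _upper(a2), _upper(b1), _upper(b2)
    if not (a1 | a2 | b1 | b2):
        raise ValueError("all four sets are empty")
    if a1 & a2:
        raise ValueError("first signature's up/down sets overlap")
    if b1 & b2:
        raise ValueError("second signature's up/down sets overlap")
    return (
        _jaccard_or_zero(a1, b1) + _jaccard_or_zero(a2, b2)
        - _jaccard_or_zero(a1, b2) - _jaccard_or_zero(a2, b1)
    )


@dataclass
class OverlapResult:
    drug_id: str
    score: float
    jaccard: float
    odds_ratio: float
    fold_enrichment: float
    p_value: float
    adjusted_p: float = 1.0
    overlap_genes: tuple[str, ...] = ()
    universe_size: int = 0
    species: str = ""
    tissue: str = ""
    dose: str = ""
    duration: str = ""
    rank: int = 0
    significant: bool = False


def fisher_overlap(drug, query, universe: int, drug_id: str = "") -> OverlapResult:
    """One-sided (enrichment) Fisher's exact test of the 2x2 overlap table.

    Fold enrichment is (overlap/|drug|) / (|query|/universe). A saturated
    table (no cell to compare against) reports an infinite odds ratio.
    """
    drug_u, query_u = _upper(drug), _upper(query)
    if not drug_u or not query_u:
        raise ValueError("drug and query sets must be non-empty")
    if universe < len(drug_u | query_u):
        raise ValueError(
            f"universe ({universe}) smaller than union of sets ({len(drug_u | query_u)})"
        )
    overlap = sorted(drug_u & query_u)
    a = len(overlap)
    b = len(drug_u) - a
    c = len(query_u) - a
    d = universe - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        odds = math.inf if a * d > 0 or (b == 0 and c == 0) else 0.0
    else:
        odds = (a * d) / (b * c)
    fold = (a / len(drug_u)) / (len(query_u) / universe) if a else 0.0
    p = min(max(float(p), 5e-324), 1.0)
    return OverlapResult(
        drug_id=drug_id, score=fold, jaccard=_jaccard_or_zero(drug_u, query_u),
        odds_ratio=odds, fold_enrichment=fold, p_value=p, adjusted_p=p,
        overlap_genes=tuple(overlap), universe_size=universe,
    )


def rank_drugs_by_overlap(
    library: SignatureLibrary,
    query,
    universe: int | None = None,
    method: str = "jaccard",
    alpha: float = BH_ALPHA,
) -> list[OverlapResult]:
    """Score every library signature against the query and rank.

    ``query`` is a GeneSet (undirected) or a GeneSignature / (up, down)
    pair for the signed method. The ranking score is the Jaccard index,
    the signed Jaccard, or the fold enrichment depending on ``method``;
    Fisher p-values are computed on direction-pooled sets in every mode
    and BH-adjusted across the drugs scored in this run. Results are in
    descending score order with ties broken by drug id.
    """
    if len(library) == 0:
        raise ValueError("signature library is empty")
    if method not in {"jaccard", "signed_jaccard", "fisher"}:
        raise ValueError(f"unknown method {method!r}")

    if isinstance(query, GeneSignature):
        q_up, q_down = query.up_upper, query.down_upper
    elif isinstance(query, GeneSet):
        q_up, q_down = query.upper, frozenset()
    elif isinstance(query, tuple) and len(query) == 2:
        q_up, q_down = _upper(query[0]), _upper(query[1])
    else:
        q_up, q_down = _upper(query), frozenset()
    q_all = q_up | q_down
    if not q_all:
        raise ValueError("query gene set is empty")
    if method == "signed_jaccard" and not (q_up and q_down):
        raise ValueError("signed_jaccard needs a direction-split query")

    if universe is None:
        universe = len(library.universe() | q_all)

    results: list[OverlapResult] = []
    for sig in library:
        res = fisher_overlap(sig.all_upper, q_all, universe, drug_id=sig.id)
        if method == "jaccard":
            res.score = res.jaccard
        elif method == "signed_jaccard":
            res.score = signed_jaccard(sig.up_upper, sig.down_upper, q_up, q_down)
        res.species, res.tissue = sig.species, sig.tissue
        res.dose, res.duration = sig.dose or "", sig.duration or ""
        results.append(res)

    _, adjusted, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for res, adj in zip(results, adjusted):
        res.adjusted_p = max(float(adj), res.p_value)
        res.significant = res.adjusted_p < alpha
    results.sort(key=lambda r: (-r.score, r.drug_id, r.species, r.tissue, r.dose, r.duration))
    for rank, res in enumerate(results, start=1):
        res.rank = rank
    return results


def overlap_results_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Results table with a stable column order for TSV export."""
    return pd.DataFrame(
        [
            [r.drug_id, r.species, r.tissue, r.dose, r.duration, r.score,
             r.odds_ratio, r.fold_enrichment, r.p_value, r.adjusted_p,
             ",".join(r.overlap_genes), r.rank, r.significant]
            for r in results
        ],
        columns=["drug_id", "species", "tissue", "dose", "duration", "score",
                 "odds_ratio", "fold_enrichment", "p_value", "adjusted_p",
                 "overlap_genes", "rank", "significant"],
    )
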