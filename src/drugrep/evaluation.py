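"""Retrieval benchmarking: AUROC, balanced accuracy, percentile summaries,
rank tests, and the masked-signature robustness experiment.

AUROC is computed by the midrank (Mann-Whitney) formula: the probability
that a random positive outranks a random negative, with ties counted half.
Balanced accuracy is (sensitivity + specificity) / 2, reported in percent,
from the confusion counts of a significance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import MASKING_REPEATS
from .network import GeneNetwork, rank_drugs_by_proximity
from .overlap import rank_drugs_by_overlap
from .signatures import GeneSet, SignatureLibrary


def auroc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher_is_positive",
) -> tuple[float, float]:
    """Area under the ROC curve and a Mann-Whitney separation p-value.

    Midrank formula with tie handling; the p-value is the one-sided
    normal-approximated Mann-Whitney test that positives score better.
    """
    if direction not in {"higher_is_positive", "lower_is_positive"}:
        raise ValueError(f"unknown direction {direction!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if direction == "lower_is_positive":
        scores = -scores
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    res = stats.mannwhitneyu(scores[labels], scores[~labels],
                             alternative="greater", method="asymptotic")
    return float(auc), float(res.pvalue)


def balanced_accuracy_from_counts(
    total: int, n_significant: int, n_positive: int, n_positive_significant: int
) -> float:
    """Balanced accuracy (percent) from the confusion counts of a cutoff.

    sensitivity = positives called significant / positives;
    specificity = negatives not called significant / negatives.
    """
    if not (0 <= n_positive_significant <= min(n_significant, n_positive)):
        raise ValueError("inconsistent counts: n_positive_significant too large")
    if n_significant > total or n_positive > total:
        raise ValueError("counts exceed total")
    if n_positive == 0 or n_positive == total:
        raise ValueError("both classes must be present")
    sensitivity = n_positive_significant / n_positive
    false_pos = n_significant - n_positive_significant
    specificity = (total - n_positive - false_pos) / (total - n_positive)
    return 100.0 * (sensitivity + specificity) / 2.0


def percentile_summary(values: Sequence[float]) -> tuple[float, float]:
    """Sample median (midpoint for even n) and mean of prediction
    percentiles, rounded to 3 decimals."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty percentile list")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("percentiles must lie in [0, 1]")
    return round(float(np.median(arr)), 3), round(float(arr.mean()), 3)


def rank_test_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float, str]:
    """Nonparametric two-group comparison.

    Paired samples use the Wilcoxon signed-rank test; independent samples
    use the Mann-Whitney rank-sum test (normal approximation with tie
    correction). Returns (statistic, p, test name).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired mode requires equal lengths")
        diffs = a - b
        if int((diffs != 0).sum()) < 3:
            raise ValueError("fewer than 3 informative pairs")
        if np.all(diffs == diffs[0]):
            pass  # constant nonzero shift is fine for the test
        res = stats.wilcoxon(a, b, zero_method="wilcox", method="approx", correction=True)
        return float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank"
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "mann_whitney_u"


def kruskal_test(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis test across more than two groups."""
    if len(groups) < 3:
        raise ValueError("use rank_test_two_groups for fewer than 3 groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BenchmarkResult:
    scores: tuple[float, ...]
    labels: tuple[bool, ...]
    auroc: float
    auroc_p: float
    total: int
    n_significant: int
    n_positive: int
    n_positive_significant: int
    balanced_accuracy: float


def summarize_benchmark(
    scores: Sequence[float],
    labels: Sequence[bool],
    significant: Sequence[bool],
    direction: str = "higher_is_positive",
) -> BenchmarkResult:
    """Full retrieval summary: AUROC plus cutoff confusion counts and
    balanced accuracy."""
    labels = np.asarray(labels, dtype=bool)
    significant = np.asarray(significant, dtype=bool)
    auc, p = auroc(scores, labels, direction=direction)
    total = int(labels.size)
    n_sig = int(significant.sum())
    n_pos = int(labels.sum())
    n_pos_sig = int((labels & significant).sum())
    bal = balanced_accuracy_from_counts(total, n_sig, n_pos, n_pos_sig)
    return BenchmarkResult(
        scores=tuple(float(s) for s in scores), labels=tuple(bool(x) for x in labels),
        auroc=auc, auroc_p=p, total=total, n_significant=n_sig,
        n_positive=n_pos, n_positive_significant=n_pos_sig, balanced_accuracy=bal,
    )


def _score_library(
    library: SignatureLibrary,
    query: GeneSet,
    labels: Mapping[str, bool],
    net: GeneNetwork | None,
    method: str,
    n_perm: int,
    seed,
    universe: int | None,
) -> tuple[float, float]:
    """One repositioning run -> AUROC of retrieving the labeled positives."""
    if method == "network":
        results = rank_drugs_by_proximity(library, query, net, n_perm=n_perm, seed=seed)
        scores = [r.z for r in results]
        direction = "lower_is_positive"
    elif method == "overlap":
        results = rank_drugs_by_overlap(library, query, universe=universe, method="jaccard")
        scores = [r.score for r in results]
        direction = "higher_is_positive"
    else:
        raise ValueError(f"unknown method {method!r}")
    lab = [labels[r.drug_id] for r in results]
    return auroc(scores, lab, direction=direction)


def masking_robustness(
    query: GeneSet,
    library: SignatureLibrary,
    labels: Mapping[str, bool],
    net: GeneNetwork | None,
    proportions: Sequence[float],
    n_repeat: int = MASKING_REPEATS,
    method: str = "network",
    seed: int = 0,
    n_perm: int = 200,
    universe: int | None = None,
) -> pd.DataFrame:
    """Retrieval AUROC after masking part of the query signature.

    For each proportion p, ``n_repeat`` seeded subsamples retain a fraction
    p of the query genes and the repositioning run is repeated. Subsampling
    uses independent child seeds per repeat, while the scoring itself uses
    one seed shared across all repeats and proportions, so proportion 1.0
    reproduces the unmasked AUROC exactly in every repeat. Proportions
    leaving fewer than 5 genes are skipped with a warning.
    Returns a tidy frame (proportion, repeat, auroc, auroc_p).
    """
    proportions = list(proportions)
    rows = []
    root = np.random.SeedSequence(seed)
    scoring_seed, subsample_seed = root.spawn(2)
    scoring_entropy = int(scoring_seed.generate_state(1)[0]) % (2**31)
    genes = sorted(query.upper)
    n = len(genes)
    rep_seeds = subsample_seed.spawn(len(proportions) * n_repeat)
    for pi, prop in enumerate(proportions):
        if not (0.0 < prop <= 1.0):
            raise ValueError(f"proportion must lie in (0, 1], got {prop}")
        n_keep = int(round(prop * n))
        if n_keep < 5:
            warnings.warn(
                f"proportion {prop} retains {n_keep} genes (<5); skipped", stacklevel=2
            )
            continue
        for rep in range(n_repeat):
            if prop >= 1.0:
                kept = genes
            else:
                rng = np.random.default_rng(rep_seeds[pi * n_repeat + rep])
                kept = sorted(rng.choice(genes, size=n_keep, replace=False))
            sub = GeneSet(id=f"{query.id}_p{prop}_r{rep}", genes=kept)
            auc, p = _score_library(library, sub, labels, net, method,
                                    n_perm, scoring_entropy, universe)
            rows.append([prop, rep, auc, p])
    return pd.DataFrame(rows, columns=["proportion", "repeat", "auroc", "auroc_p"])
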