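"""Feature selection: Fisher-score ranking, nested experimental datasets,
and greedy sequential forward selection (SFS).

The Fisher score of feature i for a two-class sample is

    F(i) = [ (xbar+_i - xbar_i)^2 + (xbar-_i - xbar_i)^2 ]
           / [ s+_i^2 + s-_i^2 ]

where xbar_i is the whole-cohort mean, xbar+/- the class means, and
s+/-^2 the per-class *sample* variances (n-1 divisors).  A larger score
means larger between-class separation relative to within-class spread.
The score is invariant under positive affine transforms of a feature,
so the ranking is unchanged by min-max normalization (up to ties on
constant columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .schema import FeatureTable


@dataclass
class FScoreRanking:
    """Per-feature scores and the descending-score feature order.

    ``order`` holds 1-based feature (descriptor) indices; ties are
    broken by ascending feature index.  ``has_infinite`` flags features
    with zero pooled within-class variance but nonzero class separation.
    """

    scores: np.ndarray          # indexed by column position
    order: np.ndarray           # 1-based feature indices, best first
    feature_indices: np.ndarray  # 1-based index of each column
    has_infinite: bool = False

    def top(self, k: int) -> list[int]:
        return [int(i) for i in self.order[:k]]

    def score_of(self, feature_index: int) -> float:
        pos = int(np.flatnonzero(self.feature_indices == feature_index)[0])
        return float(self.scores[pos])


def fscore(table: FeatureTable) -> FScoreRanking:
    """Rank all features of a two-class table by Fisher score.

    Degenerate columns: 0/0 -> score 0; positive/0 -> +inf (flagged).
    Requires at least two subjects in each class.
    """
    pos = table.labels == 1
    neg = table.labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("Fisher score needs >= 2 subjects per class")
    X = table.values
    mean_all = X.mean(axis=0)
    mean_pos = X[pos].mean(axis=0)
    mean_neg = X[neg].mean(axis=0)
    num = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    den = X[pos].var(axis=0, ddof=1) + X[neg].var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                          np.where(num > 0, np.inf, 0.0))
    feature_indices = np.array([d.index for d in table.descriptors], dtype=int)
    # descending score, ties by ascending feature index
    order_pos = np.lexsort((feature_indices, -scores))
    return FScoreRanking(
        scores=scores,
        order=feature_indices[order_pos],
        feature_indices=feature_indices,
        has_infinite=bool(np.isinf(scores).any()),
    )


def cumulative_datasets(ranking: FScoreRanking, k_max: int) -> list[list[int]]:
    """Nested top-k feature prefixes ("experimental datasets"), k = 1..k_max.

    The k-th experimental dataset combines the k-th ranked feature with
    all better-ranked features, so prefix k is a subset of prefix k+1.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if k_max > len(ranking.order):
        raise ValidationError(
            f"k_max={k_max} exceeds number of features ({len(ranking.order)})")
    return [ranking.top(k) for k in range(1, k_max + 1)]


@dataclass
class SFSTrace:
    """Greedy forward-selection path.

    ``steps`` records (added_feature_index, criterion_value) in order;
    ``selected_at_best`` is the earliest prefix attaining the maximum
    criterion value.
    """

    steps: list[tuple[int, float]]
    selected_at_best: tuple[int, ...]

    @property
    def best_value(self) -> float:
        return max(v for _, v in self.steps)


def sfs(candidate_pool: Iterable[int],
        criterion: Callable[[tuple[int, ...]], float],
        max_steps: int | None = None) -> SFSTrace:
    """Sequential forward selection over a pool of feature indices.

    Starting from the empty set, each step adds the pool feature whose
    addition maximizes ``criterion`` of the augmented subset (ties go
    to the lowest feature index).  Runs to ``max_steps`` (or pool
    exhaustion) and returns the whole trace; the selected subset is the
    best prefix of the path, not the last one, so the search is robust
    to local dips in the criterion.
    """
    pool = sorted(set(int(i) for i in candidate_pool))
    if not pool:
        raise ValidationError("SFS candidate pool is empty")
    n_steps = len(pool) if max_steps is None else min(max_steps, len(pool))
    if n_steps < 1:
        raise ValidationError("max_steps must be >= 1")
    selected: list[int] = []
    remaining = list(pool)
    steps: list[tuple[int, float]] = []
    for _ in range(n_steps):
        best_feat, best_val = None, None
        for feat in remaining:  # ascending order makes ties -> lowest index
            val = float(criterion(tuple(selected + [feat])))
            if best_val is None or val > best_val:
                best_feat, best_val = feat, val
        selected.append(best_feat)
        remaining.remove(best_feat)
        steps.append((best_feat, best_val))
    values = [v for _, v in steps]
    best_len = int(np.argmax(values)) + 1  # argmax -> earliest on ties
    return SFSTrace(steps=steps,
                    selected_at_best=tuple(f for f, _ in steps[:best_len]))
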