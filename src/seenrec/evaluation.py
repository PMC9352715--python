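"""Leave-one-out evaluation: HR@k and nDCG@k for next-item prediction.

Per user, the last item of the sequence is hidden for test and the
second-last for validation; a recommender scores candidates given the
remaining context and is judged by where the hidden item lands:

    HR@k   = mean over users of [rank <= k]   (= 1 - missRatio)
    nDCG@k = mean over users of 1/log2(rank+1) if rank <= k else 0

With a single relevant item per user the ideal DCG is 1, so nDCG
reduces to the discounted reciprocal-log of the rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import derive_rng, id_key
from .data import SequentialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "EvalSplit",
    "MetricsRecord",
    "split_leave_one_out",
    "hit_at_k",
    "ndcg_at_k",
    "rank_of_item",
    "evaluate",
    "run_grid",
]


@dataclass
class EvalSplit:
    """Per-user train prefix / validation item / test item."""

    train: dict[str, list[tuple[str, int]]]
    val: dict[str, tuple[str, int]]
    test: dict[str, tuple[str, int]]
    catalogue: set[str] = field(default_factory=set)

    @property
    def users(self) -> list[str]:
        return list(self.train)


def split_leave_one_out(ds: SequentialDataset) -> EvalSplit:
    """Hide each user's last item for test and second-last for validation.

    Users with fewer than 3 interactions cannot be split and are excluded
    with a warning (the usual min-20 filter makes this moot).
    """
    train, val, test = {}, {}, {}
    for user, seq in ds.sequences.items():
        if len(seq) < 3:
            logger.warning("user %s has %d < 3 interactions; excluded from evaluation",
                           user, len(seq))
            continue
        train[user] = list(seq[:-2])
        val[user] = seq[-2]
        test[user] = seq[-1]
    return EvalSplit(train=train, val=val, test=test, catalogue=set(ds.catalogue))


def hit_at_k(rank: int, k: int) -> int:
    """1 iff the hidden item's rank is within the top-k list."""
    if rank < 1:
        raise ValueError("ranks are 1-based")
    return 1 if rank <= k else 0


def ndcg_at_k(rank: int, k: int) -> float:
    """Discounted gain of the single relevant item: 1/log2(rank+1) in-window."""
    if rank < 1 or k < 1:
        raise ValueError("rank and k must be >= 1")
    return 1.0 / math.log2(rank + 1) if rank <= k else 0.0


@dataclass(frozen=True)
class MetricsRecord:
    """HR@k and nDCG@k aggregated over users for one experiment cell."""

    k: int
    hr: float
    ndcg: float
    n_users: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.hr <= 1.0 and 0.0 <= self.ndcg <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")


def rank_of_item(scores: Mapping[str, float], item: str) -> int:
    """1-based rank of ``item`` among the scored candidates.

    Higher score is better; ties break by ascending item id, consistently
    with every other ranking in the package.
    """
    if item not in scores:
        raise KeyError(f"item {item!r} was not scored")
    s = scores[item]
    key = id_key(item)
    rank = 1
    for cand, sc in scores.items():
        if cand == item:
            continue
        if sc > s or (sc == s and id_key(cand) < key):
            rank += 1
    return rank


def _sample_negatives(catalogue: Sequence[str], popularity: Mapping[str, int],
                      exclude: set[str], m: int, rng: np.random.Generator) -> list[str]:
    pool = [c for c in catalogue if c not in exclude]
    if m >= len(pool) + 1:
        raise ValueError(f"cannot sample {m} negatives from {len(pool)} candidates")
    weights = np.array([popularity.get(c, 0) + 1 for c in pool], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(pool), size=m, replace=False, p=weights)
    return [pool[i] for i in picks]


def evaluate(score_fn: Callable[[str, list[str]], Mapping[str, float]],
             split: EvalSplit,
             ks: Sequence[int] = (1, 5, 10),
             policy: str = "full",
             n_negatives: int = 100,
             seed: int = 0,
             context: str = "train+val") -> dict[int, MetricsRecord]:
    """Rank each user's hidden test item and aggregate HR/nDCG at each k.

    ``score_fn(user, context_items)`` returns candidate→score. The context
    is the training prefix plus the validation item (the model predicts the
    *next* item after everything it may see). ``policy="full"`` ranks the
    whole catalogue; ``"sampled"`` ranks the test item against
    ``n_negatives`` popularity-proportional negatives drawn outside the
    user's training items. A test item the scorer does not cover counts as
    a miss.
    """
    if policy not in ("full", "sampled"):
        raise ValueError(f"unknown candidate policy {policy!r}")
    popularity: dict[str, int] = {}
    for seq in split.train.values():
        for item, _ in seq:
            popularity[item] = popularity.get(item, 0) + 1
    catalogue = sorted(split.catalogue, key=id_key)

    ranks: dict[str, int | None] = {}
    for user in split.train:
        ctx = [i for i, _ in split.train[user]]
        if context == "train+val":
            ctx = ctx + [split.val[user][0]]
        test_item = split.test[user][0]
        scores = score_fn(user, ctx)
        if policy == "full":
            candidates = {c: scores.get(c, -math.inf) for c in catalogue}
        else:
            rng = derive_rng(seed, "negatives", user)
            exclude = {i for i, _ in split.train[user]} | {test_item}
            negs = _sample_negatives(catalogue, popularity, exclude, n_negatives, rng)
            candidates = {c: scores.get(c, -math.inf) for c in negs + [test_item]}
        if test_item not in candidates or test_item not in scores:
            logger.warning("test item %s of user %s not scored; counted as miss",
                           test_item, user)
            ranks[user] = None
            continue
        ranks[user] = rank_of_item(candidates, test_item)

    out = {}
    n = len(ranks)
    for k in ks:
        hits = [hit_at_k(r, k) if r is not None else 0 for r in ranks.values()]
        gains = [ndcg_at_k(r, k) if r is not None else 0.0 for r in ranks.values()]
        out[k] = MetricsRecord(k=k, hr=float(np.mean(hits)), ndcg=float(np.mean(gains)),
                               n_users=n)
    return out


def run_grid(cells: Sequence[dict], runner: Callable[..., dict[int, MetricsRecord]],
             seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """Run an experiment grid and collect one row per (cell, seed, k).

    ``cells`` are keyword dictionaries (dataset, algorithm, sequence_mode,
    enrichment, n, ...) forwarded to ``runner(seed=..., **cell)``, which
    must return ``{k: MetricsRecord}``. Full provenance travels in the
    output columns; a rerun with the same seeds reproduces the table.
    """
    rows = []
    for cell in cells:
        for seed in seeds:
            records = runner(seed=seed, **cell)
            for k, rec in sorted(records.items()):
                row = {**cell, "seed": seed, "k": k,
                       "HR": rec.hr, "nDCG": rec.ndcg, "n_users": rec.n_users}
                rows.append(row)
    return pd.DataFrame(rows)
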