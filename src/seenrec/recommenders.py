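"""Order-agnostic baseline recommenders: Most-Pop and implicit-feedback ALS.

Both ignore within-user sequence order — they are the collaborative-
filtering baselines a sequence-aware model has to beat. The masked-item
transformer lives in :mod:`seenrec.transformer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from ._util import id_key

__all__ = ["PopularityModel", "fit_most_pop", "ALSModel", "fit_als"]


@dataclass
class PopularityModel:
    """Recommends the globally most-rated items to everyone."""

    counts: dict[str, int]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranking:
            self.ranking = sorted(self.counts, key=lambda i: (-self.counts[i], id_key(i)))

    def scores(self, user: str | None = None, context: Sequence[str] | None = None
               ) -> dict[str, float]:
        """Per-item scores; the user and context are irrelevant by design."""
        return {i: float(c) for i, c in self.counts.items()}

    def top_k(self, k: int) -> list[str]:
        return self.ranking[:k]


def fit_most_pop(train: Mapping[str, Sequence]) -> PopularityModel:
    """Count ratings per item over all users' training sequences."""
    if not train:
        raise ValueError("empty training data")
    counts: dict[str, int] = {}
    for seq in train.values():
        for entry in seq:
            item = entry[0] if isinstance(entry, tuple) else str(entry)
            counts[item] = counts.get(item, 0) + 1
    return PopularityModel(counts=counts)


@dataclass
class ALSModel:
    """Low-rank factorisation of the implicit preference matrix.

    Trained on the confidence-weighted objective

        sum_ui c_ui (p_ui - x_u.y_i)^2 + lam (|X|^2 + |Y|^2),

    with p_ui = 1 iff the pair was observed and c_ui = 1 + alpha r_ui.
    """

    users: list[str]
    items: list[str]
    user_factors: np.ndarray  # (n_users, f)
    item_factors: np.ndarray  # (n_items, f)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._uidx = {u: i for i, u in enumerate(self.users)}
        self._iidx = {i: j for j, i in enumerate(self.items)}

    def scores(self, user: str, context: Sequence[str] | None = None) -> dict[str, float]:
        """Dot-product preference scores for every catalogue item."""
        if user not in self._uidx:
            raise KeyError(f"unknown user {user!r}")
        s = self.user_factors[self._uidx[user]] @ self.item_factors.T
        return {item: float(s[j]) for item, j in self._iidx.items()}

    def objective(self, matrix: sp.spmatrix, alpha: float, lam: float) -> float:
        """Dense evaluation of the confidence-weighted objective (small data)."""
        p = np.asarray((matrix > 0).todense(), dtype=float)
        r = np.asarray(matrix.todense(), dtype=float)
        c = 1.0 + alpha * r
        pred = self.user_factors @ self.item_factors.T
        loss = float(np.sum(c * (p - pred) ** 2))
        reg = lam * (float(np.sum(self.user_factors ** 2)) + float(np.sum(self.item_factors ** 2)))
        return loss + reg


def interaction_matrix(train: Mapping[str, Sequence]) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Unique user–item pairs as a sparse unit-rating matrix."""
    users = sorted(train, key=id_key)
    item_set = {e[0] if isinstance(e, tuple) else str(e) for seq in train.values() for e in seq}
    items = sorted(item_set, key=id_key)
    iidx = {i: j for j, i in enumerate(items)}
    rows, cols = [], []
    for ui, user in enumerate(users):
        seen = set()
        for entry in train[user]:
            item = entry[0] if isinstance(entry, tuple) else str(entry)
            if item not in seen:
                seen.add(item)
                rows.append(ui)
                cols.append(iidx[item])
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(users), len(items))), users, items


def fit_als(train: Mapping[str, Sequence] | sp.spmatrix,
            f: int = 64, lam: float = 0.01, alpha: float = 40.0,
            iters: int = 15, seed: int = 0,
            users: list[str] | None = None, items: list[str] | None = None,
            track_objective: bool = False) -> ALSModel:
    """Alternating least squares for implicit feedback (Hu–Koren–Volinsky).

    Each sweep solves the per-user then per-item ridge systems exactly, so
    the objective is non-increasing sweep over sweep. ``track_objective``
    stores the per-sweep objective values on ``model.params["objective_trace"]``.
    """
    if f < 1 or lam <= 0 or alpha <= 0:
        raise ValueError("require f >= 1, lam > 0, alpha > 0")
    if isinstance(train, Mapping):
        matrix, users, items = interaction_matrix(train)
    else:
        matrix = sp.csr_matrix(train)
        users = users or [str(u) for u in range(matrix.shape[0])]
        items = items or [str(i) for i in range(matrix.shape[1])]
    if matrix.nnz == 0:
        raise ValueError("empty interaction matrix")
    n_users, n_items = matrix.shape
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.01, size=(n_users, f))
    Y = rng.normal(scale=0.01, size=(n_items, f))
    csr = matrix.tocsr()
    csc = matrix.tocsc()
    eye = lam * np.eye(f)

    def solve_side(factors_fixed: np.ndarray, mat, n_rows: int) -> np.ndarray:
        gram = factors_fixed.T @ factors_fixed + eye
        out = np.empty((n_rows, f))
        indptr, indices, data = mat.indptr, mat.indices, mat.data
        for row in range(n_rows):
            sl = slice(indptr[row], indptr[row + 1])
            idx = indices[sl]
            r = data[sl]
            if len(idx) == 0:
                out[row] = np.linalg.solve(gram, np.zeros(f))
                continue
            Yo = factors_fixed[idx]
            c = 1.0 + alpha * r
            # A = YtY + Yo^T (C - I) Yo, b = Yo^T C p with p = 1 on observed
            A = gram + Yo.T @ ((c - 1.0)[:, None] * Yo)
            b = Yo.T @ c
            out[row] = np.linalg.solve(A, b)
        return out

    trace = []
    for _ in range(iters):
        X = solve_side(Y, csr, n_users)
        Y = solve_side(X, csc.T.tocsr(), n_items)
        if track_objective:
            model = ALSModel(users=users, items=items, user_factors=X, item_factors=Y)
            trace.append(model.objective(matrix, alpha, lam))
    model = ALSModel(users=users, items=items, user_factors=X, item_factors=Y,
                     params={"f": f, "lam": lam, "alpha": alpha, "iters": iters,
                             "seed": seed})
    if track_objective:
        model.params["objective_trace"] = trace
    return model
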