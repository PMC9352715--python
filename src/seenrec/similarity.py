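"""Item–item similarity from an is_a ontology or from numeric features.

Two backends feed the enrichment transform:

* semantic similarity over a ChEBI-like is_a hierarchy, via information
  content (IC) and the most informative common ancestor (MICA) — the
  Resnik, Lin and Jiang–Conrath family;
* cosine similarity over per-item numeric feature vectors (e.g. mean
  sky position and parallax of an open cluster's member stars).

Either backend is materialised as a :class:`SimilarityTable` holding
symmetric scores and per-item top-n neighbour lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from ._util import id_key

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "parse_obo",
    "information_content",
    "mica",
    "semantic_similarity",
    "FeatureMatrix",
    "aggregate_features",
    "cosine_similarity",
    "SimilarityTable",
    "build_similarity_table",
    "read_similarity_table",
    "write_similarity_table",
]


@dataclass
class OntologyDAG:
    """An is_a term hierarchy: acyclic, every non-root term reaches a root."""

    parents: dict[str, tuple[str, ...]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"term {term!r} has unknown is_a target {p!r}")
        cycle = self._find_cycle()
        if cycle:
            raise ValueError(f"is_a cycle detected: {' -> '.join(cycle)}")

    def _find_cycle(self) -> list[str] | None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return [e[0] for e in cyc] + [cyc[-1][1]]

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {t: [] for t in self.parents}
        for c, ps in self.parents.items():
            for p in ps:
                ch[p].append(c)
        return ch

    def ancestors(self, term: str, inclusive: bool = True) -> frozenset[str]:
        """Transitive is_a closure of ``term`` (including the term itself
        when ``inclusive``)."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestors_cache.get(term)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents[term])
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self.parents[t])
            cached = frozenset(out)
            self._ancestors_cache[term] = cached
        return cached | {term} if inclusive else cached

    def descendant_counts(self) -> dict[str, int]:
        """Number of strict descendants of each term."""
        counts = {t: set() for t in self.parents}
        for t in self.parents:
            for a in self.ancestors(t, inclusive=False):
                counts[a].add(t)
        return {t: len(s) for t, s in counts.items()}


def parse_obo(source) -> OntologyDAG:
    """Read an OBO 1.2 ontology into an :class:`OntologyDAG`.

    Only [Term] stanzas with id, name, is_a and is_obsolete are
    interpreted; obsolete terms (and edges to them) are dropped. Cycles
    and is_a targets that are not defined terms are rejected.
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)
    defined = {n for n, d in graph.nodes(data=True) if d}
    obsolete = {n for n in defined
                if str(graph.nodes[n].get("is_obsolete", "false")).lower() == "true"}
    live = defined - obsolete
    parents: dict[str, tuple[str, ...]] = {}
    names: dict[str, str] = {}
    for node in sorted(live, key=id_key):
        data = graph.nodes[node]
        names[node] = data.get("name", node)
        targets = []
        for t in data.get("is_a", []):
            if t in obsolete:
                continue  # edges into obsolete terms are dropped with them
            if t not in live:
                raise ValueError(f"term {node!r}: dangling is_a target {t!r}")
            targets.append(t)
        parents[node] = tuple(sorted(targets, key=id_key))
    return OntologyDAG(parents=parents, names=names)


def information_content(dag: OntologyDAG, mode: str = "intrinsic",
                        annotations: Mapping[str, int] | None = None) -> dict[str, float]:
    """Per-term information content in nats.

    Intrinsic mode uses the topology only: IC(t) = −ln((desc(t)+1)/N)
    where desc(t) counts strict descendants and N is the number of terms,
    so a root scores 0 and leaves score highest. Corpus mode uses
    annotation counts propagated to ancestors: IC(t) = −ln(n(t)/total).
    """
    if mode == "intrinsic":
        n = len(dag.parents)
        desc = dag.descendant_counts()
        return {t: abs(-math.log((desc[t] + 1) / n)) for t in dag.parents}
    if mode == "corpus":
        if annotations is None:
            raise ValueError("corpus mode requires annotation counts")
        total = sum(annotations.values())
        if total <= 0:
            raise ValueError("corpus mode requires a positive total annotation count")
        propagated = {t: 0 for t in dag.parents}
        for term, count in annotations.items():
            for a in dag.ancestors(term, inclusive=True):
                propagated[a] += count
        out = {}
        for t in dag.parents:
            p = propagated[t] / total
            out[t] = -math.log(p) if p > 0 else math.inf
        return out
    raise ValueError(f"unknown IC mode {mode!r}")


def mica(dag: OntologyDAG, ic: Mapping[str, float], a: str, b: str) -> str:
    """Most informative common ancestor of two terms (self included).

    Ties on IC break by ascending term id.
    """
    common = dag.ancestors(a, inclusive=True) & dag.ancestors(b, inclusive=True)
    if not common:
        raise ValueError(f"terms {a!r} and {b!r} share no ancestor (multi-rooted DAG)")
    return min(common, key=lambda t: (-ic[t], id_key(t)))


def semantic_similarity(dag: OntologyDAG, ic: Mapping[str, float], a: str, b: str,
                        metric: str = "lin") -> float:
    """Resnik / Lin / Jiang–Conrath similarity between two ontology terms.

    resnik = IC(MICA); lin = 2·IC(MICA)/(IC(a)+IC(b)) (0 when both ICs are
    0); jc = 1/(1 + IC(a)+IC(b)−2·IC(MICA)), the distance folded into a
    [0, 1] similarity so all three metrics rank "most similar" the same
    way up.
    """
    for t in (a, b):
        if t not in dag.parents:
            raise KeyError(f"unknown term {t!r}")
    m = mica(dag, ic, a, b)
    ic_m = ic[m]
    if metric == "resnik":
        return ic_m
    if metric == "lin":
        denom = ic[a] + ic[b]
        return 0.0 if denom == 0 else 2.0 * ic_m / denom
    if metric == "jc":
        dist = ic[a] + ic[b] - 2.0 * ic_m
        return 1.0 / (1.0 + dist)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class FeatureMatrix:
    """Fixed-dimension numeric vectors per item (the inputs to cosine)."""

    items: list[str]
    matrix: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.items):
            raise ValueError("matrix must be (n_items, n_features)")
        self._index = {item: i for i, item in enumerate(self.items)}

    def vector(self, item: str) -> np.ndarray:
        return self.matrix[self._index[item]]

    def __contains__(self, item: str) -> bool:
        return item in self._index


def aggregate_features(member_rows: pd.DataFrame, item_col: str = "item") -> FeatureMatrix:
    """Mean-aggregate per-member feature rows into one vector per item.

    E.g. averaging the member stars' longitude/latitude/parallax into a
    per-cluster vector. Items whose mean has any non-finite component are
    omitted with a warning.
    """
    if member_rows.empty:
        raise ValueError("no member rows to aggregate")
    feature_cols = [c for c in member_rows.columns if c != item_col]
    means = member_rows.groupby(item_col, sort=False)[feature_cols].mean()
    finite = np.isfinite(means.to_numpy()).all(axis=1)
    for item in means.index[~finite]:
        logger.warning("item %s dropped: non-finite mean feature", item)
    means = means[finite]
    means.index = means.index.astype(str)
    items = sorted(means.index, key=id_key)
    return FeatureMatrix(items=items, matrix=means.reindex(items).to_numpy(),
                         feature_names=tuple(feature_cols))


def cosine_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """cos(x, y) = x·y / (‖x‖‖y‖) for two non-zero vectors of equal length."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(x, y) / (nx_ * ny_))


class SimilarityTable:
    """Symmetric item–item scores with top-n neighbour queries.

    Self-pairs are excluded. Neighbour lists order by (score descending,
    item id ascending).
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, list[tuple[str, float]]] = {}
        if pairs:
            for (a, b), s in pairs.items():
                self.add(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if id_key(a) <= id_key(b) else (b, a)

    def add(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        key = self._key(a, b)
        existing = self._scores.get(key)
        if existing is not None and existing != score:
            raise ValueError(f"conflicting scores for pair {key}: {existing} vs {score}")
        if existing is None:
            self._scores[key] = float(score)
            self._neighbors.setdefault(a, []).append((b, float(score)))
            self._neighbors.setdefault(b, []).append((a, float(score)))
            self._sorted = False

    def similarity(self, a: str, b: str) -> float | None:
        return self._scores.get(self._key(a, b))

    @property
    def items(self) -> set[str]:
        return set(self._neighbors)

    def __len__(self) -> int:
        return len(self._scores)

    def _ensure_sorted(self) -> None:
        if not getattr(self, "_sorted", False):
            for lst in self._neighbors.values():
                lst.sort(key=lambda t: (-t[1], id_key(t[0])))
            self._sorted = True

    def top_neighbors(self, item: str, n: int) -> list[tuple[str, float]]:
        """The ``n`` most similar known items to ``item`` (may be fewer)."""
        if n < 0:
            raise ValueError("n must be >= 0")
        self._ensure_sorted()
        return list(self._neighbors.get(item, ())[:n])

    def pairs(self) -> dict[tuple[str, str], float]:
        return dict(self._scores)


def build_similarity_table(items: Iterable[str],
                           scorer: Callable[[str, str], float],
                           top_n: int) -> SimilarityTable:
    """Score all item pairs and keep each item's ``top_n`` neighbours.

    A pair is stored (symmetrically) if it makes either endpoint's top-n
    list.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    items = sorted(set(items), key=id_key)
    scored: dict[tuple[str, str], float] = {}
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            scored[(a, b)] = float(scorer(a, b))
    per_item: dict[str, list[tuple[str, float]]] = {a: [] for a in items}
    for (a, b), s in scored.items():
        per_item[a].append((b, s))
        per_item[b].append((a, s))
    table = SimilarityTable()
    for a, lst in per_item.items():
        lst.sort(key=lambda t: (-t[1], id_key(t[0])))
        for b, s in lst[:top_n]:
            if table.similarity(a, b) is None:
                table.add(a, b, s)
    return table


def feature_similarity_table(features: FeatureMatrix, top_n: int) -> SimilarityTable:
    """Cosine-similarity neighbour table over a feature matrix.

    Vectorised equivalent of :func:`build_similarity_table` with a cosine
    scorer.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    m = features.matrix
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms == 0):
        bad = [features.items[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero feature vector for items {bad[:5]}")
    unit = m / norms[:, None]
    sims = unit @ unit.T
    items = features.items
    table = SimilarityTable()
    n = len(items)
    for i in range(n):
        row = [(items[j], float(sims[i, j])) for j in range(n) if j != i]
        row.sort(key=lambda t: (-t[1], id_key(t[0])))
        for b, s in row[:top_n]:
            if table.similarity(items[i], b) is None:
                table.add(items[i], b, s)
    return table


def read_similarity_table(source) -> SimilarityTable:
    """Read a TSV of ``item_a<TAB>item_b<TAB>score`` lines.

    Undirected pairs are stored once; a repeated pair with a different
    score is an error (with its line number).
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = open(source, encoding="utf-8")
        close = True
    else:
        handle, close = source, False
    try:
        table = SimilarityTable()
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric score {raw!r}") from exc
            try:
                table.add(a, b, score)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
        return table
    finally:
        if close:
            handle.close()


def write_similarity_table(table: SimilarityTable, sink) -> None:
    """Write each undirected pair once as ``item_a<TAB>item_b<TAB>score``."""
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        handle = open(sink, "w", encoding="utf-8")
        close = True
    else:
        handle, close = sink, False
    try:
        for (a, b), s in sorted(table.pairs().items(), key=lambda kv: (id_key(kv[0][0]), id_key(kv[0][1]))):
            handle.write(f"{a}\t{b}\t{s!r}\n")
    finally:
        if close:
            handle.close()
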