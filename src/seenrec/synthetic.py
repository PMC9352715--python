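"""Seeded generators for long-tail implicit-feedback data.

Real literature-derived interaction data show a Zipf long tail (a few
items collect most ratings), per-user sequence lengths from tens to
hundreds, publication years ordering each sequence, and — crucially for
sequence-aware models — a tendency for consecutive items to be related.
The generators here reproduce exactly those features at desk scale:
Zipf item popularity, seeded per-user lengths and years, a toy is_a
ontology, group-structured feature vectors, and sequences with a
planted "next item is similar to the current item" signal of tunable
strength q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._util import id_key
from .data import SequentialDataset
from .similarity import FeatureMatrix, OntologyDAG, SimilarityTable

__all__ = ["SyntheticSpec", "gen_interactions", "gen_planted_sequences",
           "gen_toy_ontology", "gen_feature_matrix"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic interaction generator.

    Defaults target the statistical shape of literature-derived datasets:
    500 users, 1000 items, Zipf exponent 1.2 (strong long tail), sequence
    lengths in [20, 80] with mean about 40 (interaction-matrix sparsity
    above 90%), and a 30-year publication window. ``q`` is the planted
    sequential-signal strength: the probability that each next item is
    drawn from the current item's top similarity neighbours instead of
    from global popularity.
    """

    n_users: int = 500
    n_items: int = 1000
    zipf_s: float = 1.2
    min_len: int = 20
    max_len: int = 80
    mean_len: float = 40.0
    year_range: tuple[int, int] = (1990, 2020)
    q: float = 0.0
    n_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be in [0, 1]")
        if self.n_items < 2:
            raise ValueError("need at least 2 items")


def _item_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"i{k:0{width}d}" for k in range(1, n + 1)]


def _zipf_probs(n: int, s: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** s
    return w / w.sum()


def _draw_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    # lognormal around the mean target, clipped into [min, max]
    sigma = 0.4
    mu = math.log(max(spec.mean_len, 1.0)) - sigma**2 / 2
    raw = int(round(rng.lognormal(mu, sigma)))
    return int(np.clip(raw, spec.min_len, spec.max_len))


def gen_planted_sequences(spec: SyntheticSpec,
                          similarity: SimilarityTable | Callable[[str], list[str]] | None = None
                          ) -> SequentialDataset:
    """Generate user sequences with a planted similarity-transition signal.

    Each user performs a walk over the catalogue: with probability ``q``
    the next item is drawn uniformly from the current item's top
    ``n_neighbors`` similarity neighbours, otherwise from the global Zipf
    popularity distribution (never repeating the current item). Years are
    sorted uniform draws, so each sequence is non-decreasing in year.
    With ``q = 0`` the walk is pure popularity sampling and the similarity
    source is not consulted.
    """
    if spec.q > 0 and similarity is None:
        raise ValueError("a similarity source is required when q > 0")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    items = _item_ids(spec.n_items)
    probs = _zipf_probs(spec.n_items, spec.zipf_s)

    if isinstance(similarity, SimilarityTable):
        def neighbors(item: str) -> list[str]:
            return [b for b, _ in similarity.top_neighbors(item, spec.n_neighbors)]
    elif callable(similarity):
        neighbors = similarity
    else:
        def neighbors(item: str) -> list[str]:
            return []

    width = len(str(spec.n_users))
    sequences: dict[str, list[tuple[str, int]]] = {}
    lo, hi = spec.year_range
    for u in range(1, spec.n_users + 1):
        length = _draw_length(spec, rng)
        years = np.sort(rng.integers(lo, hi + 1, size=length))
        seq: list[str] = []
        cur: str | None = None
        for _ in range(length):
            nxt = None
            if cur is not None and spec.q > 0 and rng.random() < spec.q:
                pool = [b for b in neighbors(cur) if b != cur]
                if pool:
                    nxt = pool[int(rng.integers(len(pool)))]
            while nxt is None or nxt == cur:
                nxt = items[int(rng.choice(spec.n_items, p=probs))]
            seq.append(nxt)
            cur = nxt
        sequences[f"u{u:0{width}d}"] = list(zip(seq, (int(y) for y in years)))
    return SequentialDataset(sequences=sequences, catalogue=set(items),
                             name="synthetic",
                             provenance=(f"gen_planted(q={spec.q},seed={spec.seed})",))


def gen_interactions(spec: SyntheticSpec) -> SequentialDataset:
    """Zipf-popularity interaction sequences with no sequential signal.

    Identical to :func:`gen_planted_sequences` with ``q = 0`` (same seed
    path), so the planted generator strictly generalises this one.
    """
    if spec.q != 0.0:
        spec = SyntheticSpec(**{**spec.__dict__, "q": 0.0})
    return gen_planted_sequences(spec, similarity=None)


def gen_toy_ontology(depth: int, branching: int, seed: int = 0,
                     extra_edge_frac: float = 0.1) -> OntologyDAG:
    """A rooted is_a tree plus a few extra shallower-level edges (a DAG).

    Terms are laid out level by level under a single root; each non-root
    level-d term is_a one level-(d-1) parent, and ``extra_edge_frac`` of
    terms gain a second is_a edge to a random term at a strictly
    shallower level (acyclicity is preserved by construction). Leaves are
    usable as catalogue items.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0B0]))
    levels: list[list[str]] = [["T0"]]
    parents: dict[str, tuple[str, ...]] = {"T0": ()}
    counter = 1
    for d in range(1, depth + 1):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                term = f"T{counter}"
                counter += 1
                parents[term] = (parent,)
                level.append(term)
        levels.append(level)
    # extra is_a edges: from a term at level >= 2 to a non-parent at a
    # strictly shallower level
    candidates = [t for d in range(2, depth + 1) for t in levels[d]]
    n_extra = int(round(extra_edge_frac * len(candidates)))
    for term in (candidates[i] for i in rng.permutation(len(candidates))[:n_extra]):
        term_level = next(d for d, lv in enumerate(levels) if term in lv)
        shallow = [t for d in range(term_level) for t in levels[d]]
        pool = [t for t in shallow if t not in parents[term]]
        if pool:
            extra = pool[int(rng.integers(len(pool)))]
            parents[term] = tuple(sorted(set(parents[term]) | {extra}, key=id_key))
    names = {t: f"term {t}" for t in parents}
    return OntologyDAG(parents=parents, names=names)


def gen_feature_matrix(n_items: int, n_groups: int, noise_sd: float, seed: int = 0,
                       dim: int | None = None,
                       items: list[str] | None = None) -> FeatureMatrix:
    """Group-structured item feature vectors for cosine similarity.

    Items are assigned round-robin to ``n_groups`` latent groups with
    orthonormal centroids (QR of a random matrix); each item's vector is
    its group centroid plus isotropic Gaussian noise. Within-group cosine
    therefore exceeds between-group cosine in expectation, and equals 1
    (resp. 0) exactly when ``noise_sd`` is 0.
    """
    if n_groups > n_items:
        raise ValueError("n_groups must be <= n_items")
    if dim is None:
        dim = max(8, n_groups)
    if dim < n_groups:
        raise ValueError("dim must be >= n_groups for orthonormal centroids")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEA7]))
    raw = rng.normal(size=(dim, n_groups))
    centroids, _ = np.linalg.qr(raw)
    centroids = centroids.T  # (n_groups, dim), orthonormal rows
    if items is None:
        items = _item_ids(n_items)
    elif len(items) != n_items:
        raise ValueError("items list length must equal n_items")
    groups = np.arange(n_items) % n_groups
    matrix = centroids[groups] + rng.normal(scale=noise_sd, size=(n_items, dim))
    return FeatureMatrix(items=list(items), matrix=matrix,
                         feature_names=tuple(f"f{d}" for d in range(dim)))
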