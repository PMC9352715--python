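"""Sequence enrichment (SeEn): inject similar items into user sequences.

After each original item in a user's sequence, the transform inserts
that item's n most similar items (descending similarity), densifying
the interaction matrix before a sequence-aware recommender is trained.
A random-injection control inserts n uniformly drawn items instead, to
separate the effect of *similar* items from the effect of sheer length.

Enrichment is train-only: the validation and test targets of the
leave-one-out split are never enriched, so the evaluation target cannot
leak into the model's input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from ._util import derive_rng, id_key
from .data import CsvDialect
from .evaluation import EvalSplit
from .similarity import SimilarityTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentConfig",
    "EnrichedItem",
    "EnrichedSplit",
    "enrich_sequence",
    "enrich_random",
    "enrich_dataset",
    "original_items",
    "write_enriched",
    "read_enriched",
]

ORIGINAL = "original"
INJECTED = "injected"


class EnrichedItem(NamedTuple):
    """One position of an enriched sequence.

    Injected items carry the anchor (the original item that pulled them
    in) and inherit its year; they receive the same unit rating, though
    the anchor/origin fields leave room for similarity-valued ratings.
    """

    item: str
    origin: str  # ORIGINAL or INJECTED
    anchor: str | None
    year: int


@dataclass(frozen=True)
class EnrichmentConfig:
    """How to enrich: n items per anchor, similar vs random, seed for random."""

    n: int = 1
    mode: str = "similar"  # "similar" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.mode not in ("similar", "random"):
            raise ValueError(f"unknown enrichment mode {self.mode!r}")


def _as_pairs(seq: Sequence) -> list[tuple[str, int]]:
    out = []
    for entry in seq:
        if isinstance(entry, tuple):
            out.append((entry[0], int(entry[1])))
        else:
            out.append((str(entry), 0))
    return out


def enrich_sequence(seq: Sequence, table: SimilarityTable, n: int) -> list[EnrichedItem]:
    """Insert each item's top-n similarity neighbours right after it.

    ``seq`` is a list of item ids or of (item, year) pairs. Anchors
    missing from the table inject nothing (real similarity tables are
    incomplete); the anchor itself is never injected; duplicates with
    items elsewhere in the sequence are allowed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    out: list[EnrichedItem] = []
    for item, year in _as_pairs(seq):
        out.append(EnrichedItem(item, ORIGINAL, None, year))
        if n == 0:
            continue
        neighbors = table.top_neighbors(item, n)  # self-pairs cannot occur in a table
        if not neighbors and item not in table.items:
            logger.debug("anchor %s absent from similarity table; nothing injected", item)
        for b, _score in neighbors:
            out.append(EnrichedItem(b, INJECTED, item, year))
    return out


def enrich_random(seq: Sequence, catalogue: Sequence[str], n: int, seed: int) -> list[EnrichedItem]:
    """Control transform: insert n uniform random items after each anchor.

    Draws are without replacement from the catalogue minus the anchor,
    independently per anchor position, reproducible from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    catalogue = sorted(set(catalogue), key=id_key)
    if not catalogue:
        raise ValueError("catalogue must be non-empty")
    if n > len(catalogue) - 1:
        raise ValueError(f"cannot draw {n} distinct items from a catalogue of {len(catalogue)}")
    rng = derive_rng(seed, "enrich_random")
    out: list[EnrichedItem] = []
    for item, year in _as_pairs(seq):
        out.append(EnrichedItem(item, ORIGINAL, None, year))
        if n == 0:
            continue
        pool = [c for c in catalogue if c != item]
        picks = rng.choice(len(pool), size=n, replace=False)
        for idx in picks:
            out.append(EnrichedItem(pool[idx], INJECTED, item, year))
    return out


@dataclass
class EnrichedSplit:
    """A leave-one-out split whose training prefixes have been enriched.

    ``max_seq_multiplier`` is (n+1): the model-side window grows from
    base_max to base_max × (n+1) so enrichment does not crowd out the
    original items.
    """

    train: dict[str, list[EnrichedItem]]
    val: dict[str, tuple[str, int]]
    test: dict[str, tuple[str, int]]
    config: EnrichmentConfig
    max_seq_multiplier: int = 1

    def train_items(self, user: str) -> list[str]:
        return [e.item for e in self.train[user]]


def enrich_dataset(split: EvalSplit, cfg: EnrichmentConfig,
                   table: SimilarityTable | None = None,
                   catalogue: Sequence[str] | None = None) -> EnrichedSplit:
    """Enrich every user's training prefix; leave val/test untouched."""
    train: dict[str, list[EnrichedItem]] = {}
    for user in split.train:
        seq = split.train[user]
        if cfg.mode == "similar":
            if table is None:
                raise ValueError("similar mode needs a similarity table")
            train[user] = enrich_sequence(seq, table, cfg.n)
        else:
            if catalogue is None:
                raise ValueError("random mode needs a catalogue")
            # per-user derived seed keeps draws independent across users
            user_seed = int(derive_rng(cfg.seed, "enrich_user", user).integers(2**31))
            train[user] = enrich_random(seq, catalogue, cfg.n, user_seed)
    return EnrichedSplit(train=train, val=dict(split.val), test=dict(split.test),
                         config=cfg, max_seq_multiplier=cfg.n + 1)


def original_items(enriched: Sequence[EnrichedItem]) -> list[tuple[str, int]]:
    """Project an enriched sequence back to its original (item, year) list."""
    return [(e.item, e.year) for e in enriched if e.origin == ORIGINAL]


def write_enriched(enriched: dict[str, list[EnrichedItem]], sink,
                   dialect: CsvDialect = CsvDialect()) -> None:
    """Serialise enriched sequences as CSV with extra origin/anchor columns."""
    close = False
    if isinstance(sink, (str, bytes)) or hasattr(sink, "__fspath__"):
        sink = open(sink, "w", encoding="utf-8", newline="")
        close = True
    try:
        sink.write("user,item,rating,year,origin,anchor\n")
        for user in sorted(enriched, key=id_key):
            for e in enriched[user]:
                sink.write(f"{user},{e.item},1,{e.year},{e.origin},{e.anchor or ''}\n")
    finally:
        if close:
            sink.close()


def read_enriched(source) -> dict[str, list[EnrichedItem]]:
    """Inverse of :func:`write_enriched`."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, encoding="utf-8")
        close = True
    try:
        out: dict[str, list[EnrichedItem]] = {}
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\r\n")
            if not line or lineno == 1:
                continue
            parts = line.split(",")
            if len(parts) != 6:
                raise ValueError(f"line {lineno}: expected 6 fields")
            user, item, _rating, year, origin, anchor = parts
            out.setdefault(user, []).append(
                EnrichedItem(item, origin, anchor or None, int(year)))
        return out
    finally:
        if close:
            source.close()
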