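"""Interaction tables and per-user item sequences.

The atomic record is an implicit-feedback interaction ``<user, item,
rating, year>`` where the rating is always 1 and the year orders the
items within each user. Sequences built from these records are the
object every transform and recommender in this package consumes.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from ._util import derive_rng, id_key

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "CsvDialect",
    "DEFAULT_DIALECT",
    "ARMSEQ_DIALECT",
    "SequentialDataset",
    "DatasetStats",
    "read_interactions",
    "write_interactions",
    "build_sequences",
    "filter_min_interactions",
    "truncate_max_sequence",
    "shuffle_sequences",
    "compute_stats",
]


@dataclass(frozen=True)
class Interaction:
    """One user–item event. Ratings are unary (always 1) in this setting."""

    user_id: str
    item_id: str
    rating: int = 1
    year: int = 0
    item_name: str | None = None


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of an interaction CSV.

    ``columns`` names the fields in file order; allowed field names are
    user, item, rating, year, item_name. ``header`` says whether the file
    carries (and should be written with) a header row.
    """

    columns: tuple[str, ...] = ("user", "item", "rating", "year")
    header: bool = True
    delimiter: str = ","

    def __post_init__(self) -> None:
        allowed = {"user", "item", "rating", "year", "item_name"}
        unknown = set(self.columns) - allowed
        if unknown:
            raise ValueError(f"unknown dialect columns: {sorted(unknown)}")
        for required in ("user", "item", "rating", "year"):
            if required not in self.columns:
                raise ValueError(f"dialect is missing required column {required!r}")


DEFAULT_DIALECT = CsvDialect()
#: Five-column layout with the item name between rating and year, as used
#: by the astronomy (open-cluster) interaction tables.
ARMSEQ_DIALECT = CsvDialect(columns=("user", "item", "rating", "item_name", "year"))


@dataclass
class SequentialDataset:
    """Per-user year-ordered item sequences plus the item catalogue.

    ``sequences`` maps user id to an ordered list of ``(item_id, year)``
    pairs, non-decreasing in year. ``provenance`` records the filters and
    transforms that produced this dataset.
    """

    sequences: dict[str, list[tuple[str, int]]]
    catalogue: set[str] = field(default_factory=set)
    name: str = "dataset"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.catalogue:
            self.catalogue = {i for seq in self.sequences.values() for i, _ in seq}

    @property
    def n_users(self) -> int:
        return len(self.sequences)

    @property
    def n_items(self) -> int:
        return len(self.catalogue)

    @property
    def total_interactions(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def items_of(self, user: str) -> list[str]:
        return [i for i, _ in self.sequences[user]]

    def validate(self) -> None:
        """Check the structural invariants (year order, catalogue closure)."""
        for user, seq in self.sequences.items():
            years = [y for _, y in seq]
            if any(a > b for a, b in zip(years, years[1:])):
                raise ValueError(f"sequence of user {user!r} is not year-ordered")
            missing = {i for i, _ in seq} - self.catalogue
            if missing:
                raise ValueError(f"user {user!r} has items outside the catalogue: {sorted(missing)[:5]}")

    def _evolve(self, sequences, note: str) -> "SequentialDataset":
        return SequentialDataset(
            sequences=sequences,
            catalogue={i for seq in sequences.values() for i, _ in seq},
            name=self.name,
            provenance=self.provenance + (note,),
        )


@dataclass(frozen=True)
class DatasetStats:
    """Summary statistics of a sequential dataset (size, long tail, sparsity)."""

    total_interactions: int
    n_users: int
    n_items: int
    min_seq: int
    max_seq: int
    mean_seq: float
    year_range: tuple[int, int]
    sparsity: float
    percentile_shares: dict[int, float]
    top_item: tuple[str, int]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["percentile_shares"] = {str(k): v for k, v in d["percentile_shares"].items()}
        return json.dumps(d, indent=2)

    def to_table(self) -> str:
        rows = [
            ("total interactions", self.total_interactions),
            ("users", self.n_users),
            ("items", self.n_items),
            ("min seq", self.min_seq),
            ("max seq", self.max_seq),
            ("mean seq", f"{self.mean_seq:.2f}"),
            ("year range", f"{self.year_range[0]}-{self.year_range[1]}"),
            ("sparsity", f"{self.sparsity:.4f}"),
            ("top item", f"{self.top_item[0]} ({self.top_item[1]} ratings)"),
        ]
        rows += [(f"top {p}% item share", f"{s:.4f}") for p, s in sorted(self.percentile_shares.items())]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _open_maybe_gzip(source, mode: str) -> IO:
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        path = str(source)
        if path.endswith(".gz"):
            return gzip.open(path, mode + "t", encoding="utf-8")
        return open(path, mode, encoding="utf-8", newline="")
    return source


def read_interactions(source, dialect: CsvDialect = DEFAULT_DIALECT) -> list[Interaction]:
    """Parse a delimited interaction table into a list of records.

    ``source`` is a path (gzip-transparent) or a text stream. Row order is
    preserved. Malformed rows (wrong arity, non-integer rating/year) raise
    ``ValueError`` naming the line number.
    """
    handle = _open_maybe_gzip(source, "r")
    close = handle is not source
    try:
        records: list[Interaction] = []
        ncols = len(dialect.columns)
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            if dialect.header and lineno == 1:
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) != ncols:
                raise ValueError(
                    f"line {lineno}: expected {ncols} fields, got {len(parts)}"
                )
            row = dict(zip(dialect.columns, parts))
            try:
                rating = int(row["rating"])
                year = int(row["year"])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer rating or year") from exc
            records.append(
                Interaction(
                    user_id=row["user"],
                    item_id=row["item"],
                    rating=rating,
                    year=year,
                    item_name=row.get("item_name"),
                )
            )
        return records
    finally:
        if close:
            handle.close()


def write_interactions(ds: SequentialDataset, sink, dialect: CsvDialect = DEFAULT_DIALECT,
                       item_names: Mapping[str, str] | None = None) -> None:
    """Write a dataset back to the interaction CSV format (rating always 1).

    Round-trips with :func:`read_interactions` + :func:`build_sequences`.
    """
    handle = _open_maybe_gzip(sink, "w")
    close = handle is not sink
    try:
        if dialect.header:
            handle.write(dialect.delimiter.join(dialect.columns) + "\n")
        for user in user_order(ds.sequences):
            for item, year in ds.sequences[user]:
                row = {
                    "user": user,
                    "item": item,
                    "rating": "1",
                    "year": str(year),
                    "item_name": (item_names or {}).get(item, ""),
                }
                handle.write(dialect.delimiter.join(row[c] for c in dialect.columns) + "\n")
    finally:
        if close:
            handle.close()


def user_order(sequences: Mapping[str, object]) -> list[str]:
    """Deterministic user order for serialisation."""
    return sorted(sequences, key=id_key)


def build_sequences(records: Iterable[Interaction], dedup: str = "first",
                    tie_break: str = "item_id", seed: int = 0,
                    name: str = "dataset") -> SequentialDataset:
    """Order each user's interactions by publication year into a sequence.

    Same-year interactions have no inherent order; ``tie_break="item_id"``
    sorts them by ascending item id for reproducibility, ``"random"`` uses a
    seeded per-user permutation. ``dedup="first"`` (default) keeps each
    user–item pair once, at its earliest year; ``"keep-all"`` retains
    repeats.
    """
    if dedup not in ("first", "keep-all"):
        raise ValueError(f"unknown dedup policy {dedup!r}")
    if tie_break not in ("item_id", "random"):
        raise ValueError(f"unknown tie_break policy {tie_break!r}")
    per_user: dict[str, list[Interaction]] = {}
    for rec in records:
        if rec.rating != 1:
            raise ValueError(f"implicit-feedback rating must be 1, got {rec.rating}")
        per_user.setdefault(rec.user_id, []).append(rec)

    sequences: dict[str, list[tuple[str, int]]] = {}
    for user, recs in per_user.items():
        if tie_break == "item_id":
            recs = sorted(recs, key=lambda r: (r.year, id_key(r.item_id)))
        else:
            rng = derive_rng(seed, "tie_break", user)
            jitter = rng.random(len(recs))
            recs = [r for _, r in sorted(zip(jitter, recs), key=lambda t: (t[1].year, t[0]))]
        if dedup == "first":
            seen: set[str] = set()
            kept = []
            for r in recs:
                if r.item_id not in seen:
                    seen.add(r.item_id)
                    kept.append(r)
            recs = kept
        sequences[user] = [(r.item_id, r.year) for r in recs]
    return SequentialDataset(sequences=sequences, name=name,
                             provenance=(f"build(dedup={dedup},tie_break={tie_break})",))


def filter_min_interactions(ds: SequentialDataset, min_len: int = 20) -> SequentialDataset:
    """Drop users with fewer than ``min_len`` interactions (cold-start guard)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = {u: s for u, s in ds.sequences.items() if len(s) >= min_len}
    return ds._evolve(kept, f"min_len={min_len}")


def truncate_max_sequence(ds: SequentialDataset, max_len: int) -> SequentialDataset:
    """Cap each sequence at its ``max_len`` most recent items (suffix kept).

    The suffix is kept because leave-one-out evaluation hides the final
    item; dropping the tail would drop the test target.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    truncated = {u: s[-max_len:] for u, s in ds.sequences.items()}
    return ds._evolve(truncated, f"max_len={max_len}")


def shuffle_sequences(ds: SequentialDataset, seed: int, fix_last: int = 2) -> SequentialDataset:
    """Destroy within-user order while pinning the evaluation targets.

    The last ``fix_last`` positions (test item, and by default also the
    validation item) stay where they are; the remaining prefix is permuted
    by a per-user stream derived from ``seed``. Years travel with their
    items, so the shuffled dataset intentionally breaks year monotonicity —
    that is the point of the ablation.
    """
    if fix_last < 1:
        raise ValueError("fix_last must be >= 1 (the test item is always pinned)")
    shuffled = {}
    for user, seq in ds.sequences.items():
        cut = max(len(seq) - fix_last, 0)
        prefix = list(seq[:cut])
        rng = derive_rng(seed, "shuffle", user)
        rng.shuffle(prefix)
        shuffled[user] = prefix + list(seq[cut:])
    out = ds._evolve(shuffled, f"shuffled(seed={seed},fix_last={fix_last})")
    return out


def compute_stats(ds: SequentialDataset, percentiles: Sequence[int] = (1, 5, 10)) -> DatasetStats:
    """Dataset summary: sizes, year span, sparsity, and long-tail shares.

    Sparsity is 1 − (unique user–item pairs)/(users × items). The p%
    share is the fraction of all ratings received by the ceil(p% × n_items)
    most-rated items.
    """
    if not ds.sequences:
        raise ValueError("cannot compute statistics of an empty dataset")
    lengths = [len(s) for s in ds.sequences.values()]
    counts: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    years: list[int] = []
    for user, seq in ds.sequences.items():
        for item, year in seq:
            counts[item] = counts.get(item, 0) + 1
            pairs.add((user, item))
            years.append(year)
    total = sum(counts.values())
    n_users, n_items = ds.n_users, ds.n_items
    by_count = sorted(counts.items(), key=lambda kv: (-kv[1], id_key(kv[0])))
    shares = {}
    cum = 0
    idx = 0
    for p in sorted(percentiles):
        top_k = math.ceil(p / 100 * n_items)
        while idx < min(top_k, len(by_count)):
            cum += by_count[idx][1]
            idx += 1
        shares[p] = cum / total
    # top item's count is in unique users, matching "n users who rated it"
    per_item_users: dict[str, set[str]] = {}
    for user, item in pairs:
        per_item_users.setdefault(item, set()).add(user)
    top = sorted(((i, len(us)) for i, us in per_item_users.items()),
                 key=lambda kv: (-kv[1], id_key(kv[0])))[0]
    return DatasetStats(
        total_interactions=total,
        n_users=n_users,
        n_items=n_items,
        min_seq=min(lengths),
        max_seq=max(lengths),
        mean_seq=total / n_users,
        year_range=(min(years), max(years)),
        sparsity=1.0 - len(pairs) / (n_users * n_items),
        percentile_shares=shares,
        top_item=top,
    )
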