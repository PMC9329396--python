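"""Domain types and I/O for forced-choice paired-comparison data.

The unit of observation is a single judgment: a subject tastes two items in
a fixed order and states which one they prefer.  Data live in two
interchangeable shapes:

* long format — one :class:`ComparisonRecord` per judgment, carrying the
  presentation order;
* aggregated — a pair of square count matrices (:class:`CountMatrices`):
  ordered-pair comparison counts and order-aggregated win counts.

Aggregation loses the per-order outcome breakdown, so order-effect models
require long-format data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemSet",
    "ComparisonRecord",
    "CountMatrices",
    "ValidationReport",
    "read_records",
    "write_records",
    "aggregate",
    "validate",
    "read_count_matrix",
    "write_count_matrix",
    "load_fixture_counts",
]

RECORD_COLUMNS = ("subject", "first", "second", "preferred")


class DataError(ValueError):
    """Invalid paired-comparison data."""


@dataclass(frozen=True)
class ItemSet:
    """Ordered collection of unique item labels.

    The order is significant: it fixes row/column order in every matrix,
    table and report derived from the data.
    """

    items: tuple[str, ...]

    def __init__(self, items: Iterable[str]):
        labels = tuple(str(x) for x in items)
        if len(labels) < 2:
            raise DataError("an ItemSet needs at least 2 items")
        if len(set(labels)) != len(labels):
            raise DataError("item labels must be unique")
        object.__setattr__(self, "items", labels)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, label: object) -> bool:
        return label in self.items

    def index(self, label: str) -> int:
        try:
            return self.items.index(label)
        except ValueError:
            raise DataError(f"unknown item label {label!r}") from None

    @classmethod
    def standard(cls, n: int, prefix: str = "A") -> "ItemSet":
        """Labels ``A1 … An`` in the study's naming convention."""
        return cls(f"{prefix}{i}" for i in range(1, n + 1))


@dataclass(frozen=True)
class ComparisonRecord:
    """One forced-choice judgment.

    ``first``/``second`` record presentation order; ``preferred`` must be
    one of the two.  Ties are not representable: the study design forces a
    choice.
    """

    subject: str
    first: str
    second: str
    preferred: str

    def __post_init__(self):
        if self.first == self.second:
            raise DataError(
                f"degenerate pair: subject {self.subject!r} compares "
                f"{self.first!r} with itself"
            )
        if self.preferred not in (self.first, self.second):
            raise DataError(
                f"preferred item {self.preferred!r} is not among the pair "
                f"({self.first!r}, {self.second!r})"
            )

    @property
    def winner_was_first(self) -> bool:
        return self.preferred == self.first


@dataclass(frozen=True)
class CountMatrices:
    """Aggregated comparison and win counts over a fixed :class:`ItemSet`.

    ``comparisons[i, j]`` counts judgments with item *i* tasted first and
    *j* second; ``wins[i, j]`` counts judgments in which *i* was preferred
    over *j*, regardless of order.  Both matrices have a zero diagonal and,
    for consistent data, ``wins + wins.T == comparisons + comparisons.T``
    elementwise.
    """

    items: ItemSet
    comparisons: np.ndarray
    wins: np.ndarray

    def __post_init__(self):
        m = len(self.items)
        for name in ("comparisons", "wins"):
            a = np.asarray(getattr(self, name), dtype=np.int64)
            if a.shape != (m, m):
                raise DataError(f"{name} matrix must be {m}x{m}, got {a.shape}")
            if (a < 0).any():
                raise DataError(f"{name} matrix has negative entries")
            if np.diag(a).any():
                raise DataError(f"{name} matrix has a nonzero diagonal")
            object.__setattr__(self, name, a)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def total(self) -> int:
        """Total number of judgments (sum of the win matrix)."""
        return int(self.wins.sum())

    @property
    def pair_totals(self) -> np.ndarray:
        """Symmetric matrix of judgments per unordered pair."""
        return self.wins + self.wins.T


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate`; reports, never repairs."""

    total_judgments: int
    pair_failures: tuple[tuple[str, str, int, int], ...]
    win_tallies: dict[str, int]
    loss_tallies: dict[str, int]
    strongly_connected: bool
    items_without_wins: tuple[str, ...] = field(default=())
    items_without_losses: tuple[str, ...] = field(default=())

    @property
    def consistent(self) -> bool:
        return not self.pair_failures

    @property
    def ok(self) -> bool:
        return self.consistent and self.strongly_connected


def read_records(
    source: str | Path | IO[str], items: ItemSet | None = None
) -> list[ComparisonRecord]:
    """Read long-format judgments from CSV.

    Expects columns ``subject,first,second,preferred``.  If *items* is
    given, every label is checked against it; otherwise the item set is
    implied by the data.
    """
    df = pd.read_csv(source, dtype=str, comment="#")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing columns: {', '.join(missing)}")
    records = [
        ComparisonRecord(row.subject, row.first, row.second, row.preferred)
        for row in df.itertuples(index=False)
    ]
    if items is not None:
        for r in records:
            for label in (r.first, r.second):
                if label not in items:
                    raise DataError(f"unknown item label {label!r}")
    return records


def write_records(records: Sequence[ComparisonRecord], dest: str | Path | IO[str]) -> None:
    """Write long-format judgments as CSV with the standard header."""
    df = pd.DataFrame(
        [(r.subject, r.first, r.second, r.preferred) for r in records],
        columns=list(RECORD_COLUMNS),
    )
    df.to_csv(dest, index=False)


def infer_items(records: Sequence[ComparisonRecord]) -> ItemSet:
    """Item set implied by a record list, in order of first appearance."""
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.first)
        seen.setdefault(r.second)
    return ItemSet(seen)


def aggregate(
    records: Sequence[ComparisonRecord], items: ItemSet | None = None
) -> CountMatrices:
    """Aggregate judgments into ordered-comparison and win count matrices."""
    if items is None:
        if not records:
            raise DataError("cannot infer an ItemSet from an empty record list")
        items = infer_items(records)
    m = len(items)
    comparisons = np.zeros((m, m), dtype=np.int64)
    wins = np.zeros((m, m), dtype=np.int64)
    for r in records:
        i, j = items.index(r.first), items.index(r.second)
        comparisons[i, j] += 1
        if r.winner_was_first:
            wins[i, j] += 1
        else:
            wins[j, i] += 1
    return CountMatrices(items, comparisons, wins)


def validate(counts: CountMatrices) -> ValidationReport:
    """Check the consistency identities of a :class:`CountMatrices`.

    Reports the total judgment count, per-pair consistency
    (``W[i,j]+W[j,i] == C[i,j]+C[j,i]``), per-item win/loss tallies, and
    whether the win digraph (edge i→j when i ever beat j) is strongly
    connected — the condition under which the Bradley–Terry maximum
    likelihood estimate is finite.  Inconsistencies are itemized, never
    silently repaired.
    """
    import networkx as nx

    items = counts.items
    C, W = counts.comparisons, counts.wins
    failures = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            w_sum = int(W[i, j] + W[j, i])
            c_sum = int(C[i, j] + C[j, i])
            if w_sum != c_sum:
                failures.append((items.items[i], items.items[j], w_sum, c_sum))

    win_tallies = {lab: int(W[k].sum()) for k, lab in enumerate(items)}
    loss_tallies = {lab: int(W[:, k].sum()) for k, lab in enumerate(items)}

    g = nx.DiGraph()
    g.add_nodes_from(range(len(items)))
    g.add_edges_from(zip(*np.nonzero(W)))
    connected = nx.is_strongly_connected(g)

    return ValidationReport(
        total_judgments=counts.total,
        pair_failures=tuple(failures),
        win_tallies=win_tallies,
        loss_tallies=loss_tallies,
        strongly_connected=connected,
        items_without_wins=tuple(lab for lab, t in win_tallies.items() if t == 0),
        items_without_losses=tuple(lab for lab, t in loss_tallies.items() if t == 0),
    )


def read_count_matrix(source: str | Path | IO[str], items: ItemSet | None = None):
    """Read a square count matrix CSV (item labels as header row/column)."""
    df = pd.read_csv(source, index_col=0, comment="#")
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    if list(df.columns) != list(df.index):
        raise DataError("matrix row and column labels differ")
    found = ItemSet(df.columns)
    if items is not None:
        if tuple(items) != tuple(found):
            raise DataError(
                f"matrix labels {list(found)} do not match the expected "
                f"item set {list(items)}"
            )
        found = items
    return found, df.to_numpy(dtype=np.int64)


def write_count_matrix(
    items: ItemSet, matrix: np.ndarray, dest: str | Path | IO[str], comment: str | None = None
) -> None:
    """Write a square count matrix as CSV, preserving item order."""
    df = pd.DataFrame(np.asarray(matrix, dtype=np.int64),
                      index=list(items), columns=list(items))
    buf = io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf)
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def load_fixture_counts() -> CountMatrices:
    """The bundled eight-thickener study counts (ordered comparisons and wins)."""
    pkg = resources.files("pairpref") / "fixtures"
    with (pkg / "table2_comparisons.csv").open() as fh:
        items, comparisons = read_count_matrix(fh)
    with (pkg / "table3_wins.csv").open() as fh:
        items2, wins = read_count_matrix(fh, items)
    return CountMatrices(items, comparisons, wins)
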