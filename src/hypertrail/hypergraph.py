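"""Temporal hypergraph data model, file I/O, filtering and splitting.

A temporal hypergraph is a sequence of hypergraph snapshots indexed by
discrete time (here: publication year remapped to a 0-based index).  Each
hyperedge is the unique set of concepts attached to one article.  This
module provides the containers plus the dataset-preparation steps used
throughout the pipeline: size filtering, time-sliced train/validation/test
splitting with a random halving of the validation period, removal of
val/test hyperedges whose member sets already occur in training, and
incidence-matrix construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ConceptVocabulary",
    "Hyperedge",
    "TemporalHypergraph",
    "IncidenceMatrix",
    "DatasetSplits",
    "HypergraphParseError",
    "read_hyperedges",
    "write_hyperedges",
    "filter_by_size",
    "split_by_period",
    "remove_split_leakage",
    "incidence",
    "subgraph",
]


class HypergraphParseError(ValueError):
    """Raised when an input record cannot be parsed; names the line number."""


@dataclass(frozen=True)
class ConceptVocabulary:
    """Ordered set of concept labels with contiguous integer ids."""

    labels: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "ConceptVocabulary":
        seen: dict[str, int] = {}
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen)
        return cls(labels=tuple(seen), index=seen)

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.labels)


@dataclass(frozen=True)
class Hyperedge:
    """One article: a set of concept ids observed at one time step."""

    id: int
    timestamp: int
    members: frozenset[int]
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"hyperedge {self.id} has no members")
        if self.timestamp < 0:
            raise ValueError(f"hyperedge {self.id} has negative timestamp")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TemporalHypergraph:
    """Year-indexed snapshots of concept-set hyperedges over a shared vocabulary.

    ``snapshots`` maps consecutive integer time indices ``0..T`` to the list
    of hyperedges observed at that step; ``years`` records the calendar year
    each index corresponds to (``years[0]`` is the origin).
    """

    vocabulary: ConceptVocabulary
    snapshots: dict[int, list[Hyperedge]]
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        keys = sorted(self.snapshots)
        if keys and keys != list(range(keys[0], keys[-1] + 1)):
            raise ValueError("snapshot keys must be consecutive integers")
        if keys and keys[0] != 0:
            raise ValueError("snapshot keys must start at 0")
        n = self.vocabulary.size
        for t, edges in self.snapshots.items():
            for e in edges:
                if e.timestamp != t:
                    raise ValueError(f"hyperedge {e.id} filed under wrong snapshot")
                if any(j < 0 or j >= n for j in e.members):
                    raise ValueError(f"hyperedge {e.id} has out-of-vocabulary member")

    @property
    def year_origin(self) -> int:
        return self.years[0] if self.years else 0

    @property
    def num_steps(self) -> int:
        return len(self.snapshots)

    def hyperedges(self) -> Iterator[Hyperedge]:
        for t in sorted(self.snapshots):
            yield from self.snapshots[t]

    @property
    def num_hyperedges(self) -> int:
        return sum(len(v) for v in self.snapshots.values())

    def year_of(self, t: int) -> int:
        return self.years[t]

    def step_of_year(self, year: int) -> int | None:
        try:
            return self.years.index(year)
        except ValueError:
            return None


@dataclass
class IncidenceMatrix:
    """Binary concepts x hyperedges membership matrix H."""

    entries: np.ndarray  # (N, M) float array with 0/1 entries
    column_index: dict[int, int]  # hyperedge id -> column

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass
class DatasetSplits:
    """Time-sliced splits: train, optimisation-half and trail-half of the
    validation period, and test, with the year ranges that produced them."""

    train: list[Hyperedge]
    val_opt: list[Hyperedge]
    val_trail: list[Hyperedge]
    test: list[Hyperedge]
    boundaries: dict[str, tuple[int, int]]


def _build(records: list[tuple[str, int, list[str]]]) -> TemporalHypergraph:
    vocab = ConceptVocabulary.from_labels(
        lab for _, _, labs in records for lab in labs
    )
    years_present = sorted({y for _, y, _ in records})
    year_to_t = {y: t for t, y in enumerate(years_present)}
    snapshots: dict[int, list[Hyperedge]] = {t: [] for t in range(len(years_present))}
    for eid, (src, year, labs) in enumerate(records):
        t = year_to_t[year]
        members = frozenset(vocab.index[lab] for lab in labs)
        snapshots[t].append(Hyperedge(id=eid, timestamp=t, members=members, source_id=src))
    return TemporalHypergraph(vocabulary=vocab, snapshots=snapshots, years=tuple(years_present))


def read_hyperedges(path, dialect: str = "jsonl") -> TemporalHypergraph:
    """Read year-stamped hyperedge records from JSONL or TSV.

    JSONL: one object per line, keys ``id`` (string), ``year`` (int),
    ``concepts`` (list of strings).  TSV: columns id, year,
    semicolon-joined concepts.  Duplicate concept labels inside one record
    are collapsed, so each hyperedge is the article's *unique* concept set.
    Years are remapped to 0-based consecutive indices preserving order.
    """
    if dialect not in ("jsonl", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[tuple[str, int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "jsonl":
                    obj = json.loads(line)
                    src, year, labs = str(obj["id"]), int(obj["year"]), list(obj["concepts"])
                else:
                    src, year_s, concepts_s = line.split("\t")
                    year, labs = int(year_s), concepts_s.split(";")
                labs = [str(x) for x in labs if str(x)]
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                raise HypergraphParseError(f"line {lineno}: malformed record ({exc})") from exc
            if not labs:
                raise HypergraphParseError(f"line {lineno}: record has zero concepts")
            records.append((src, year, labs))
    if not records:
        raise HypergraphParseError(f"{path}: no records found")
    return _build(records)


def write_hyperedges(th: TemporalHypergraph, path, dialect: str = "jsonl") -> None:
    """Write a hypergraph in the same dialect ``read_hyperedges`` accepts."""
    labels = th.vocabulary.labels
    with open(path, "w", encoding="utf-8") as fh:
        for e in th.hyperedges():
            labs = sorted(labels[j] for j in e.members)
            src = e.source_id if e.source_id is not None else str(e.id)
            year = th.year_of(e.timestamp)
            if dialect == "jsonl":
                fh.write(json.dumps({"id": src, "year": year, "concepts": labs}) + "\n")
            elif dialect == "tsv":
                fh.write(f"{src}\t{year}\t{';'.join(labs)}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def filter_by_size(
    th: TemporalHypergraph,
    min_size: int = 5,
    max_size: int = 30,
    compact_vocabulary: bool = True,
) -> TemporalHypergraph:
    """Discard hyperedges with fewer than ``min_size`` or more than
    ``max_size`` concepts (defaults 5 and 30, the noise filter used on the
    article-derived hypergraphs).

    When ``compact_vocabulary`` is set, concepts left with no surviving
    incidence are dropped and ids recompacted, since downstream positional
    encodings require degree >= 1.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("require 1 <= min_size <= max_size")
    kept = {
        t: [e for e in edges if min_size <= e.size <= max_size]
        for t, edges in th.snapshots.items()
    }
    if not compact_vocabulary:
        return TemporalHypergraph(th.vocabulary, kept, th.years)
    surviving = sorted({j for edges in kept.values() for e in edges for j in e.members})
    old_labels = th.vocabulary.labels
    vocab = ConceptVocabulary.from_labels(old_labels[j] for j in surviving)
    remap = {old: new for new, old in enumerate(surviving)}
    snapshots = {
        t: [replace(e, members=frozenset(remap[j] for j in e.members)) for e in edges]
        for t, edges in kept.items()
    }
    return TemporalHypergraph(vocab, snapshots, th.years)


def split_by_period(
    th: TemporalHypergraph,
    boundaries: dict[str, Sequence[int]],
    val_half_seed: int = 0,
) -> DatasetSplits:
    """Partition hyperedges into train/val/test by calendar-year ranges and
    randomly split the validation period in half.

    ``boundaries`` maps ``train``/``val``/``test`` to inclusive year ranges
    ``[y0, y1]``.  The validation half used for model optimisation
    (``val_opt``) receives the extra element when the count is odd; the
    other half (``val_trail``) stays available as test-time trail history.
    The halving is uniform at random and deterministic under
    ``val_half_seed``.
    """
    ranges = {k: (int(v[0]), int(v[1])) for k, v in boundaries.items()}
    for key in ("train", "val", "test"):
        if key not in ranges:
            raise ValueError(f"missing boundary {key!r}")
    order = [ranges["train"], ranges["val"], ranges["test"]]
    for (a0, a1), (b0, b1) in zip(order, order[1:]):
        if a1 >= b0 or a0 > a1:
            raise ValueError("year ranges must be disjoint and ordered")

    def in_range(e: Hyperedge, rng: tuple[int, int]) -> bool:
        y = th.year_of(e.timestamp)
        return rng[0] <= y <= rng[1]

    all_edges = list(th.hyperedges())
    train = [e for e in all_edges if in_range(e, ranges["train"])]
    val = [e for e in all_edges if in_range(e, ranges["val"])]
    test = [e for e in all_edges if in_range(e, ranges["test"])]
    for name, part in (("train", train), ("val", val), ("test", test)):
        if not part:
            warnings.warn(f"{name} split is empty for ranges {ranges[name]}")
    rng = np.random.default_rng(val_half_seed)
    perm = rng.permutation(len(val))
    n_opt = (len(val) + 1) // 2  # odd count: extra element goes to val_opt
    opt_idx = set(perm[:n_opt].tolist())
    val_opt = [e for i, e in enumerate(val) if i in opt_idx]
    val_trail = [e for i, e in enumerate(val) if i not in opt_idx]
    return DatasetSplits(train=train, val_opt=val_opt, val_trail=val_trail,
                         test=test, boundaries=ranges)


def remove_split_leakage(splits: DatasetSplits) -> DatasetSplits:
    """Drop every val/test hyperedge whose member set equals (as a set,
    ignoring timestamp and source id) the member set of any training
    hyperedge, so that evaluated concept combinations are genuinely unseen.
    """
    train_sets = {e.members for e in splits.train}
    keep = lambda part: [e for e in part if e.members not in train_sets]
    return DatasetSplits(
        train=list(splits.train),
        val_opt=keep(splits.val_opt),
        val_trail=keep(splits.val_trail),
        test=keep(splits.test),
        boundaries=dict(splits.boundaries),
    )


def incidence(hyperedges: Sequence[Hyperedge], vocab: ConceptVocabulary) -> IncidenceMatrix:
    """Build the binary incidence matrix H (concepts x hyperedges); entry
    (j, i) is 1 iff concept j belongs to hyperedge i.  Column order follows
    the input order."""
    n = vocab.size
    m = len(hyperedges)
    entries = np.zeros((n, m), dtype=float)
    column_index: dict[int, int] = {}
    for col, e in enumerate(hyperedges):
        for j in e.members:
            if j < 0 or j >= n:
                raise ValueError(f"member id {j} out of vocabulary range 0..{n - 1}")
            entries[j, col] = 1.0
        column_index[e.id] = col
    return IncidenceMatrix(entries=entries, column_index=column_index)


def subgraph(th: TemporalHypergraph, hyperedges: Iterable[Hyperedge]) -> TemporalHypergraph:
    """Restrict a hypergraph to the given hyperedges (vocabulary and time
    axis are preserved so ids and timestamps remain comparable)."""
    chosen = list(hyperedges)
    snapshots: dict[int, list[Hyperedge]] = {t: [] for t in th.snapshots}
    for e in chosen:
        snapshots[e.timestamp].append(e)
    return TemporalHypergraph(th.vocabulary, snapshots, th.years)
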