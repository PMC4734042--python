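"""Hit filtering, best-hit read assignment and functional profile aggregation.

A read's surviving hits are those passing all three thresholds; among them
only the hits sharing the minimum E-value count ("best hits", ties kept).
Each read contributes total weight 1, split equally over its distinct
hierarchy paths, so read counts are conserved at every level.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from subsysfocus.io_formats import TabularHit
from subsysfocus.subsystem_db import SubsystemPath

logger = logging.getLogger(__name__)

LEVELS = (1, 2, 3, "function")


@dataclass(frozen=True)
class FilterThresholds:
    max_evalue: float = 1e-5
    min_identity: float = 60.0
    min_aln_len: int = 15


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    paths: frozenset  # of SubsystemPath

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError(f"read {self.read_id!r} assigned an empty path set")

    @property
    def weight_per_path(self) -> float:
        return 1.0 / len(self.paths)


@dataclass
class FunctionalProfile:
    level: object
    abundance: dict[str, float] = field(default_factory=dict)
    read_counts: dict[str, float] = field(default_factory=dict)
    n_assigned: int = 0
    n_unassigned: int = 0


def filter_hits(hits: Iterable[TabularHit], thresholds: FilterThresholds | None = None
                ) -> list[TabularHit]:
    """Threshold filter then best-E-value selection (all ties) for one read.

    Boundaries are inclusive. E-values are compared exactly as parsed.
    """
    t = thresholds or FilterThresholds()
    hits = list(hits)
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("filter_hits expects hits of a single query")
    passing = [
        h
        for h in hits
        if h.evalue <= t.max_evalue
        and h.pct_identity >= t.min_identity
        and h.aln_length >= t.min_aln_len
    ]
    if not passing:
        return []
    best_e = min(h.evalue for h in passing)
    return [h for h in passing if h.evalue == best_e]


def assign_read(
    best_hits: list[TabularHit], path_map: Mapping[str, SubsystemPath]
) -> ReadAssignment | None:
    """Collapse a read's tied best hits into its distinct hierarchy paths."""
    if not best_hits:
        return None
    paths = set()
    for h in best_hits:
        try:
            paths.add(path_map[h.subject_id])
        except KeyError:
            raise KeyError(
                f"subject {h.subject_id!r} not present in the database annotation "
                "map (hits file and database do not match)"
            ) from None
    return ReadAssignment(read_id=best_hits[0].query_id, paths=frozenset(paths))


def group_hits_by_query(hits: Iterable[TabularHit]) -> Iterator[list[TabularHit]]:
    """Group a hit stream by query id (order-preserving; ids may interleave)."""
    groups: "defaultdict[str, list[TabularHit]]" = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.query_id not in groups:
            order.append(h.query_id)
        groups[h.query_id].append(h)
    for qid in order:
        yield groups[qid]


def assign_all(
    hits: Iterable[TabularHit],
    path_map: Mapping[str, SubsystemPath],
    thresholds: FilterThresholds | None = None,
) -> list[ReadAssignment]:
    out = []
    for group in group_hits_by_query(hits):
        assignment = assign_read(filter_hits(group, thresholds), path_map)
        if assignment is not None:
            out.append(assignment)
    return out


def aggregate_profile(
    assignments: Iterable[ReadAssignment],
    level,
    n_total_reads: int | None = None,
) -> FunctionalProfile:
    """Sum per-read weights by hierarchy label and normalize by assigned reads."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    counts: dict[str, float] = defaultdict(float)
    n_assigned = 0
    for a in assignments:
        n_assigned += 1
        w = a.weight_per_path
        for path in a.paths:
            counts[path.label(level)] += w
    if n_assigned == 0:
        warnings.warn("no reads were assigned; profile is empty", stacklevel=2)
        return FunctionalProfile(level=level,
                                 n_unassigned=n_total_reads or 0)
    abundance = {label: c / n_assigned for label, c in counts.items()}
    n_unassigned = (n_total_reads - n_assigned) if n_total_reads is not None else 0
    return FunctionalProfile(
        level=level,
        abundance=dict(sorted(abundance.items())),
        read_counts=dict(sorted(counts.items())),
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
    )


def measure_throughput(n_sequences: int, elapsed_seconds: float) -> tuple[float, float]:
    """(sequences per minute, seconds per sequence); logged, never asserted."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if elapsed_seconds <= 0:
        raise ValueError("elapsed_seconds must be positive")
    per_minute = 60.0 * n_sequences / elapsed_seconds
    per_sequence = elapsed_seconds / n_sequences
    logger.info("throughput: %.1f seq/min (%.4f s/seq)", per_minute, per_sequence)
    return per_minute, per_sequence
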