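"""Benchmarking: truth construction, sensitivity/precision, confusion
matrices, and hierarchical clustering of sample profiles.

Truth for a read set is the best hit(s) of the exhaustive Smith-Waterman
search against the full (100% cut-off) database under the default filter
thresholds; equal-lowest-E ties all count. A prediction is "correct" when
its label set at the requested level intersects the truth label set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import pdist

from subsysfocus.aligner.search import SearchParams, exhaustive_search
from subsysfocus.io_formats import SequenceRecord
from subsysfocus.profiler import (
    FilterThresholds,
    ReadAssignment,
    assign_all,
)
from subsysfocus.subsystem_db import ClusteredDatabase, SubsystemPath

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

# read_id -> set of SubsystemPath
TruthAnnotation = dict


@dataclass(frozen=True)
class EvalReport:
    level: object
    sensitivity: float | None  # percent, None when undefined
    precision: float | None
    n_truth: int
    n_classified: int
    n_correct: int


def make_truth(
    reads: Iterable[SequenceRecord],
    full_db: ClusteredDatabase,
    thresholds: FilterThresholds | None = None,
    params: SearchParams | None = None,
) -> TruthAnnotation:
    """Best-hit annotation via the exhaustive aligner against the full db."""
    hits = exhaustive_search(reads, full_db, params)
    assignments = assign_all(hits, full_db.representative_paths(), thresholds)
    return {a.read_id: set(a.paths) for a in assignments}


def _labels_at(paths: Iterable[SubsystemPath], level) -> set[str]:
    return {p.label(level) for p in paths}


def predictions_from_assignments(assignments: Iterable[ReadAssignment]) -> dict:
    return {a.read_id: set(a.paths) for a in assignments}


def evaluate(
    predicted: Mapping[str, set],
    truth: Mapping[str, set],
    level,
    include_reads: set[str] | None = None,
) -> EvalReport:
    """Sensitivity = correct / truth-annotated reads; precision = correct /
    classified reads (both x100). ``include_reads`` optionally masks the
    read universe before counting."""
    if include_reads is not None:
        predicted = {r: v for r, v in predicted.items() if r in include_reads}
        truth = {r: v for r, v in truth.items() if r in include_reads}
    n_truth = len(truth)
    n_classified = len(predicted)
    n_correct = 0
    for read_id, true_paths in truth.items():
        pred_paths = predicted.get(read_id)
        if not pred_paths:
            continue
        if _labels_at(pred_paths, level) & _labels_at(true_paths, level):
            n_correct += 1
    sensitivity = 100.0 * n_correct / n_truth if n_truth else None
    precision = 100.0 * n_correct / n_classified if n_classified else None
    return EvalReport(
        level=level,
        sensitivity=sensitivity,
        precision=precision,
        n_truth=n_truth,
        n_classified=n_classified,
        n_correct=n_correct,
    )


def confusion_matrix(
    predicted: Mapping[str, set],
    truth: Mapping[str, set],
    level=1,
) -> pd.DataFrame:
    """Row-normalized (percent) confusion matrix at one hierarchy level.

    Rows are truth labels; columns are predicted labels plus
    ``unclassified``. Ties spread a read's unit mass equally over its
    labels, so every row sums to 100.
    """
    truth_labels = sorted(set().union(*(
        _labels_at(p, level) for p in truth.values())) if truth else set())
    pred_labels = sorted(set().union(*(
        _labels_at(p, level) for p in predicted.values())) if predicted else set())
    columns = sorted(set(truth_labels) | set(pred_labels)) + [UNCLASSIFIED]
    mat = pd.DataFrame(0.0, index=truth_labels, columns=columns)
    for read_id, true_paths in truth.items():
        tl = sorted(_labels_at(true_paths, level))
        pred_paths = predicted.get(read_id)
        pl = sorted(_labels_at(pred_paths, level)) if pred_paths else [UNCLASSIFIED]
        w = 1.0 / (len(tl) * len(pl))
        for t in tl:
            for p in pl:
                mat.loc[t, p] += w
    row_sums = mat.sum(axis=1)
    mat = mat.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0) * 100.0
    return mat


# ---------------------------------------------------------------------------
# Profile clustering
# ---------------------------------------------------------------------------


def _profiles_to_matrix(profiles: Mapping[str, Mapping[str, float]]
                        ) -> tuple[list[str], np.ndarray]:
    samples = list(profiles)
    labels = sorted(set().union(*(set(p) for p in profiles.values())))
    X = np.zeros((len(samples), len(labels)), dtype=float)
    for i, s in enumerate(samples):
        for j, lab in enumerate(labels):
            X[i, j] = profiles[s].get(lab, 0.0)
    return samples, X


def cluster_profiles(
    profiles: Mapping[str, Mapping[str, float]],
    linkage: str = "average",
) -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of samples on Euclidean profile distances.

    Returns (scipy linkage matrix, sample order, Newick string).
    """
    if len(profiles) < 2:
        raise ValueError("profile clustering needs at least 2 samples")
    if linkage not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    samples, X = _profiles_to_matrix(profiles)
    dists = pdist(X, metric="euclidean")
    Z = scipy_linkage(dists, method=linkage)
    newick = _to_newick(Z, samples)
    return Z, samples, newick


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(Z)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return render(tree, tree.dist) + ";"


def root_bipartition(Z: np.ndarray, labels: list[str]) -> tuple[set[str], set[str]]:
    """The two leaf sets separated by the final (root) merge."""
    tree = to_tree(Z)
    left = {labels[i] for i in tree.left.pre_order()}
    right = {labels[i] for i in tree.right.pre_order()}
    return left, right


# ---------------------------------------------------------------------------
# Truth serialization: TSV (read_id, level1, level2, level3, function),
# one row per tied path.
# ---------------------------------------------------------------------------

TRUTH_HEADER = "read_id\tlevel1\tlevel2\tlevel3\tfunction"


def write_truth(truth: Mapping[str, set], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(TRUTH_HEADER + "\n")
        for read_id in sorted(truth):
            for p in sorted(truth[read_id],
                            key=lambda p: (p.level1, p.level2, p.level3, p.function)):
                out.write(f"{read_id}\t{p.level1}\t{p.level2}\t{p.level3}\t{p.function}\n")


def read_truth(path: str | Path) -> TruthAnnotation:
    truth: dict[str, set] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != TRUTH_HEADER:
            raise ValueError(f"{path}: unexpected truth header {header!r}")
        for line in handle:
            read_id, l1, l2, l3, fn = line.rstrip("\n").split("\t")
            truth.setdefault(read_id, set()).add(SubsystemPath(l1, l2, l3, fn))
    return truth
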