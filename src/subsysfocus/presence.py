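"""Genus x subsystem presence/absence matrix from annotated genomes.

Each genome's proteins are searched against the clustered reference; only
best hits passing the thresholds (E <= 1e-5, identity >= 60%, alignment
>= 15 aa by default) contribute their level-3 subsystems. A subsystem is
present in a genus iff it is present in at least one of its species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from subsysfocus.aligner.search import SearchParams, protein_search
from subsysfocus.io_formats import SequenceRecord
from subsysfocus.profiler import FilterThresholds, filter_hits, group_hits_by_query
from subsysfocus.subsystem_db import ClusteredDatabase

logger = logging.getLogger(__name__)


@dataclass
class GenomeProteinSet:
    species: str
    proteins: list[SequenceRecord]
    genus: str = ""

    def __post_init__(self) -> None:
        if not self.genus:
            self.genus = self.species.split()[0] if self.species.split() else ""
        if not self.genus:
            raise ValueError(f"cannot determine genus for species {self.species!r}")
        if not self.proteins:
            raise ValueError(f"genome {self.species!r} has no proteins")


@dataclass
class PresenceMatrix:
    genera: list[str]
    subsystems: list[str]  # level-3 labels
    present: np.ndarray  # boolean genus x subsystem

    def __post_init__(self) -> None:
        if len(set(self.genera)) != len(self.genera):
            raise ValueError("duplicate genus rows")
        if len(set(self.subsystems)) != len(self.subsystems):
            raise ValueError("duplicate subsystem columns")
        self.present = np.asarray(self.present, dtype=bool)

    def row(self, genus: str) -> set[str]:
        i = self.genera.index(genus)
        return {s for s, p in zip(self.subsystems, self.present[i]) if p}

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("genus\t" + "\t".join(self.subsystems) + "\n")
            for genus, row in zip(self.genera, self.present):
                out.write(genus + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PresenceMatrix":
        genera, rows = [], []
        with open(path) as handle:
            subsystems = handle.readline().rstrip("\n").split("\t")[1:]
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                genera.append(fields[0])
                rows.append([f == "1" for f in fields[1:]])
        return cls(genera=genera, subsystems=subsystems,
                   present=np.asarray(rows, dtype=bool))


def annotate_genome(
    genome: GenomeProteinSet,
    db: ClusteredDatabase,
    thresholds: FilterThresholds | None = None,
    params: SearchParams | None = None,
    exhaustive: bool = False,
) -> set[str]:
    """Level-3 subsystems carried by a genome (union over best hits of its
    proteins; equal-lowest-E ties all contribute)."""
    thresholds = thresholds or FilterThresholds()
    rep_paths = db.representative_paths()
    hits = protein_search(genome.proteins, db, params, exhaustive=exhaustive)
    subsystems: set[str] = set()
    for group in group_hits_by_query(hits):
        for hit in filter_hits(group, thresholds):
            subsystems.add(rep_paths[hit.subject_id].level3)
    if not subsystems:
        warnings.warn(
            f"genome {genome.species!r}: no protein hit passed the thresholds",
            stacklevel=2,
        )
    return subsystems


def build_presence_matrix(
    genomes: Iterable[GenomeProteinSet],
    db: ClusteredDatabase,
    thresholds: FilterThresholds | None = None,
    params: SearchParams | None = None,
    exhaustive: bool = False,
) -> PresenceMatrix:
    """Union the species-level subsystem sets into genus rows."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("need at least one genome")
    by_genus: dict[str, set[str]] = {}
    for genome in genomes:
        subsystems = annotate_genome(genome, db, thresholds, params, exhaustive)
        by_genus.setdefault(genome.genus, set()).update(subsystems)
    dropped = [g for g, s in by_genus.items() if not s]
    for genus in dropped:
        warnings.warn(f"genus {genus!r} has zero subsystems; row dropped", stacklevel=2)
        del by_genus[genus]
    genera = sorted(by_genus)
    subsystems = sorted(set().union(*by_genus.values())) if by_genus else []
    present = np.zeros((len(genera), len(subsystems)), dtype=bool)
    col = {s: j for j, s in enumerate(subsystems)}
    for i, genus in enumerate(genera):
        for s in by_genus[genus]:
            present[i, col[s]] = True
    return PresenceMatrix(genera=genera, subsystems=subsystems, present=present)
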