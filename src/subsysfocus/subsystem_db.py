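"""Subsystem-annotated protein reference and identity-clustered databases.

Every reference protein carries a 4-tuple hierarchy label (level1, level2,
level3, function). Proteins are deduplicated, grouped by their level-3
subsystem, and clustered greedily at a stated identity cut-off; the cluster
representatives form the searchable sequence set and a member->representative
map routes hits back to subsystem labels.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

from subsysfocus.io_formats import SequenceRecord, read_sequences, write_fasta

logger = logging.getLogger(__name__)

NAMED_CUTOFFS = (100.0, 98.0, 95.0, 90.0)


@dataclass(frozen=True)
class SubsystemPath:
    """Hierarchy label of a reference protein: three levels plus a function.

    level2 may be empty (the hierarchy has gaps); level1 and level3 may not.
    """

    level1: str
    level2: str
    level3: str
    function: str

    def __post_init__(self) -> None:
        if not self.level1 or not self.level3:
            raise ValueError("level1 and level3 must be non-empty")

    def label(self, level) -> str:
        if level == 1:
            return self.level1
        if level == 2:
            return self.level2
        if level == 3:
            return self.level3
        if level == "function":
            return self.function
        raise ValueError(f"unknown hierarchy level {level!r}")


@dataclass(frozen=True)
class ReferenceProtein:
    protein_id: str
    seq: SequenceRecord
    path: SubsystemPath


@dataclass
class Cluster:
    representative: ReferenceProtein
    members: list[ReferenceProtein] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.representative]

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Pairwise identity
#
# Identity is (identical aligned residues) / (length of the shorter
# sequence), over the alignment of the shorter against the longer that
# maximizes the number of identical residues, with end gaps on the longer
# free and neither gaps nor mismatches penalized. The match count under
# that objective is computed with the bit-parallel LCS-length algorithm
# (Hyyro-style), which makes clustering fast without heuristics.
# ---------------------------------------------------------------------------


def _match_count(a: str, b: str) -> int:
    """Maximum number of identical aligned residues between a and b."""
    m = len(a)
    if m == 0 or len(b) == 0:
        return 0
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    full = (1 << m) - 1
    v = full
    for ch in b:
        u = v & masks.get(ch, 0)
        v = ((v + u) | (v - u)) & full
    # zero bits of v record matched positions of a
    return m - bin(v).count("1")


def pairwise_identity(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """Percent identity between two protein sequences, in [0, 100].

    Symmetric; normalized by the shorter sequence, so an exact substring
    of a longer sequence scores 100.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if len(sa) > len(sb):
        sa, sb = sb, sa
    return 100.0 * _match_count(sa, sb) / len(sa)


def deduplicate(proteins) -> list[ReferenceProtein]:
    """Drop later records that repeat both sequence and hierarchy path.

    Identical sequences annotated under different paths are all kept —
    they are genuinely distinct reference entries.
    """
    seen: set[tuple[str, SubsystemPath]] = set()
    out: list[ReferenceProtein] = []
    for p in proteins:
        key = (p.seq.seq, p.path)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def _kmer_set(seq: str, k: int = 4) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_subsystem(
    proteins: list[ReferenceProtein],
    cutoff: float,
    prefilter: bool = False,
) -> list[Cluster]:
    """Greedy incremental clustering of one subsystem's proteins.

    Sequences are visited longest-first (ties by protein_id) and join the
    first existing cluster whose representative they match at >= cutoff
    identity, else found a new cluster. ``prefilter`` skips alignment
    against representatives sharing no 4-mer — a speed heuristic that is
    safe for family-structured inputs at high cutoffs but not guaranteed
    in general, hence off by default.
    """
    if not 0 < cutoff <= 100:
        raise ValueError(f"cutoff must be in (0, 100], got {cutoff}")
    level3s = {p.path.level3 for p in proteins}
    if len(level3s) > 1:
        raise ValueError(f"cluster_subsystem got proteins from {len(level3s)} subsystems")
    ordered = sorted(proteins, key=lambda p: (-len(p.seq.seq), p.protein_id))
    clusters: list[Cluster] = []
    rep_kmers: list[frozenset] = []
    use_prefilter = prefilter and cutoff >= 50
    for prot in ordered:
        kmers = _kmer_set(prot.seq.seq) if use_prefilter else None
        placed = False
        for ci, cl in enumerate(clusters):
            if kmers is not None and len(prot.seq.seq) >= 8 and not (kmers & rep_kmers[ci]):
                continue
            if pairwise_identity(prot.seq, cl.representative.seq) >= cutoff:
                cl.members.append(prot)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=prot, members=[prot]))
            if use_prefilter:
                rep_kmers.append(_kmer_set(prot.seq.seq))
    return clusters


@dataclass
class ClusteredDatabase:
    """Per-subsystem clusters of reference proteins at one identity cut-off."""

    identity_cutoff: float
    clusters: "OrderedDict[str, list[Cluster]]"

    def __post_init__(self) -> None:
        if not isinstance(self.clusters, OrderedDict):
            self.clusters = OrderedDict(self.clusters)

    # -- views -------------------------------------------------------------
    @property
    def subsystems(self) -> list[str]:
        return list(self.clusters)

    def representatives(self) -> list[ReferenceProtein]:
        return [cl.representative for cls in self.clusters.values() for cl in cls]

    def representative_paths(self) -> dict[str, SubsystemPath]:
        """Map representative protein_id -> hierarchy path."""
        return {
            cl.representative.protein_id: cl.representative.path
            for cls in self.clusters.values()
            for cl in cls
        }

    def member_to_representative(self) -> dict[str, str]:
        return {
            m.protein_id: cl.representative.protein_id
            for cls in self.clusters.values()
            for cl in cls
            for m in cl.members
        }

    @property
    def n_representatives(self) -> int:
        return sum(len(cls) for cls in self.clusters.values())

    @property
    def n_proteins(self) -> int:
        return sum(len(cl) for cls in self.clusters.values() for cl in cls)

    @property
    def total_residues(self) -> int:
        return sum(len(cl.representative.seq.seq) for cls in self.clusters.values() for cl in cls)

    # -- serialization -----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Write ``sequences.faa`` (representatives), ``members.faa`` (all
        proteins) and ``annotations.tsv`` (member, representative, 4 labels)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        reps = [cl.representative for cls in self.clusters.values() for cl in cls]
        write_fasta((SequenceRecord(p.protein_id, p.seq.seq, "protein") for p in reps),
                    directory / "sequences.faa")
        members = [m for cls in self.clusters.values() for cl in cls for m in cl.members]
        write_fasta((SequenceRecord(p.protein_id, p.seq.seq, "protein") for p in members),
                    directory / "members.faa")
        with open(directory / "annotations.tsv", "w") as out:
            out.write("protein_id\trepresentative_id\tlevel1\tlevel2\tlevel3\tfunction\n")
            for cls in self.clusters.values():
                for cl in cls:
                    rep_id = cl.representative.protein_id
                    for m in cl.members:
                        p = m.path
                        out.write(
                            f"{m.protein_id}\t{rep_id}\t{p.level1}\t{p.level2}\t"
                            f"{p.level3}\t{p.function}\n"
                        )
        with open(directory / "cutoff.txt", "w") as out:
            out.write(f"{self.identity_cutoff}\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ClusteredDatabase":
        directory = Path(directory)
        cutoff = float((directory / "cutoff.txt").read_text().strip())
        seqs = {r.id: r for r in read_sequences(directory / "members.faa", "protein")}
        rows_by_rep: OrderedDict[str, list[ReferenceProtein]] = OrderedDict()
        rep_level3: dict[str, str] = {}
        with open(directory / "annotations.tsv") as handle:
            header = handle.readline()
            if not header.startswith("protein_id\t"):
                raise ValueError(f"{directory}: bad annotations.tsv header")
            for line in handle:
                pid, rep_id, l1, l2, l3, fn = line.rstrip("\n").split("\t")
                prot = ReferenceProtein(pid, seqs[pid], SubsystemPath(l1, l2, l3, fn))
                rows_by_rep.setdefault(rep_id, []).append(prot)
                rep_level3[rep_id] = l3
        clusters: OrderedDict[str, list[Cluster]] = OrderedDict()
        for rep_id, members in rows_by_rep.items():
            rep = next(m for m in members if m.protein_id == rep_id)
            cl = Cluster(representative=rep, members=members)
            clusters.setdefault(rep_level3[rep_id], []).append(cl)
        return cls(identity_cutoff=cutoff, clusters=clusters)


def build_clustered_database(
    proteins,
    cutoff: float,
    prefilter: bool = False,
) -> ClusteredDatabase:
    """Deduplicate, group by level-3 subsystem, and cluster each group."""
    proteins = list(proteins)
    for p in proteins:
        if not isinstance(p.path, SubsystemPath):
            raise ValueError(f"protein {p.protein_id!r} has no subsystem path")
    deduped = deduplicate(proteins)
    groups: OrderedDict[str, list[ReferenceProtein]] = OrderedDict()
    for p in deduped:
        groups.setdefault(p.path.level3, []).append(p)
    clusters: OrderedDict[str, list[Cluster]] = OrderedDict()
    for level3, group in groups.items():
        clusters[level3] = cluster_subsystem(group, cutoff, prefilter=prefilter)
    db = ClusteredDatabase(identity_cutoff=cutoff, clusters=clusters)
    logger.info(
        "clustered %d proteins (%d after dedup) into %d clusters at %.0f%%",
        len(proteins), len(deduped), db.n_representatives, cutoff,
    )
    return db


def load_annotated_proteins(
    fasta_path: str | Path, annotations_path: str | Path
) -> list[ReferenceProtein]:
    """Load a flat reference: protein FASTA + TSV (protein_id, 4 labels)."""
    paths: dict[str, SubsystemPath] = {}
    with open(annotations_path) as handle:
        first = handle.readline().rstrip("\n").split("\t")
        rows = [] if first and first[0] == "protein_id" else [first]
        rows.extend(line.rstrip("\n").split("\t") for line in handle if line.strip())
    for row in rows:
        if len(row) != 5:
            raise ValueError(f"{annotations_path}: expected 5 columns, got {len(row)}")
        pid, l1, l2, l3, fn = row
        paths[pid] = SubsystemPath(l1, l2, l3, fn)
    out = []
    for rec in read_sequences(fasta_path, "protein"):
        if rec.id not in paths:
            raise ValueError(f"protein {rec.id!r} missing from {annotations_path}")
        out.append(ReferenceProtein(rec.id, rec, paths[rec.id]))
    return out
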