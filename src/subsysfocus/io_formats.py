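"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats: FASTA/FASTQ sequence input (auto-detected, transparent
``.gz``), 12-column BLAST tabular ("m8") hit files, and the TSV functional
profile outputs (one file per hierarchy level).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet (stored uppercase)."""

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TabularHit:
    """One row of BLAST 12-column tabular output (1-based inclusive coords)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")

    def to_m8_line(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.2f}",
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_openings),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                f"{self.evalue:.2e}",
                f"{self.bit_score:.1f}",
            ]
        )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path, alphabet: str = "dna") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file (auto-detected).

    FASTQ quality strings are discarded; the pipeline never uses them.
    Duplicate ids are an error because downstream best-hit grouping keys
    on the query id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as handle:
        first = handle.read(1)
        if not first:
            warnings.warn(f"{path}: empty sequence file", stacklevel=2)
            return
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(
                f"{path}: line 1: cannot detect format "
                f"(expected '>' or '@', found {first!r})"
            )
        seen: set[str] = set()
        try:
            for rec in SeqIO.parse(handle, fmt):
                if rec.id in seen:
                    raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
                seen.add(rec.id)
                yield SequenceRecord(id=rec.id, seq=str(rec.seq), alphabet=alphabet)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def read_tabular_hits(path: str | Path) -> Iterator[TabularHit]:
    """Stream hits from a 12-column BLAST tabular (m8) file.

    Lines starting with '#' are skipped. Wrong column counts raise with
    the offending line number.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                yield TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_openings=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc


def write_tabular_hits(hits, path: str | Path) -> int:
    """Write hits as m8; returns the number of rows written."""
    n = 0
    with open(path, "w") as out:
        for hit in hits:
            out.write(hit.to_m8_line() + "\n")
            n += 1
    return n


PROFILE_HEADER = ("label", "relative_abundance", "read_count")


def write_profile(profile, path: str | Path, level) -> None:
    """Write one functional-profile level as TSV.

    Rows are sorted by abundance descending, ties broken lexicographically
    by label; abundances are printed with 6 decimals.
    """
    abundance = profile.abundance if hasattr(profile, "abundance") else dict(profile)
    counts = getattr(profile, "read_counts", {})
    if not abundance:
        warnings.warn(f"{path}: empty profile at level {level}", stacklevel=2)
    rows = sorted(abundance.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as out:
        out.write("\t".join(PROFILE_HEADER) + "\n")
        for label, ab in rows:
            out.write(f"{label}\t{ab:.6f}\t{counts.get(label, ab):.6f}\n")


def read_profile(path: str | Path) -> dict[str, float]:
    """Re-read a profile TSV as a label -> relative abundance map."""
    out: dict[str, float] = {}
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_HEADER:
            raise ValueError(f"{path}: unexpected profile header {header}")
        for line in handle:
            label, ab, _count = line.rstrip("\n").split("\t")
            out[label] = float(ab)
    return out


def write_fasta(records, path: str | Path) -> int:
    n = 0
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def write_fastq(records, path: str | Path) -> int:
    """Write records as FASTQ with flat maximum quality (qualities unused)."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
            n += 1
    return n
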