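"""K-mer/NNLS taxonomic profiling: which genera are in the sample?

The sample's k-mer frequency vector is modelled as a non-negative mixture
of per-genus genome signatures; non-negative least squares recovers the
mixture weights, which are normalized into relative abundances. Genera
below a reporting floor are zeroed (they would only inflate the reduced
database with noise subsystems).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import nnls

from subsysfocus.aligner.translate import reverse_complement
from subsysfocus.io_formats import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 7
DEFAULT_MIN_REPORTED = 0.01

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class KmerSignature:
    k: int
    counts: Mapping[str, float]  # normalized to sum 1


@dataclass
class ReferenceSignatureMatrix:
    k: int
    genera: list[str]
    kmers: list[str]
    matrix: np.ndarray  # |kmers| x |genera|, column-stochastic

    def __post_init__(self) -> None:
        if len(set(self.genera)) != len(self.genera):
            raise ValueError("genus names must be unique")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("reference matrix columns must sum to 1")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("kmer\t" + "\t".join(self.genera) + "\n")
            for i, kmer in enumerate(self.kmers):
                row = "\t".join(f"{v:.10g}" for v in self.matrix[i])
                out.write(f"{kmer}\t{row}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceSignatureMatrix":
        kmers: list[str] = []
        rows: list[list[float]] = []
        with open(path) as handle:
            genera = handle.readline().rstrip("\n").split("\t")[1:]
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                kmers.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if not kmers:
            raise ValueError(f"{path}: empty reference matrix")
        return cls(k=len(kmers[0]), genera=genera, kmers=kmers,
                   matrix=np.asarray(rows, dtype=float))


@dataclass
class TaxonomicProfile:
    abundances: dict[str, float]
    min_reported: float = DEFAULT_MIN_REPORTED

    @property
    def reported_genera(self) -> list[str]:
        return [g for g, a in self.abundances.items() if a >= self.min_reported and a > 0]

    def save(self, path: str | Path) -> None:
        rows = sorted(self.abundances.items(), key=lambda kv: (-kv[1], kv[0]))
        with open(path, "w") as out:
            out.write("genus\trelative_abundance\n")
            for genus, ab in rows:
                out.write(f"{genus}\t{ab:.6f}\n")


def _count_kmers(seq: str, k: int, counts: dict[str, int]) -> None:
    """Count overlapping k-mers of one strand; windows containing non-ACGT skip."""
    n = len(seq)
    if n < k:
        return
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    if k == 1:
        window_ok = valid
    else:
        kernel = np.ones(k, dtype=np.int64)
        window_ok = np.convolve((~valid).astype(np.int64), kernel, mode="valid") == 0
    # encode each window as a base-4 integer
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(np.where(valid, codes, 0), k)
    vals = windows @ weights
    vals = vals[window_ok]
    uniq, cnt = np.unique(vals, return_counts=True)
    for v, c in zip(uniq.tolist(), cnt.tolist()):
        kmer = _decode_kmer(v, k)
        counts[kmer] = counts.get(kmer, 0) + c


def _decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[value & 3])
        value >>= 2
    return "".join(reversed(out))


def kmer_signature(seqs: Iterable[str | SequenceRecord], k: int = DEFAULT_K
                   ) -> KmerSignature:
    """Normalized k-mer frequencies of the sequences plus reverse complements."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for s in seqs:
        seq = s.seq if isinstance(s, SequenceRecord) else s.upper()
        _count_kmers(seq, k, counts)
        _count_kmers(reverse_complement(seq), k, counts)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"input too short for k={k}: no countable k-mer")
    return KmerSignature(k=k, counts={km: c / total for km, c in counts.items()})


def build_reference_matrix(
    genomes: Mapping[str, Iterable[str | SequenceRecord]], k: int = DEFAULT_K
) -> ReferenceSignatureMatrix:
    """Per-genus signatures over the union k-mer vocabulary.

    A genus column is the equal-weight average of its per-sequence-set
    signature (each value passed per genus is treated as one genome pool).
    """
    if not genomes:
        raise ValueError("need at least one genus")
    signatures: dict[str, KmerSignature] = {}
    for genus, seqs in genomes.items():
        seqs = list(seqs)
        if not seqs:
            raise ValueError(f"genus {genus!r} has no sequence")
        signatures[genus] = kmer_signature(seqs, k)
    vocab = sorted(set().union(*(sig.counts.keys() for sig in signatures.values())))
    kmer_idx = {km: i for i, km in enumerate(vocab)}
    genera = list(genomes)
    matrix = np.zeros((len(vocab), len(genera)), dtype=float)
    for j, genus in enumerate(genera):
        for km, v in signatures[genus].counts.items():
            matrix[kmer_idx[km], j] = v
    return ReferenceSignatureMatrix(k=k, genera=genera, kmers=vocab, matrix=matrix)


def reference_matrix_from_species(
    species: Mapping[str, tuple[str, Iterable[str | SequenceRecord]]],
    k: int = DEFAULT_K,
) -> ReferenceSignatureMatrix:
    """Build genus columns as equal-weight averages of species signatures.

    ``species`` maps a species name to (genus, DNA sequences).
    """
    per_species = {name: (genus, kmer_signature(list(seqs), k))
                   for name, (genus, seqs) in species.items()}
    by_genus: dict[str, list[KmerSignature]] = {}
    for _name, (genus, sig) in per_species.items():
        by_genus.setdefault(genus, []).append(sig)
    vocab = sorted(
        set().union(*(sig.counts.keys() for _g, sig in per_species.values()))
    )
    kmer_idx = {km: i for i, km in enumerate(vocab)}
    genera = list(by_genus)
    matrix = np.zeros((len(vocab), len(genera)), dtype=float)
    for j, genus in enumerate(genera):
        sigs = by_genus[genus]
        for sig in sigs:
            for km, v in sig.counts.items():
                matrix[kmer_idx[km], j] += v / len(sigs)
    return ReferenceSignatureMatrix(k=k, genera=genera, kmers=vocab, matrix=matrix)


def fit_genus_abundances(
    sample: KmerSignature,
    ref: ReferenceSignatureMatrix,
    min_reported: float = DEFAULT_MIN_REPORTED,
) -> TaxonomicProfile:
    """Non-negative least squares fit of the sample onto genus signatures."""
    if sample.k != ref.k:
        raise ValueError(f"sample k={sample.k} does not match reference k={ref.k}")
    kmer_idx = {km: i for i, km in enumerate(ref.kmers)}
    s = np.zeros(len(ref.kmers), dtype=float)
    dropped = 0.0
    for km, v in sample.counts.items():
        i = kmer_idx.get(km)
        if i is None:
            dropped += v
        else:
            s[i] = v
    if dropped > 0:
        warnings.warn(
            f"{dropped:.1%} of sample k-mer mass absent from the reference "
            "vocabulary was dropped",
            stacklevel=2,
        )
    x, _residual = nnls(ref.matrix, s)
    total = x.sum()
    if total <= 0:
        raise ValueError("no genus explains the sample (all-zero NNLS solution)")
    x = x / total
    x[x < min_reported] = 0.0
    if x.sum() == 0:
        raise ValueError(
            f"no genus reached the {min_reported:.2%} reporting floor"
        )
    x = x / x.sum()
    return TaxonomicProfile(
        abundances={g: float(a) for g, a in zip(ref.genera, x)},
        min_reported=min_reported,
    )
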