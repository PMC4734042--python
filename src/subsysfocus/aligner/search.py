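"""Seeded translated search and the exhaustive Smith-Waterman alternative.

Both report one 12-column tabular row per (query, subject): the best-scoring
local alignment over reading frames. Bit scores use gapped-BLOSUM62
Karlin-Altschul constants (lambda = 0.267, K = 0.041); E-values follow
E = m * n * 2^(-bit). Exact E-value calibration is not a goal — downstream
logic depends only on E-value ordering and the filtering ceiling, both
robust to the constant choice at this scale.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio.Align import substitution_matrices

from subsysfocus.aligner import _kernels as K
from subsysfocus.aligner.translate import TranslatedFrame, six_frame_translate
from subsysfocus.io_formats import SequenceRecord, TabularHit
from subsysfocus.subsystem_db import ClusteredDatabase

logger = logging.getLogger(__name__)

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X_IDX = _AA_INDEX["X"]

KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int16)
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            mat[_AA_INDEX[a], _AA_INDEX[b]] = int(blosum[a][b])
    # a stop codon must never sit inside a reported alignment
    stop = _AA_INDEX["*"]
    mat[stop, :] = -100
    mat[:, stop] = -100
    return mat


BLOSUM62 = _blosum62_matrix()


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, _X_IDX) for ch in seq], dtype=np.int8)


def bitscore_from_raw(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / LN2


def evalue_from_bitscore(bit: float, m: int, n: int) -> float:
    """Expected chance hits: E = m * n * 2^(-bit); decreasing in bit."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    return float(m) * float(n) * math.pow(2.0, -bit)


@dataclass(frozen=True)
class SearchParams:
    seed_len: int = 4
    gap_open: int = 11
    gap_extend: int = 1
    x_drop: int = 20
    min_bit_score: float = 30.0
    band: int = 16

    @classmethod
    def for_mode(cls, mode: str) -> "SearchParams":
        """'sensitive' seeds at 3 aa, 'fast' at 5, 'default' at 4."""
        seed = {"sensitive": 3, "default": 4, "fast": 5}.get(mode)
        if seed is None:
            raise ValueError(f"unknown mode {mode!r}")
        return cls(seed_len=seed)


class SubjectIndex:
    """Encoded representatives plus an exact amino-acid seed index."""

    def __init__(self, db: ClusteredDatabase, seed_len: int):
        reps = db.representatives()
        if not reps:
            raise ValueError("database has no representative sequences")
        # deterministic subject order regardless of subsystem iteration order
        reps = sorted(reps, key=lambda p: p.protein_id)
        self.ids = [p.protein_id for p in reps]
        self.seqs = [p.seq.seq for p in reps]
        self.encoded = [encode_protein(s) for s in self.seqs]
        self.total_residues = sum(len(s) for s in self.seqs)
        self.seed_len = seed_len
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, seq in enumerate(self.seqs):
            for pos in range(len(seq) - seed_len + 1):
                word = seq[pos : pos + seed_len]
                if "X" in word or "*" in word:
                    continue
                index[word].append((si, pos))
        self.index = dict(index)

    def candidates(self, peptide: str) -> dict[int, tuple[int, int]]:
        """Subjects sharing >= 1 exact seed -> (min, max) seed diagonal."""
        k = self.seed_len
        diags: dict[int, tuple[int, int]] = {}
        for qpos in range(len(peptide) - k + 1):
            for si, spos in self.index.get(peptide[qpos : qpos + k], ()):
                d = spos - qpos
                cur = diags.get(si)
                if cur is None:
                    diags[si] = (d, d)
                else:
                    diags[si] = (min(cur[0], d), max(cur[1], d))
        return diags


def _hit_from_alignment(
    frame: TranslatedFrame | None,
    query_id: str,
    subject_id: str,
    res: np.ndarray,
    m: int,
    n: int,
    min_bit: float,
) -> TabularHit | None:
    raw = int(res[K.R_SCORE])
    if raw <= 0:
        return None
    bit = bitscore_from_raw(raw)
    if bit < min_bit:
        return None
    alnlen = int(res[K.R_ALNLEN])
    matches = int(res[K.R_MATCH])
    qs, qe = int(res[K.R_QS]), int(res[K.R_QE])
    if frame is None:
        q_start, q_end = qs + 1, qe + 1
    else:
        q_start, q_end = frame.nt_start(qs), frame.nt_end(qe)
    return TabularHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=round(100.0 * matches / alnlen, 2),
        aln_length=alnlen,
        mismatches=int(res[K.R_MISM]),
        gap_openings=int(res[K.R_GAPOPEN]),
        q_start=q_start,
        q_end=q_end,
        s_start=int(res[K.R_SS]) + 1,
        s_end=int(res[K.R_SE]) + 1,
        evalue=evalue_from_bitscore(bit, m, n),
        bit_score=round(bit, 1),
    )


def _align_query(
    frames: list[tuple[TranslatedFrame | None, np.ndarray]],
    query_id: str,
    idx: SubjectIndex,
    params: SearchParams,
    exhaustive: bool,
) -> list[TabularHit]:
    # best alignment per subject across frames
    best: dict[int, tuple[int, TranslatedFrame | None, np.ndarray, int]] = {}
    for frame, enc in frames:
        if enc.shape[0] == 0:
            continue
        if exhaustive:
            cand: Iterable[tuple[int, tuple[int, int] | None]] = (
                (si, None) for si in range(len(idx.ids))
            )
        else:
            peptide = frame.peptide if frame is not None else None
            if peptide is None:
                raise ValueError("seeded search requires peptide strings")
            cand = idx.candidates(peptide).items()
        for si, dband in cand:
            subj = idx.encoded[si]
            if dband is None:
                dlo, dhi = -enc.shape[0], subj.shape[0]
            else:
                dlo, dhi = dband[0] - params.band, dband[1] + params.band
            res = K.sw_align(
                enc, subj, BLOSUM62, params.gap_open, params.gap_extend, dlo, dhi
            )
            score = int(res[K.R_SCORE])
            if score <= 0:
                continue
            cur = best.get(si)
            if cur is None or score > cur[0]:
                best[si] = (score, frame, res, enc.shape[0])
    hits = []
    for si, (_score, frame, res, qlen) in best.items():
        hit = _hit_from_alignment(
            frame, query_id, idx.ids[si], res, qlen, idx.total_residues,
            params.min_bit_score,
        )
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def _translated_frames(read: SequenceRecord):
    return [(fr, encode_protein(fr.peptide)) for fr in six_frame_translate(read)]


def search(
    reads: Iterable[SequenceRecord],
    db: ClusteredDatabase,
    params: SearchParams | None = None,
) -> Iterator[TabularHit]:
    """Seeded translated search of DNA reads against db representatives."""
    params = params or SearchParams()
    idx = SubjectIndex(db, params.seed_len)
    for read in reads:
        yield from _align_query(
            _translated_frames(read), read.id, idx, params, exhaustive=False
        )


def exhaustive_search(
    reads: Iterable[SequenceRecord],
    db: ClusteredDatabase,
    params: SearchParams | None = None,
) -> Iterator[TabularHit]:
    """Full Smith-Waterman of every frame against every representative."""
    params = params or SearchParams()
    idx = SubjectIndex(db, params.seed_len)
    for read in reads:
        yield from _align_query(
            _translated_frames(read), read.id, idx, params, exhaustive=True
        )


def protein_search(
    proteins: Iterable[SequenceRecord],
    db: ClusteredDatabase,
    params: SearchParams | None = None,
    exhaustive: bool = False,
) -> Iterator[TabularHit]:
    """Protein-protein search (used for genome annotation); aa coordinates."""
    params = params or SearchParams()
    idx = SubjectIndex(db, params.seed_len)
    for prot in proteins:
        frame = None if exhaustive else _ProteinFrame(prot.seq)
        frames = [(frame, encode_protein(prot.seq))]
        yield from _align_query(frames, prot.id, idx, params, exhaustive=exhaustive)


class _ProteinFrame:
    """Duck-typed stand-in for TranslatedFrame when the query is a protein."""

    frame = 0

    def __init__(self, peptide: str):
        self.peptide = peptide

    @staticmethod
    def nt_start(pep_pos: int) -> int:
        return pep_pos + 1

    @staticmethod
    def nt_end(pep_pos: int) -> int:
        return pep_pos + 1
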