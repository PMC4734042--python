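"""Six-frame translation of DNA reads (standard genetic code, table 1)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

from subsysfocus.io_formats import SequenceRecord

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a read.

    ``nt_start(i)`` / ``nt_end(i)`` map a 0-based peptide position to the
    1-based coordinates (on the original read) of its codon's first and
    last nucleotide; for negative frames start > end.
    """

    read_id: str
    frame: int
    peptide: str
    read_length: int

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def nt_start(self, pep_pos: int) -> int:
        if self.frame > 0:
            return self.offset + 3 * pep_pos + 1
        return self.read_length - (self.offset + 3 * pep_pos)

    def nt_end(self, pep_pos: int) -> int:
        if self.frame > 0:
            return self.offset + 3 * pep_pos + 3
        return self.read_length - (self.offset + 3 * pep_pos + 2)


def translate_frame(dna: str, frame: int) -> str:
    """Translate one frame; codons containing N become 'X', stops '*'."""
    if frame < 0:
        dna = reverse_complement(dna)
    off = abs(frame) - 1
    usable = dna[off:]
    aa = []
    for i in range(0, len(usable) - 2, 3):
        codon = usable[i : i + 3]
        aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


def six_frame_translate(read: SequenceRecord) -> list[TranslatedFrame]:
    """All six reading frames of a DNA read; empty peptides are dropped."""
    if read.alphabet != "dna":
        raise ValueError(f"six_frame_translate needs DNA input, got {read.alphabet}")
    if len(read.seq) < 3:
        warnings.warn(f"read {read.id!r} shorter than one codon; no frames", stacklevel=2)
        return []
    out = []
    for frame in FRAMES:
        pep = translate_frame(read.seq, frame)
        if pep:
            out.append(TranslatedFrame(read.id, frame, pep, len(read.seq)))
    return out
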