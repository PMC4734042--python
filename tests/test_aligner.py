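import random

import pytest

from helpers import GENETIC_CODE, random_dna, random_protein, sw_oracle_score
from subsysfocus.aligner import (
    SearchParams,
    evalue_from_bitscore,
    exhaustive_search,
    search,
    six_frame_translate,
)
from subsysfocus.aligner.search import (
    AA_ALPHABET,
    BLOSUM62,
    bitscore_from_raw,
    encode_protein,
    protein_search,
)
from subsysfocus.aligner.translate import reverse_complement, translate_frame
from subsysfocus.io_formats import SequenceRecord
from subsysfocus.subsystem_db import (
    ReferenceProtein,
    SubsystemPath,
    build_clustered_database,
)
from subsysfocus.synthetic import reverse_translate


def _blosum_fn(a, b):
    ia = AA_ALPHABET.index(a)
    ib = AA_ALPHABET.index(b)
    return int(BLOSUM62[ia, ib])


def make_db(seqs):
    prots = [
        ReferenceProtein(
            f"p{i}",
            SequenceRecord(f"p{i}", s, "protein"),
            SubsystemPath("L1_0", "L2_0", f"L3_{i}", f"fn_{i}"),
        )
        for i, s in enumerate(seqs)
    ]
    return build_clustered_database(prots, 100)


class TestTranslation:
    def test_frame_plus1(self):
        assert translate_frame("ATGGCC", 1) == "MA"

    def test_frame_minus1_hand_derived(self):
        # RC of ATGGCC is GGCCAT -> GGC=G, CAT=H
        assert translate_frame("ATGGCC", -1) == "GH"

    def test_n_codon_is_x(self):
        assert translate_frame("ATGNCC", 1) == "MX"

    def test_stop_is_star(self):
        assert translate_frame("TAAATG", 1) == "*M"

    def test_six_frames_against_code_table(self):
        rng = random.Random(0)
        dna = random_dna(rng, 31)
        frames = six_frame_translate(SequenceRecord("r", dna, "dna"))
        assert {f.frame for f in frames} == {1, 2, 3, -1, -2, -3}
        for fr in frames:
            template = dna if fr.frame > 0 else reverse_complement(dna)
            off = abs(fr.frame) - 1
            expected = "".join(
                GENETIC_CODE[template[i : i + 3]]
                for i in range(off, len(template) - 2, 3)
            )
            assert fr.peptide == expected
            assert len(fr.peptide) == (len(dna) - off) // 3

    def test_short_read_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert six_frame_translate(SequenceRecord("r", "AC", "dna")) == []

    def test_offset_map_positive(self):
        (fr,) = [f for f in six_frame_translate(SequenceRecord("r", "ATGGCCAAA", "dna")) if f.frame == 2]
        assert fr.nt_start(0) == 2 and fr.nt_end(0) == 4

    def test_offset_map_negative(self):
        (fr,) = [f for f in six_frame_translate(SequenceRecord("r", "ATGGCCAAA", "dna")) if f.frame == -1]
        # peptide position 0 covers the last three bases, reported 9 -> 7
        assert fr.nt_start(0) == 9 and fr.nt_end(0) == 7


class TestEvalue:
    def test_arithmetic_example(self):
        assert evalue_from_bitscore(30, 100, 10**6) == pytest.approx(0.0931, abs=1e-4)

    def test_limit(self):
        assert evalue_from_bitscore(1e6, 100, 10**6) == pytest.approx(0.0)

    def test_doubling_n_doubles_e(self):
        assert evalue_from_bitscore(40, 50, 2000) == pytest.approx(
            2 * evalue_from_bitscore(40, 50, 1000)
        )

    def test_strictly_decreasing_in_bit(self):
        values = [evalue_from_bitscore(b, 100, 1000) for b in range(10, 60, 5)]
        assert values == sorted(values, reverse=True)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            evalue_from_bitscore(30, 0, 100)


class TestSearch:
    def test_exact_coding_read_self_hit(self):
        rng = random.Random(1)
        db = make_db([random_protein(rng, 80) for _ in range(4)])
        target = db.representatives()[0]
        segment = target.seq.seq[20:50]  # 30 aa
        read = SequenceRecord("r1", reverse_translate(rng, segment), "dna")
        hits = list(search([read], db))
        assert hits, "expected a self-hit"
        top = hits[0]
        assert top.subject_id == target.protein_id
        assert top.pct_identity == 100.0
        assert top.aln_length == 30
        assert top.mismatches == 0 and top.gap_openings == 0

    def test_no_shared_seed_no_hit(self):
        db = make_db(["M" + "W" * 60])
        read = SequenceRecord("r1", "GCA" * 20, "dna")  # poly-alanine
        assert list(search([read], db)) == []

    def test_empty_db_rejected(self):
        from subsysfocus.subsystem_db import ClusteredDatabase
        from collections import OrderedDict

        empty = ClusteredDatabase(identity_cutoff=100, clusters=OrderedDict())
        with pytest.raises(ValueError):
            list(search([SequenceRecord("r", "ACGTAA", "dna")], empty))

    def test_best_subject_matches_sw_oracle(self):
        rng = random.Random(2)
        db = make_db([random_protein(rng, rng.randint(30, 50)) for _ in range(5)])
        subjects = {p.protein_id: p.seq.seq for p in db.representatives()}
        n_checked = 0
        for ri in range(20):
            src = rng.choice(list(subjects.values()))
            start = rng.randrange(len(src) - 15)
            pep = src[start : start + 15]
            read = SequenceRecord(f"r{ri}", reverse_translate(rng, pep), "dna")
            hits = list(exhaustive_search([read], db, SearchParams(min_bit_score=0)))
            if not hits:
                continue
            # oracle: full SW of every frame against every subject
            frames = six_frame_translate(read)
            best_oracle = (-1, None)
            for pid, sseq in sorted(subjects.items()):
                sc = max(
                    sw_oracle_score(fr.peptide, sseq, _blosum_fn, 11, 1)
                    for fr in frames
                )
                if sc > best_oracle[0]:
                    best_oracle = (sc, pid)
            assert hits[0].subject_id == best_oracle[1]
            # and the reported raw score equals the oracle optimum
            n_checked += 1
        assert n_checked >= 15

    def test_seeded_score_close_to_oracle(self):
        # heuristic must reach >= 95% of the oracle bit score for >= 95%
        # of reads that contain a true seed match
        rng = random.Random(3)
        db = make_db([random_protein(rng, 60) for _ in range(5)])
        subjects = [p.seq.seq for p in db.representatives()]
        ok = total = 0
        for ri in range(40):
            src = rng.choice(subjects)
            start = rng.randrange(len(src) - 20)
            read = SequenceRecord(
                f"r{ri}", reverse_translate(rng, src[start : start + 20]), "dna"
            )
            params = SearchParams(min_bit_score=0)
            seeded = {h.subject_id: h.bit_score for h in search([read], db, params)}
            exact = {h.subject_id: h.bit_score for h in exhaustive_search([read], db, params)}
            if not exact:
                continue
            best_subject = max(exact, key=exact.get)
            total += 1
            if seeded.get(best_subject, 0) >= 0.95 * exact[best_subject]:
                ok += 1
        assert total >= 30
        assert ok / total >= 0.95

    def test_hit_self_audit(self):
        # reported identity/aln_length consistent with re-scoring coordinates
        rng = random.Random(4)
        db = make_db([random_protein(rng, 70) for _ in range(3)])
        subjects = {p.protein_id: p.seq.seq for p in db.representatives()}
        src = list(subjects.values())[0]
        read = SequenceRecord("r", reverse_translate(rng, src[5:45]), "dna")
        for hit in search([read], db):
            sseq = subjects[hit.subject_id]
            sub_aln = sseq[hit.s_start - 1 : hit.s_end]
            assert hit.aln_length >= len(sub_aln)
            assert hit.aln_length >= hit.mismatches
            assert 0 < hit.pct_identity <= 100
            # nucleotide span equals 3x the aligned peptide span when gapless
            if hit.gap_openings == 0:
                assert abs(hit.q_end - hit.q_start) + 1 == 3 * hit.aln_length

    def test_results_sorted_deterministically(self):
        rng = random.Random(5)
        base = random_protein(rng, 50)
        db = make_db([base, base])  # two identical subjects, distinct ids
        read = SequenceRecord("r", reverse_translate(rng, base[10:40]), "dna")
        hits = list(search([read], db))
        assert [h.subject_id for h in hits] == sorted(h.subject_id for h in hits)
        assert hits[0].bit_score == hits[1].bit_score

    def test_reverse_strand_found(self):
        rng = random.Random(6)
        db = make_db([random_protein(rng, 60)])
        src = db.representatives()[0].seq.seq
        dna = reverse_translate(rng, src[10:40])
        read = SequenceRecord("r", reverse_complement(dna), "dna")
        hits = list(search([read], db))
        assert hits and hits[0].pct_identity == 100.0
        assert hits[0].q_start > hits[0].q_end  # minus-strand convention

    def test_bitscore_floor_filters(self):
        rng = random.Random(7)
        db = make_db([random_protein(rng, 60)])
        src = db.representatives()[0].seq.seq
        read = SequenceRecord("r", reverse_translate(rng, src[0:6]), "dna")
        # 6 aa perfect match: raw ~30 -> bit ~16, below the default floor 30
        assert list(search([read], db)) == []
        assert list(search([read], db, SearchParams(min_bit_score=5)))


class TestProteinSearch:
    def test_exact_protein_best_hit(self):
        rng = random.Random(8)
        db = make_db([random_protein(rng, 60) for _ in range(4)])
        target = db.representatives()[2]
        query = SequenceRecord("q", target.seq.seq, "protein")
        hits = list(protein_search([query], db))
        assert hits[0].subject_id == target.protein_id
        assert hits[0].pct_identity == 100.0
        assert hits[0].aln_length == 60
        exact = list(protein_search([query], db, exhaustive=True))
        assert exact[0].subject_id == target.protein_id


def test_bitscore_from_raw_monotone():
    assert bitscore_from_raw(100) > bitscore_from_raw(50)


def test_encode_protein_roundtrip():
    enc = encode_protein("ARND")
    assert [AA_ALPHABET[i] for i in enc] == list("ARND")
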