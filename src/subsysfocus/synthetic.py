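"""Synthetic fixtures with known truth: reference databases, annotated
genomes, and metagenomic read sets.

Families within a subsystem descend from one random ancestral protein by
point substitutions; families across subsystems are independent random
sequences, so cross-subsystem identity stays near background. Community
genomes carry reverse-translated coding DNA (random synonymous codons) for
proteins sampled from the reference, and reads are drawn from those coding
regions with an optional substitution error model (no indels; frame-shift
handling is out of scope for the built-in aligner).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from subsysfocus.aligner.translate import CODON_TO_AA, reverse_complement
from subsysfocus.io_formats import SequenceRecord
from subsysfocus.presence import GenomeProteinSet
from subsysfocus.subsystem_db import ClusteredDatabase, ReferenceProtein, SubsystemPath

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def _mutate_protein(rng: random.Random, seq: str, n_subs: int) -> str:
    positions = rng.sample(range(len(seq)), n_subs)
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([a for a in AA20 if a != chars[pos]])
    return "".join(chars)


def generate_subsystem_db(
    n_level1: int = 2,
    n_level3_per_level1: int = 3,
    families_per_subsystem: int = 2,
    seqs_per_family: int = 3,
    within_family_identity: float = 95.0,
    seed: int = 0,
    min_len: int = 80,
    max_len: int = 300,
) -> list[ReferenceProtein]:
    """Reference proteins with synthesized 4-tier labels L1_i/L2_j/L3_k/fn_m."""
    if not 50 < within_family_identity <= 100:
        raise ValueError("within_family_identity must be in (50, 100]")
    rng = random.Random(seed)
    proteins: list[ReferenceProtein] = []
    k = 0
    for i in range(n_level1):
        for _ in range(n_level3_per_level1):
            level1 = f"L1_{i}"
            # occasional hierarchy gap: empty level2
            level2 = "" if rng.random() < 0.1 else f"L2_{i}_{k % n_level3_per_level1}"
            level3 = f"L3_{k}"
            for fam in range(families_per_subsystem):
                length = rng.randint(min_len, max_len)
                ancestor = _random_protein(rng, length)
                n_subs = round(length * (1.0 - within_family_identity / 100.0))
                path = SubsystemPath(level1, level2, level3, f"fn_{k}_{fam}")
                for v in range(seqs_per_family):
                    seq = ancestor if v == 0 else _mutate_protein(rng, ancestor, n_subs)
                    pid = f"{level3}|fam{fam}|v{v}"
                    proteins.append(
                        ReferenceProtein(pid, SequenceRecord(pid, seq, "protein"), path)
                    )
            k += 1
    return proteins


def reverse_translate(rng: random.Random, protein: str) -> str:
    """DNA coding for the protein using random synonymous codons."""
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


@dataclass(frozen=True)
class Gene:
    protein_id: str
    path: SubsystemPath
    protein: str
    dna: str


@dataclass
class SyntheticGenome:
    species: str
    genus: str
    genes: list[Gene] = field(default_factory=list)

    @property
    def protein_set(self) -> GenomeProteinSet:
        return GenomeProteinSet(
            species=self.species,
            genus=self.genus,
            proteins=[
                SequenceRecord(g.protein_id, g.protein, "protein") for g in self.genes
            ],
        )

    @property
    def subsystems(self) -> set[str]:
        return {g.path.level3 for g in self.genes}


def generate_community(
    db: ClusteredDatabase | list[ReferenceProtein],
    n_genera: int = 3,
    species_per_genus: int = 2,
    subsystems_per_genus: int = 4,
    seed: int = 0,
    proteins_per_subsystem: int = 2,
) -> tuple[list[SyntheticGenome], dict[str, set[str]]]:
    """Genomes for a community plus the genus -> subsystem truth table.

    Each genus draws a random subsystem subset; each of its species carries
    coding DNA for proteins sampled from (a subset of) those subsystems.
    The emitted truth table is the union of each genus's species sets.
    """
    rng = random.Random(seed)
    if isinstance(db, ClusteredDatabase):
        by_subsystem: dict[str, list[ReferenceProtein]] = {
            l3: [m for cl in cls for m in cl.members] for l3, cls in db.clusters.items()
        }
    else:
        by_subsystem = {}
        for p in db:
            by_subsystem.setdefault(p.path.level3, []).append(p)
    all_subsystems = sorted(by_subsystem)
    if subsystems_per_genus > len(all_subsystems):
        raise ValueError("not enough subsystems in the reference")
    genomes: list[SyntheticGenome] = []
    truth: dict[str, set[str]] = {}
    for gi in range(n_genera):
        genus = f"Genus{gi}"
        genus_subsystems = rng.sample(all_subsystems, subsystems_per_genus)
        truth[genus] = set()
        for si in range(species_per_genus):
            n_keep = rng.randint(max(1, subsystems_per_genus - 1), subsystems_per_genus)
            species_subsystems = rng.sample(genus_subsystems, n_keep)
            genes = []
            for l3 in species_subsystems:
                pool = by_subsystem[l3]
                chosen = rng.sample(pool, min(proteins_per_subsystem, len(pool)))
                for prot in chosen:
                    genes.append(
                        Gene(
                            protein_id=prot.protein_id,
                            path=prot.path,
                            protein=prot.seq.seq,
                            dna=reverse_translate(rng, prot.seq.seq),
                        )
                    )
            genomes.append(
                SyntheticGenome(species=f"{genus} sp{si}", genus=genus, genes=genes)
            )
            truth[genus] |= {g.path.level3 for g in genes}
    return genomes, truth


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    genus: str
    species: str
    protein_id: str
    path: SubsystemPath | None  # None for intergenic (negative-control) reads


def generate_reads(
    genomes: list[SyntheticGenome],
    abundances: Mapping[str, float],
    n_reads: int = 1000,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    intergenic_fraction: float = 0.0,
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Reads sampled from coding regions proportional to genus abundance.

    Genes are chosen proportional to their number of valid start positions,
    the start uniform, the strand random; substitution errors are applied
    at ``error_rate`` per base.
    """
    if abs(sum(abundances.values()) - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = random.Random(seed)
    by_genus: dict[str, list[SyntheticGenome]] = {}
    for g in genomes:
        by_genus.setdefault(g.genus, []).append(g)
    unknown = set(abundances) - set(by_genus)
    if unknown:
        raise ValueError(f"abundances name unknown genera: {sorted(unknown)}")
    genus_names = sorted(abundances)
    weights = [abundances[g] for g in genus_names]
    reads: list[SequenceRecord] = []
    truths: list[ReadTruth] = []
    for ri in range(n_reads):
        read_id = f"read{ri}"
        genus = rng.choices(genus_names, weights=weights)[0]
        genome = rng.choice(by_genus[genus])
        if intergenic_fraction > 0 and rng.random() < intergenic_fraction:
            seq = "".join(rng.choice("ACGT") for _ in range(read_length))
            reads.append(SequenceRecord(read_id, seq, "dna"))
            truths.append(ReadTruth(read_id, genus, genome.species, "-", None))
            continue
        gene_weights = [max(len(g.dna) - read_length + 1, 1) for g in genome.genes]
        gene = rng.choices(genome.genes, weights=gene_weights)[0]
        if len(gene.dna) <= read_length:
            start, fragment = 0, gene.dna
        else:
            start = rng.randrange(len(gene.dna) - read_length + 1)
            fragment = gene.dna[start : start + read_length]
        if error_rate > 0:
            chars = list(fragment)
            for i in range(len(chars)):
                if rng.random() < error_rate:
                    chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
            fragment = "".join(chars)
        if rng.random() < 0.5:
            fragment = reverse_complement(fragment)
        reads.append(SequenceRecord(read_id, fragment, "dna"))
        truths.append(
            ReadTruth(read_id, genus, genome.species, gene.protein_id, gene.path)
        )
    return reads, truths


def save_community(genomes: list[SyntheticGenome], directory: str | Path) -> Path:
    """Write per-species coding DNA FASTA plus a genes.tsv metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "genes.tsv", "w") as out:
        out.write("species\tgenus\tprotein_id\tlevel1\tlevel2\tlevel3\tfunction\n")
        for genome in genomes:
            stem = genome.species.replace(" ", "_")
            with open(directory / f"{stem}.fna", "w") as fna:
                for gene in genome.genes:
                    fna.write(f">{gene.protein_id}\n{gene.dna}\n")
            for gene in genome.genes:
                p = gene.path
                out.write(
                    f"{genome.species}\t{genome.genus}\t{gene.protein_id}\t"
                    f"{p.level1}\t{p.level2}\t{p.level3}\t{p.function}\n"
                )
    return directory


def load_community(directory: str | Path) -> list[SyntheticGenome]:
    directory = Path(directory)
    meta: dict[str, tuple[str, list[tuple[str, SubsystemPath]]]] = {}
    with open(directory / "genes.tsv") as handle:
        handle.readline()
        for line in handle:
            species, genus, pid, l1, l2, l3, fn = line.rstrip("\n").split("\t")
            meta.setdefault(species, (genus, []))[1].append(
                (pid, SubsystemPath(l1, l2, l3, fn))
            )
    genomes = []
    for species, (genus, genes_meta) in meta.items():
        stem = species.replace(" ", "_")
        from subsysfocus.io_formats import read_sequences

        dna = {r.id: r.seq for r in read_sequences(directory / f"{stem}.fna", "dna")}
        genes = []
        for pid, path in genes_meta:
            gene_dna = dna[pid]
            protein = "".join(
                CODON_TO_AA[gene_dna[i : i + 3]] for i in range(0, len(gene_dna) - 2, 3)
            )
            genes.append(Gene(protein_id=pid, path=path, protein=protein, dna=gene_dna))
        genomes.append(SyntheticGenome(species=species, genus=genus, genes=genes))
    return genomes


def write_read_truth(truths: Iterable[ReadTruth], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("read_id\tgenus\tspecies\tprotein_id\tlevel1\tlevel2\tlevel3\tfunction\n")
        for t in truths:
            p = t.path
            labels = (p.level1, p.level2, p.level3, p.function) if p else ("-",) * 4
            out.write(
                f"{t.read_id}\t{t.genus}\t{t.species}\t{t.protein_id}\t"
                + "\t".join(labels) + "\n"
            )
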