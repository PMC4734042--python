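# subsysfocus

Subsystem-level functional profiling of shotgun metagenomes, accelerated by
two database tricks:

1. **Identity-clustered references.** The subsystem-annotated protein
   reference is clustered greedily within each level-3 subsystem at a chosen
   identity cut-off (presets `db_100`, `db_98`, `db_95`, `db_90`); only
   cluster representatives are searched, and a member→representative map
   routes hits back to hierarchy labels.
2. **On-the-fly reduction.** A k-mer/NNLS taxonomic profiler estimates which
   genera are in the sample; a genus × subsystem presence/absence matrix
   (built from annotated genomes) then restricts the search space to the
   subsystems those genera carry.

Reads are assigned by translated homology search (built-in seeded
Smith–Waterman with BLOSUM62, or any external aligner's 12-column tabular
output via `--hits`), filtered at E ≤ 1e-5, identity ≥ 60%, alignment ≥ 15 aa
(all configurable), with equal-lowest-E ties all kept. Relative abundances
are reported at hierarchy levels 1–3 (optionally the function tier).

The package also ships the evaluation toolkit (truth construction via an
exhaustive aligner, sensitivity/precision, confusion matrices, hierarchical
profile clustering) and a synthetic-data generator so the entire pipeline is
testable offline with known truth.

## CLI

All commands live under one entry point, `subsysfocus`:

```bash
# 0. simulate a reference, or bring your own proteins.faa + annotations.tsv
subsysfocus simulate db --seed 1 --out ref/

# cluster at the preset cut-offs
subsysfocus build-db --input ref/proteins.faa --annotations ref/annotations.tsv \
    --cutoffs 100,98,95,90 --out dbs/

# simulate an annotated community, build the presence matrix
subsysfocus simulate community --db dbs/db_100 --seed 2 --out community/
subsysfocus build-matrix --genomes community/ --db dbs/db_100 --out matrix.tsv

# simulate reads with per-read truth
subsysfocus simulate reads --community community/ --seed 3 \
    --abundances Genus0=0.7,Genus1=0.3 --n-reads 2000 --out reads.fq

# full pipeline: taxa -> reduce -> align -> profiles + JSON run report
subsysfocus profile --reads reads.fq --db dbs/db_98 \
    --matrix matrix.tsv --tax-ref taxref.tsv --out run1
# -> run1.level{1,2,3}.tsv, run1.taxonomy.tsv, run1.hits.m8, run1.report.json

# benchmark against a truth table; cluster sample profiles
subsysfocus evaluate --pred run1 --db dbs/db_98 --truth truth.tsv --level 1
subsysfocus cluster-profiles --profiles profiles_dir/ --out tree.nwk
```

`--no-reduce` searches the full database (the plain-aligner baseline);
`--hits external.m8` skips the built-in search; `--exhaustive` switches to
the full Smith–Waterman oracle used for truth construction; `--mode
sensitive|default|fast` trades seed length (3/4/5 aa) for speed. A YAML
config can replace flags (`--config run.yaml`; explicit flags win).

## Layout

| Module | Role |
| --- | --- |
| `io_formats` | FASTA/FASTQ/m8/profile-TSV readers and writers |
| `subsystem_db` | hierarchy labels, pairwise identity, greedy clustering, db (de)serialization |
| `taxonomy` | k-mer signatures, reference matrix, NNLS genus abundances |
| `presence` | genome annotation and genus × subsystem presence matrix |
| `reducer` | subsystem selection and database-view reduction |
| `aligner` | six-frame translation, seeded/banded and exhaustive Smith–Waterman (numba) |
| `profiler` | hit filtering, tied best-hit assignment, profile aggregation |
| `evaluation` | truth construction, sensitivity/precision, confusion matrices, profile clustering |
| `synthetic` | seeded generators for databases, communities and reads |
| `cli` | `subsysfocus` command group and `run_pipeline` orchestration |
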