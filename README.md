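# lanminer

Genome mining for lanthipeptide biosynthetic gene clusters (BGCs) and their
precursor peptides in annotated prokaryotic genomes.

The pipeline:

1. **Anchor search** — all annotated proteins are searched with a LanC-like
   cyclase profile HMM (HMMER3 backend).
2. **Neighborhood extraction** — each anchor gene plus up to seven genes on
   each side; neighborhoods within 3 kb of a contig end are edge-flagged.
3. **Class assignment** — class I (both dehydratase-N and -C domain hits,
   split enzymes allowed), class II (class-II dehydratase domain), class
   III/IV (anchor protein also hits a protein-kinase model; the two cyclase
   subfamily models are compared by E-value, ties to III). Multi-class
   neighborhoods are labeled by precedence I > II > III/IV and flagged.
4. **ORF enumeration** — all ATG/GTG/TTG → stop ORFs on both strands of the
   neighborhood span; kept if 30–120 aa, containing Cys, and not encoded
   entirely within an annotated gene; one ORF per stop codon (longest kept).
5. **Leader/core split** — the region after the best leader motif (FxLD,
   LxLxKx5L, LxLQ, E/D-L/M, GG) is scanned for GG, GA, or S/T(x)2-7C; the
   core starts right after a GG/GA or one residue before the S/T, taking
   the occurrence that gives the longest core and ignoring occurrences
   within 10 residues of the C-terminus; otherwise the C-terminal half is
   the core. Candidates whose core lacks Cys are rejected.
6. **Scoring** — ~1350 per-region sequence features, ANOVA selection
   (p < 0.05), a standardized RBF SVM, and a configurable heuristic rubric
   (motif, cleavage, core S+T+C content, genomic context, SVM decision).
7. **Annotation & summary** — accessory genes vs. a domain-model collection
   at E ≤ 1e-5, a per-class BGC census, %GC pairs, per-phylum tallies.

Everything is testable offline: `lanminer.fixtures` generates deterministic
synthetic genomes with planted BGCs, precursor ORFs, rule-violating decoys,
profile families for every domain role, and labeled training peptides.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(oracle equivalence for ORF enumeration and boundary calling, the class
truth table, closed-form ANOVA checks, classifier recovery on synthetic
peptides, HMM discrimination, end-to-end planted-fixture recovery, and
determinism/conservation properties).

## CLI

Generate a synthetic fixture (genome + ground truth + role HMMs + config):

```sh
lanminer fixtures --out fx --train-peptides 100
```

Train a per-class SVM from labeled peptides (`label=1|0` in FASTA headers):

```sh
lanminer train --labeled fx/training.fasta --class II --seed 0 --out svm_II.bundle
```

Add the model to the config and mine:

```sh
# fx/config.json: {"hmms": {...}, "models": {"I": "svm_II.bundle", ...}}
lanminer mine --genbank fx/genome.gbk --config fx/config.json --out run1
lanminer census --report run1
```

`mine` writes `precursors.tsv`, `precursors.gff3`, `cores.fasta`,
`census.tsv`, `gc_pairs.tsv`, and `run_summary.json`; reruns on identical
inputs are byte-identical. Exit codes: 0 success (including empty results),
2 configuration error, 3 all inputs unparseable.

Real Pfam models (LanC-like anchor, dehydratase N/C, class-II dehydratase,
protein kinase) and custom class III/IV cyclase HMMs can be supplied as
HMMER3 text files via the same config; the packaged fixture models exist so
the full pipeline runs without downloads.

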