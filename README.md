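# chalkmir

Small-RNA MIRNA discovery, quantification and differential-expression
pipeline for multi-genotype heat-stress experiments, with a synthetic-data
generator carrying known truth.

The pipeline implements the analysis chain used for caryopsis-style sRNA
studies:

- **Novel-MIRNA discovery** — exact/1-mismatch ungapped read mapping on both
  strands, gap-merge cluster calling, known-locus subtraction (GFF3),
  base-pair-maximising hairpin folding (external dot-bracket structures
  accepted), miRNA\* derivation with 2-nt 3′ overhangs, and duplex
  evaluation (≤ 5 mismatched nt AND ≤ 3 asymmetric-bulge nt in the
  mature/star duplex).
- **Processing precision** — per-locus, per-library ratio of reads matching
  the mature, star or their 1-nt positional end variants; acceptance needs
  ≥ 10 mature reads and a ratio ≥ 0.75 (20–22-nt matures) or ≥ 0.90
  (23–24 nt) in at least 4 libraries.
- **Quantification** — mature+star catalog with redundant sequences merged,
  single best-hit read attribution (≤ 1 mismatch, no gaps, ≤ 1-nt end
  extension/truncation), raw counts and CPM (counts per million clean
  reads).
- **Differential expression** — common NB dispersion by conditional maximum
  likelihood, conditional exact test per contrast (raw p < 0.05), NB-GLM
  likelihood-ratio test for the genotype × treatment interaction, and
  shared / group-exclusive / genotype-specific set comparison.
- **Phenotype & qPCR utilities** — percent change, Pearson correlation with
  cor.test-style p-values, and 2^−ΔΔCT relative expression.
- **Synthetic data** — genomes with planted, criteria-passing hairpin loci,
  NB-distributed library counts with treatment fold changes, tunable dicing
  precision, and 24-nt-biased background siRNA clusters.

## CLI

All stages are exposed under a single entry point:

```sh
# simulate a 2-genotype experiment with known truth
chalkmir simulate --config design.json --out sim/ --seed 7

# discover novel MIRNA loci from FASTQ libraries
chalkmir discover --genome sim/genome.fa \
    --library sim/Cyp_CDT_r1.fastq --library sim/Cyp_HDT_r1.fastq \
    --known known_mirnas.gff3 --out novel/

# evaluate precursor structures against the duplex criteria
chalkmir evaluate-hairpins --hairpins hp.fa --mature mature.fa --out duplex.tsv

# quantify against a mature/star catalog (counts + CPM)
chalkmir quantify --catalog mature.fa --library lib1.fastq --library lib2.fastq --out quant/

# differential expression and the interaction term
chalkmir de --counts quant/counts.tsv --clean-sizes quant/clean_sizes.tsv \
    --samples samples.tsv --group-a CDT --group-b HDT --interaction --out de/

# cross-genotype set comparison
chalkmir compare-sets --table Cyp=de_cyp.tsv --table Lagr=de_lagr.tsv \
    --low Cyp --high Lagr --out sets.json

# phenotype / qPCR arithmetic
chalkmir pheno --traits traits.tsv --out pheno.tsv
chalkmir qpcr --ct-table ct.tsv --out qpcr.tsv
```

All formats are plain text: FASTA/FASTQ, GFF3 (1-based inclusive on disk,
0-based half-open in memory), Vienna dot-bracket (.dbn), TSV, JSON.

## Notes

- The built-in folder maximises base pairs (Watson–Crick + G:U, minimum
  loop 3 nt) and is deterministic; thermodynamic structures from any
  external folder can be supplied as `.dbn` files at every stage that folds.
- Multi-mapped reads contribute their full count to every best-stratum
  locus by default; `fractional=True` (API) splits counts evenly instead.
- The duplex criteria are applied conjunctively (≤ 5 mismatches AND ≤ 3
  asymmetric-bulge nucleotides); `--literal-or` switches to the permissive
  disjunctive reading.
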