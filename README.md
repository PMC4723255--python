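# radmarker

RAD-seq marker discovery toolkit: quality filtering of reads, in-silico
restriction digestion, samtools-pileup parsing, threshold-based SNP/InDel
calling, two-sample (inter-variety) marker detection with coverage/spacing
post-filters, and gene-model-based variant annotation — plus a
deterministic synthetic-data generator used as the test bed.

## CLI

All stages are subcommands of a single entry point and communicate via
plain text files (FASTQ, FASTA, pileup, TSV):

```bash
# generate a synthetic two-variety dataset
radmarker simulate --seed 7 --chroms 2 --length 200000 --genes 20 \
    --snps 100 --indels 20 --depth 20 --error 0.01 -o sim/

# quality-trim and filter reads
radmarker filter --standard relax --trim-q 20 --min-length 50 \
    -i in.fq -o out.fq --stats stats.tsv

# in-silico restriction digestion (TaqαI preset: site TCGA, cut T/CGA)
radmarker digest -g genome.fa --site TCGA --cut-offset 1 --min 400 --max 600

# single-sample SNP/InDel calling from a samtools pileup
radmarker call -p sim/A.pileup -o snpinfo_A.tsv --min-depth 3 \
    --min-mut-reads 3 --min-ratio 0.2 --hetero-level 0.3

# two-sample marker discovery (both directions + post-filters)
radmarker somatic -a sim/A.pileup -b sim/B.pileup -o markers.tsv

# locate markers in gene models, classify coding effects
radmarker annotate -m markers.tsv -g sim/genome.fa -a sim/genes.gff3 \
    -o annotated.tsv --summary summary.tsv

# or everything after simulation in one go
radmarker pipeline -a sim/A.pileup -b sim/B.pileup -g sim/genome.fa \
    --gff3 sim/genes.gff3 -o run/
```

## Calling rules (defaults)

* variant site: depth ≥ 3, > 2 reads supporting the dominant non-reference
  allele, mutant ratio > 20 % and ≥ the candidate proportion floor (0.3);
  genotype HOM at ratio ≥ 0.8, else HET;
* clean control site: depth ≥ 10, < 2 mutant reads, mutant ratio < 4 %;
* post-filters: treat depth ≥ 8 with zero control mutant reads, and any
  surviving markers closer than 10 bp on a chromosome are all removed.

All thresholds are exposed as CLI flags / dataclass parameters.

## Layout

| module | purpose |
|---|---|
| `radmarker.fastq_qc` | terminal quality trimming + four named filtering standards |
| `radmarker.digest` | restriction-site scan, fragment lengths, size-window yield check |
| `radmarker.pileup` | samtools pileup text → per-position allele counts |
| `radmarker.variant_call` | threshold-based SNP/InDel calling, SnpInfo/VCF output |
| `radmarker.somatic` | bidirectional two-sample comparison + post-filters |
| `radmarker.annotate` | GFF3 gene models, region categories, coding effects, MAS marker selection |
| `radmarker.fixtures` | deterministic simulator: genome, genes, planted variants, pileups, truth evaluation |
| `radmarker.cli` | `radmarker` command-line entry point |
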