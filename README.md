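# ampliclone

Genotyping of CRISPR-edited clones from barcoded amplicon reads, plus the
workflow statistics of a nanopen single-cell chip run.

The package covers the full downstream path for knock-in screening
experiments in diploid cells:

1. **simulate** — generate ground-truth edited clones (HDR knock-in, NHEJ
   indels/point mutations, post-division "late" editing with >2 alleles,
   cross-contamination), their paired amplicon reads with inline sample
   barcodes and a Phred-aware error model, plus per-pen growth tables and
   export records;
2. **demux** — split multiplexed FASTQ pairs by the inline R1 barcode
   (Hamming-distance matching, ambiguity-safe);
3. **align** — deterministic semi-global (glocal) pairwise alignment with
   affine gap costs (numba-accelerated Gotoh DP with provably optimal
   gapless fast paths), variant extraction with VCF-style left
   normalization, optional SAM/VCF export;
4. **classify** — per-read WT / HDR / NHEJ calls against the wild-type and
   knock-in references using a quality-30 variant filter inside the edit
   window, tallied into per-clone allele tables;
5. **genotype** — clone-level diploid labels (WT/WT … HDR/HDR,
   NHEJ/NHEJ_same, NHEJ/NHEJ_diff, MULTI_ALLELIC, LOW_COVERAGE) and run
   summaries with HDR/NHEJ allele rates;
6. **chip** — on-chip clonal expansion (fraction of single-cell pens
   reaching ≥6 cells at 72 h), pen cross-contamination, log-linear
   doubling-time fits, export efficiency, post-export viability stratified
   by cells exported, staining positivity, and a binomial screening-size
   planner.

Everything is reproducible: one master seed, per-clone/per-pen child
streams derived by stable hashing, byte-identical outputs for identical
configs.

## Command line

```bash
# full run (simulate -> demux -> classify -> genotype -> report) from YAML
ampliclone run --config run.yaml --outdir out/

# quick simulated dataset with defaults
ampliclone simulate --seed 1 --n-clones 12 --outdir out/

# demultiplex existing FASTQ pairs
ampliclone demux --fastq1 R1.fastq --fastq2 R2.fastq \
    --barcodes barcodes.tsv --max-mismatch 0 --outdir demux/

# genotype one demultiplexed sample against a WT/HDR FASTA pair
ampliclone genotype --fastq1 demux/cloneX_R1.fastq --fastq2 demux/cloneX_R2.fastq \
    --sample-id cloneX --references refs.fasta \
    --cut-site 200 --window-start 188 --window-end 212 --out-prefix cloneX

# chip statistics from pen/export tables
ampliclone chipstats --pens pens.tsv --exports exports.tsv \
    --intensity-threshold 500 --out chip.json

# screening-size planner: expected usable clones and binomial tail
ampliclone plan --p 0.05 --viability 0.5 --n 100

# small packaged datasets with ground truth
ampliclone make-fixture --profile mixed-day4 --outdir fixture/
```

Exit codes: `0` success, `1` data error, `2` configuration error.

Run outputs include paired FASTQ, a ground-truth TSV, barcode map,
per-clone allele and genotype TSVs, JSON summaries, and a `manifest.json`
embedding the config, seed, per-stage counts and SHA-256 checksums of all
outputs. A run with ground truth attached also reports a recovery table
(called vs. true genotype).

## Layout

```
src/ampliclone/
  simulate.py    ground-truth clones, reads, pens, exports
  demux.py       inline-barcode demultiplexing
  align.py       affine semi-global alignment + variant extraction
  classify.py    read-level WT/HDR/NHEJ calls, allele tables
  genotype.py    clone genotype labels, run summaries, plots
  chip.py        chip/export statistics and screening planner
  pipeline.py    run orchestration, configs, manifests, fixtures
  cli.py         click-based CLI
tests/           pytest suite incl. acceptance criteria and oracles
scripts/acceptance.py
```
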