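# vexseq

Design, quality control, and quantification for barcoded massively parallel
splicing reporter assays.

## The problem

Tens of thousands of human variants fall in or near alternative exons, and
most of their effects on pre-mRNA splicing are unknown. A barcoded
mini-gene reporter assay measures those effects at scale: each candidate
exon (with ≥50 nt of upstream and ≥20 nt of downstream intron) is cloned
between two constitutive exons, every designed sequence — reference exon,
variants, and two splice-site controls — is linked to at least three unique
8-nt barcodes downstream of the final exon, and RNA sequencing with 10-nt
unique molecular identifiers (UMIs) counts inclusion and skipping molecules
per barcode. The package computes, per variant and condition,

    Ψ  = 100 · n_inclusion / (n_inclusion + n_skipping)
    ΔΨ = Ψ(variant) − Ψ(matched reference exon)

and runs the analyses a splicing-reporter study needs around them. It is
aimed at groups designing such libraries, processing their sequencing runs,
or benchmarking analysis choices on simulated data with known truth.

## What's inside

| Module | Role |
| --- | --- |
| `vexseq.design_pool` | Build barcoded oligo libraries from exons (BED/GTF) + genome (FASTA) + variants (VCF); splice-site controls; design-rule validation and pool summaries |
| `vexseq.plasmid_qc` | Merge plasmid amplicon read pairs, verify barcode–variant associations, apply the 15%-incorrect barcode filter, report misassignment rate and depth skew |
| `vexseq.splice_quant` | Demultiplex RNA amplicons by barcode, collapse UMIs, classify inclusion/skipping/unannotated per molecule against variant-specific references, compute Ψ/ΔΨ |
| `vexseq.downstream` | Exonic splicing enhancer (hexamer) score deltas, cross-condition directionality agreement, the 50-nt premature-termination-codon rule with an NMD regression, conservation contrasts, external-score joins |
| `vexseq.simulate` | Synthetic pools and FASTQ read sets with planted truth (depth skew, misassignment, PCR duplicates, sequencing errors) |
| `vexseq.cli` | `vexseq design / qc-plasmid / quantify / analyze / simulate / check` |

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Simulate a small experiment, QC the plasmid pool, and quantify splicing:

```sh
vexseq simulate --seed 4 --n-exons 2 --out sim_out
vexseq qc-plasmid --r1 sim_out/plasmid_1.fastq.gz --r2 sim_out/plasmid_2.fastq.gz \
                  --pool sim_out/pool.tsv --out qc_out
vexseq quantify   --r1 sim_out/rna_K562_1.fastq.gz --r2 sim_out/rna_K562_2.fastq.gz \
                  --pool sim_out/pool.tsv --condition K562 \
                  --kept-barcodes qc_out/barcode_fidelity.tsv --out quant_out
```

`qc_out/qc_summary.json` from that run begins:

```json
{
  "misassignment_rate": 0.04425837320574163,
  "misassignment_rate_kept": 0.043687374749499,
  "skew_ratio": 5.89578163771712,
  "n_kept": 41,
  "n_dropped": 1
}
```

The simulator planted a 4.59% barcode–variant misassignment rate and a
log-normal depth distribution whose 90th/10th-percentile skew is 5.5 in
expectation; the pipeline recovers both from the reads alone (4.43% and
5.90 here, within sampling error at this depth), and drops 1 of 42 barcodes
for carrying ≥15% incorrect reads. `quant_out/psi_variant.tsv` then holds
per-variant Ψ with molecule counts, and `quant_out/delta_psi.tsv` the ΔΨ
values against each exon's reference.

The same pipeline is importable as a library; `SimulationConfig`,
`simulate_pool`, `run_plasmid_qc`, `quantify`, `aggregate`, and `delta_psi`
are the main entry points.

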