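# Methods

## The assay this package models

A variant-exon splicing reporter experiment measures how genomic variants
change exon inclusion. A candidate alternative exon plus its intronic flanks
(the *test region*) is inserted between two constitutive exons of a
mini-gene reporter. Each designed sequence — the reference exon, each
variant, and two per-exon splice-site controls — is tied to at least three
unique 8-nt barcodes placed downstream of the final exon, so that a
transcript remains attributable to its variant even when the test exon is
skipped. After transfection, RT-PCR with a 10-nt unique molecular identifier
(UMI) and paired-end sequencing yield, per molecule, an unambiguous splicing
outcome. Percent spliced in is

  Ψ = 100 · n_inclusion / (n_inclusion + n_skipping)

over UMI-collapsed molecules, and the variant effect is
ΔΨ = Ψ(variant) − Ψ(matched reference exon) in the same condition.

## Library design (`design_pool`)

Design rules: exon length within [68, 97] nt, ≥50 nt of upstream intron
(enough to cover most branchpoints), ≥20 nt of downstream intron, ≥3
barcodes per variant. Oligos are assembled as

  fwd_primer · PstI · upstream_intron · exon · downstream_intron · MfeI ·
  SpeI · barcode · XbaI · revcomp(rev_primer)

matching a two-step cloning strategy (PstI/XbaI insert, then SpeI/MfeI to
add the final exon between test sequence and barcode). The exact insert map
of any given plasmid differs; the part order is therefore configurable. Any
restriction motif occurring outside its designated site aborts the design
with the motif name and offset, because it would be cut during cloning.

Coordinates: genomic inputs are 1-based inclusive (VCF/GTF convention; BED
is converted at the reader), internal offsets are 0-based half-open.
Minus-strand exons are reverse-complemented at extraction so everything
downstream is strand-free; variant alleles are complemented at application
time. Deletions that shorten a flank below its minimum are padded back from
retained genomic context rather than silently accepted; padded bases are
not addressable by further variants.

Controls per exon:

- *Mutated splice sites*: 3′ss AG→TC and 5′ss GT→CA, nothing else —
  an inclusion-killing control. Applying it twice is an error because the
  boundaries are no longer canonical.
- *Consensus splice sites*: the 22 nt of upstream intron ending at the exon
  become a 20-nt pyrimidine tract + AG, and the first 6 nt of downstream
  intron become GTAAGT — an inclusion-maximizing control. The tract
  composition is not specified anywhere authoritative, so we use the
  deterministic alternating "TC"×10 (configurable); any pyrimidine-only
  choice serves the purpose.

Barcodes are uniform random 8-mers filtered to exclude every restriction
motif and its reverse complement as a substring, with pairwise Hamming
distance ≥ 2 so that a single sequencing error cannot convert one pool
barcode into another. The distance constraint and motif exclusion go beyond
the published count/length rule; they are cheap and strictly protective.
Generation is rejection sampling with an exact coverage-set membership test
(every word within distance 1 of an accepted barcode is recorded), which is
O(1) per candidate. A Singleton-bound argument (a distance-2 code of length
8 over 4 letters has at most 4⁷ words) rejects infeasible requests
immediately.

## Plasmid QC (`plasmid_qc`)

Paired amplicon reads covering the whole insert are merged by their 3′
overlap: among admissible overlaps (≥10 nt, mismatch fraction ≤ 0.25) the
one maximizing matched bases wins; disagreements resolve to the
higher-quality base, ties to read 1. A unique exact 16-mer seed pins the
shift in the common case; the full shift scan is the fallback and the
definition.

Each merged read is assigned by exact match of the 8-mer following the SpeI
anchor, then classified against the designed pool:

- **expected** — matches the expected oligo at every designed variant locus
  of its exon;
- **other_designed** — matches a *different* designed oligo of the same exon
  at those loci (a barcode–variant misassignment);
- **indel_only** — length-changing differences outside the loci, identity
  still ≥ 90%;
- **unrecognized** — identity < 90%, or no clean locus signature (this
  includes reads whose only flaw is a sequencing error inside a variant
  locus, mirroring how a locus-targeted caller would behave).

Barcodes with ≥15% incorrect reads are dropped; the boundary is inclusive
(exactly 15% incorrect ⇒ dropped). The published description of the same
rule appears in two forms that disagree exactly at 85% correct; the
threshold-inclusive form is implemented and the cutoff is a parameter.

Pool diagnostics: the misassignment rate is #other_designed over all
barcode-assigned reads (the denominator is a choice; the rate over kept
barcodes only is also reported), and the skew ratio is P90/P10 of
per-barcode depth with linear interpolation between closest ranks
(rank = 1 + (n−1)p/100), i.e. numpy's default percentile method.

## Splicing quantification (`splice_quant`)

Read 2 carries the UMI (bases 0–9), the gene-specific 3′-UTR anchor, and —
walking back along the transcript — the XbaI site, the reverse-complemented
barcode, the SpeI site, and the reverse complement of exon 3. A read is
accepted when the exon-3 check sequence and the restriction site adjacent
to the barcode each match within 1 mismatch and the barcode matches a pool
barcode exactly (no 1-mismatch rescue: with pairwise distance ≥2 a rescue
would be safe for pool-vs-pool confusions but is deliberately conservative
toward sequencing artifacts; it is a configuration point). Reject reasons
(no_exon3, bad_site, unknown_barcode) are counted; totals always reconcile.

Read 1 starts at a fixed PCR primer inside exon 1, so the exon-1 boundary
position is known from the layout, not inferred. The `anchor_k` = 10 bases
after the boundary are compared to the start of the variant-specific test
exon (inclusion) and to the start of exon 3 (skipping); the unique label
within ≤1 mismatch wins and anything else — both, neither, or a too-short
read — is UNANNOTATED and excluded from Ψ. This anchored classification
replaces a spliced aligner: the amplicon has fixed structure, so the
junction is the only degree of freedom. Tests enforce agreement with a
brute-force edit-distance assignment against the two full isoform
sequences.

UMI collapse is exact-match per (barcode, UMI) with majority vote over PCR
copies; exact ties are discarded and counted. Ψ with zero informative
molecules is NA, never imputed, and NA propagates out of all means.

Aggregation is unweighted means at each level: barcode Ψ → variant Ψ per
replicate → cell-line mean → cross-cell mean of means. Pooled-count Ψ is
available by summing the exported per-variant inclusion/skipping counts
(also the interchange format for external differential-splicing tests).

## Downstream analyses (`downstream`)

- **ΔESE (hexamer) scores**: the change window is every hexamer fully
  inside the exon that overlaps the variant locus; ΔESE is the sum of
  hexamer scores over the variant's window minus the reference's. For
  indels the two windows differ in length (union of affected windows per
  side). The windowed-sum form was chosen for two properties checked in
  tests: swapping reference and variant negates the score, and positions
  outside the window cannot contribute. Absent hexamers score 0.
- **Per-hexamer association**: each gain event contributes +ΔΨ and each
  loss −ΔΨ to the hexamer's mean.
- **Directionality agreement**: at threshold τ, a variant is eligible when
  |ΔΨ| > τ (strict, as worded) in the conditioning cell line and both
  values are nonzero; agreement is sign equality. Note the contrast with
  the conservation grouping below, which is inclusive (|ΔΨ| ≥ 5), exactly
  as each rule is printed.
- **PTC rule**: translate from the reporter ATG; the first in-frame stop is
  a premature termination codon when the last exon–exon junction lies ≥50
  nt downstream of the stop codon's last base. The boundary (exactly 50)
  counts as a PTC; "50 nucleotides before" is read inclusively and the
  distance is configurable.
- **NMD model**: OLS of control (NMD-competent) Ψ on knockdown Ψ and the
  PTC flag, with a seeded 2/3–1/3 train/test split stratified by the PTC
  flag (stratification keeps rare flags represented in both halves). The
  nested model without the PTC term is refit on the same split; the model
  comparison direction (PTC term lowers held-out MSE when a true effect
  exists) is an acceptance property. Applying the fit with ptc = 1 to
  measured knockdown-context Ψ predicts the endogenous (NMD-exposed) Ψ of
  stop-gain/frameshift variants; predictions are clamped to [0, 100] with
  clamping flagged.
- **Conservation**: two-sided Mann–Whitney U between |ΔΨ| ≥ 5 and < 5
  groups, optionally within annotation subgroups (non-protein-changing,
  synonymous, intron). Splice-site strength, conservation, and effect
  annotations are ingested from TSV — computing them is out of scope; when
  a variant has several annotations the first reported one wins.

## Simulator (`simulate`)

The generator emulates the features that stress each pipeline stage:
log-normally skewed per-barcode depth, per-read barcode–insert
misassignment (a chimera keeping this barcode but another designed
variant's insert), geometric PCR duplication on top of per-molecule UMIs,
and i.i.d. substitution sequencing errors at Q30 (constant qualities; no
quality model is claimed, and indel errors are off by default because the
amplicon classifier oracle assumes substitutions).

Default study conditions: misassignment rate 0.0459 and depth σ = 0.665
(chosen so the P90/P10 skew is 5.5) — the values measured for the real
plasmid pool; error rate 0.1%; duplication p = 0.5 (mean two reads per
molecule); 200 molecules per barcode; read length 150. Truth Ψ: reference
exons ~ Beta(2,2)·100 per condition; SNV effects are a mixture of a point
mass at 0 (probability 0.5) and N(0, 15), shared across cell lines with
per-line N(0, 3) jitter (an `independent` mode exists for null
experiments); mutated controls ~ Beta(1,20)·100 and consensus controls
~ Beta(20,1)·100, which puts them near 0 and near 100 without being
degenerate. All randomness flows from one master seed through named
substreams so stages can be rerun independently; outputs are bitwise
reproducible.

What the simulator does **not** model — and hence what passing tests do not
show about real data: position-dependent error profiles, indel sequencing
errors, cryptic/novel splice sites (real UNANNOTATED reads are biology as
well as noise), intron retention, RNA secondary structure, synthesis errors
within oligos, and NMD kinetics beyond an optional per-variant survival
factor on inclusion molecules.

The reporter backbone shipped as `DEFAULT_BACKBONE` is synthetic: exon 1
begins with the published read-1 PCR primer, but the remainder of both
constitutive exons is an arbitrary motif-free stand-in, since the plasmid
sequence is not distributed.

## Numerical and scale choices

- Percentiles: linear interpolation between closest ranks, fixed.
- Alignment scoring for plasmid variant calling (match +1, mismatch −1,
  gap open −2, extend −1) and the 90% identity floor are package choices;
  equal-length reads take an exact Hamming path.
- Merge parameters: min overlap 10, max mismatch fraction 0.25.
- Test problem sizes are the package's own: the Ψ-recovery check uses
  50 exons × 5 variants × 3 barcodes × 200 molecules (the design's minimum
  barcode multiplicity at a depth where binomial error is ~2 Ψ points);
  control-ordering and agreement checks use 10 seeds of smaller pools;
  the classifier oracle uses 1,000 reads.
- `scripts/acceptance.py` reruns design at the published pool scale
  (110 exons / 2,059 entries) and every other stage at reduced but
  statistically meaningful sizes, deriving all substream seeds from the
  single `--seed`.

## Known limitations

- `call_read_variant` classifies a read whose only defect is an error at a
  variant locus as unrecognized rather than expected; per-barcode fidelity
  is accordingly a slightly conservative estimate (≈3% at default error
  rates), far from the 15% filter boundary.
- The misassignment-rate estimator inherits the same effect: reads that are
  both misassigned and error-carrying at a locus can fall into
  unrecognized, biasing the estimate slightly downward (≈4.4% recovered
  for 4.59% planted at default settings).
- Indel variant support is first-class in design but plasmid-QC calling of
  indel *variants* (as opposed to indel artifacts) relies on exact-length
  signatures; complex nested indels are out of scope.
- The NMD regression is linear in Ψ and a single PTC indicator; no
  interaction or dose term is modeled.
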