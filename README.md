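# scnaumi

Guided cell-barcode and UMI assignment for noisy long-read single-cell
RNA sequencing, with per-UMI consensus calling, transcript-isoform
quantification, novel-isoform discovery and per-molecule SNV/RNA-editing
matrices.

## The problem

Droplet-based single-cell protocols (10x Chromium) tag every cDNA with a
16-nt cell barcode and a 10–12-nt unique molecular identifier (UMI).
Long-read sequencing of these libraries preserves full-length isoform
structure, but at a 5–10% per-base error rate the barcodes themselves
become hard to read: clustering raw noisy barcodes is unreliable because
two reads from the same cell can disagree at several positions.

This package implements the guided strategy: a high-accuracy short-read
run of the *same* library defines, for every gene (and every 500-nt
genomic window), exactly which cell barcodes — and for every (gene, cell),
which UMIs — exist.  A long read is then only compared against that small
search set, which makes aggressive edit-distance matching safe.

The core machinery:

* **2-bit barcode encoding** (A=00, G=01, T=10, C=11): a 16-nt barcode is
  one integer, and substitutions, insertions and deletions are bitwise
  operations.  A window of core length *L* with a 4-base extension buffer
  has exactly 8·*L* single-edit descendants (128 for *L*=16; 48 for
  substitutions only), and the branching process generates
  Σᵢ₌₁^ED 128ⁱ = 2,113,664 candidate permutations for ED = 3.
* **Dynamic edit-distance policy**: the maximal allowed ED (1–4) is chosen
  per search from the candidate-set size, calibrated by collision
  simulations so the false-assignment probability stays below a target
  (defaults 5% for cell barcodes, 2% for UMIs).  Because a wrongly
  assigned cell almost never carries a matching UMI for the same gene, the
  surviving false rate is roughly the product of the two stage rates.
* **Per-UMI consensus**: reads of one (cell, gene, UMI) molecule are
  collapsed — single read verbatim, best-of-two by alignment divergence,
  or a star multiple alignment with majority voting for ≥3 reads — lifting
  per-molecule identity from raw-read level (~93%) to >99%.
* **Isoform matching**: a molecule is assigned to an annotated transcript
  when the splice-junction chains match exactly within a ±2-base margin;
  unmatched molecules are collapsed into novel-isoform candidates,
  classified by splice-site novelty, and validated against short-read
  junctions, CAGE TSS and polyadenylation tracks (±50 nt).
* **SNV/editing matrices**: consensus molecules (never raw reads) vote at
  user-specified genomic sites, giving per-cell and per-group editing
  rates and per-molecule co-editing tables.

All stages are exercised end-to-end on synthetic data with known ground
truth (`scnaumi.simulate`), which emulates the full 10x read architecture
`adapter – cellBC – UMI – poly(T) – cDNA(rc) – TSO(rc)` including reverse
orientation, chimeric concatemers and configurable error profiles.

## Worked example

```sh
scnaumi simulate --preset small --seed 7 -o demo
# wrote 325 reads, 109 molecules to demo

scnaumi index --tsv demo/guide.tsv -o demo/guide.idx
# indexed 99 records (0 skipped): 10 genes, 16 windows

awk 'BEGIN{FS=OFS="\t"} NR==1{print "read_id","gene","chrom","pos"; next} \
     {print $1,$5,$6,$7}' demo/truth_reads.tsv > demo/loci.tsv
scnaumi assign --fastq demo/reads.fastq --loci demo/loci.tsv \
               --index demo/guide.idx --seed 7 -o demo/assigned.tsv
# assigned 288/325 reads
```

The run simulates 109 molecules across 20 cells and 10 genes at the
default 7% per-base error, indexes a short-read guide covering 90% of the
molecules (99 of 109 captured — the sequencing saturation), and assigns
288 of 325 long reads a (cell, UMI) pair.  `demo/assigned.tsv.qc.json`
records the read-fate funnel (322 reads passed the structural scan, 300
got a cell, 288 also got a UMI — the remainder are mostly molecules absent
from the guide) and the edit-distance histograms of the accepted matches
(cell barcodes: 93 at ED 0, 109 at ED 1, 69 at ED 2, …), the signature of
error-tolerant but guided matching.

The library API mirrors the CLI: see `scnaumi.kernel.find_match`,
`scnaumi.assign.assign_reads`, `scnaumi.consensus.consensus`,
`scnaumi.isoforms.match_isoform`, `scnaumi.novel.collapse`,
`scnaumi.snv.call_sites`.

## Documentation

`docs/methods.md` describes the models, parameters, numerical choices and
the limits of what the synthetic benchmarks demonstrate.
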