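# Methods

This note documents the models and procedures implemented in `scnaumi`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmarks do and do not show.

## Read model and structural scan

A 10x-style long read, in canonical (barcode-first) orientation, is

    adapter(22 nt, 3' PCR priming site) · cellBC(16) · UMI(10/12) ·
    poly(T) · cDNA(reverse complement) · TSO(reverse complement)

The scan proceeds in fixed order:

1. **Poly(A/T)**: a terminal run of ≥20 nt at ≥85% A (3' end) or T
   (5' end) starting within 100 nt of the read end.  Runs are found by a
   sliding 20-mer composition filter; merged qualifying windows are then
   *boundary-refined*: a run may not end on a base other than its target
   base, its terminal 20-mer must itself satisfy the composition rule,
   and boundaries prefer a clean 3-base homopolymer anchor (falling back
   to a single-base anchor when the stricter rule would erase the run,
   which keeps edge-mismatched tails like 17-of-20 detectable).  Without
   the refinement the run end can drift several bases into T-containing
   cDNA, which systematically truncates the extracted insert.  Runs that
   start inside the terminal window may extend beyond it.  A read with
   qualifying runs at both ends is a chimera suspect and is rejected; a
   read with neither is rejected.
2. **Orientation**: poly(T) at the 5' end means the read is already
   barcode-first; poly(A) at the 3' end means its reverse complement is.
3. **Adapter**: the terminal 10 nt of the adapter (`CTTCCGATCT`) are
   located between the read 5' extremity and the poly(T) by sliding
   global alignment with unit costs (substitutions and indels all cost 1;
   the alignment is "semi-global": the probe aligns fully, the target
   position is free).  Cost ≤3 is required; among equal-cost positions
   the one closest to the read extremity wins.  Unit costs are the
   minimal choice consistent with counting "mismatches" while allowing
   indels.
4. **Internal adapter**: the same probe rule applied to the read interior
   (terminal 150 nt excluded), but only within ±50 nt of an internal
   A/T-rich run (same composition rule, anywhere in the read).  A hit
   flags the read as a chimeric concatemer.  The 50-nt proximity window
   is configurable; the underlying signature — an adapter right next to a
   poly(A/T) tract in the middle of a read — is what the rule encodes.
5. **Extraction windows**: the barcode window is the 16 nt after the
   adapter end plus a 4-base extension buffer; windows at ±1 are also
   tried downstream to absorb terminal indels in the adapter match.  The
   UMI window (UMI length + 4) is re-anchored after barcode matching at
   the position implied by the matched barcode's net indel shift.

For cDNA extraction the scan also records, on the mRNA-sense strand, the
TSO end (TE; probe = 3' 10 nt of the TSO, cost ≤3, searched in the first
200 nt; read start if absent) and the poly(A) start (PE); the insert is
`mrna[TE:PE]`.  TSO detection parameters are a package choice — the
upstream contract is only that the insert lie between the two tags.

## Barcode kernel

Barcodes are packed 2 bits/base (A=00, G=01, T=10, C=11), position 0 in
the least-significant bits, so append/pop of extension bases are shift
operations and equality with a candidate barcode is one integer
comparison.

Editing keeps the core length fixed: a window of core length *L* with a
4-base extension has per round 3*L* substitutions, 4*L* insertions (the
last core base is pushed into the extension) and *L* deletions (the first
extension base is pulled in), i.e. 8*L* = 128 descendants for *L* = 16.
`count_permutations` reports the generated-permutation count
Σᵢ₌₁^ED (8L)ⁱ — 2,113,664 for *L*=16, ED=3 — counting paths, not distinct
sequences (the exclusion of the unedited word from the sum reproduces the
established accounting for this branching process).  When a deletion
exhausts a truncated extension a sentinel base is pulled in and any match
through it is demoted by one pseudo-edit.

`find_match` has two interchangeable strategies, tested for equivalence
against each other and against a brute-force dynamic-programming
Levenshtein oracle:

* **enum** — breadth-first enumeration of edit descendants with state
  de-duplication; each level is a batch of O(1) integer set-membership
  tests, which wins when the candidate set is large;
* **direct** — per-candidate semi-global alignment of the candidate to
  the prefixes of core+extension (one `edlib` SHW call), which wins for
  the small per-gene/per-cell sets the guide index produces.

Ambiguous results (≥2 candidates at the minimal edit distance) are never
assigned; the tie multiplicity and the next edit level producing a
different candidate (second-best) are reported.

## Edit-distance policy calibration

The maximal edit distance allowed for a search depends on the size *s* of
the candidate set.  For one random candidate, the collision probability
at edit distance *k* is `p_k = E[N_k] / 4^L`, where `N_k` is the number
of distinct cores reachable within *k* edits of a random window.  For
*k* ≤ 3, `N_k` is counted exactly by the de-duplicated enumeration on a
small sample of random windows (the counts barely vary between windows);
for *k* = 4, where the enumeration is too large, `p_4` is estimated by
Monte-Carlo sampling of `n_sims` random (window, candidate) pairs, with a
growth-rate extrapolation of the enumeration counts as fallback when no
collision is sampled.  For a set of *s* distinct candidates the collision
probability is `1 − (1 − p_k)^s`; the policy grants the largest *k* ≤ 4
keeping it at or below the target false rate, on a power-of-two bucket
grid (1…2¹⁴, sizes rounding down).

Defaults: cell barcodes (L=16) 5% target, UMIs (L=10) 2% target,
`n_sims` = 20,000.  Typical calibrated tables allow ED 4 for sets up to
tens of 16-mers, ED 2 even for 2¹⁴ 16-mers, and ED ≤ 2 for 10-mers (short
words collide much more readily).  Targets and fixed-ED overrides are
parameters.

## Assignment and accuracy estimation

Reads overlapping multiple genes try each gene's candidate set, keeping
the lowest-ED hit (ties fall back to the genomic-window set).  UMIs are
searched only within the assigned (gene-or-window, cell) UMI set — the
copy number of one gene in one cell — which is what suppresses wrongly
assigned cells at the UMI stage.

Two estimators quantify accuracy without ground truth:

* **Random replacement**: for each read assigned both stages, the
  extracted barcode (resp. UMI) window is replaced by a uniform random
  sequence and the stage re-run with the edit budget capped at the edit
  distance the true pass realized for that read; a random cell hit must
  also survive the UMI stage.  Accuracy = 100·(1 − assigned_random /
  assigned).  In the cell-replacement branch the UMI window is drawn
  random as well: the read's true UMI is statistically unrelated to the
  UMI set of a falsely matched cell, so this is equivalent in
  distribution and keeps the estimator simple.
* **Unrelated guide**: assignment re-run against the guide index of an
  independent experiment (disjoint cells), with the full policy edit
  budget.  Cross-assignment counts and the inflation of the mean edit
  distance measure the contamination floor.

## Per-UMI consensus

After dropping potentially chimeric alignments (terminal soft/hard clip
> 150 nt) and mapping-quality-0 records, a UMI group of *n* reads yields:
*n*=1 the read's cDNA verbatim; *n*=2 the cDNA of the lower-divergence
read (gap-compressed divergence from the aligner when present, edit
distance / alignment length otherwise; ties take the longer cDNA);
*n*≥3 a star multiple alignment: medoid selection by summed pairwise
edit distance over a sample of ≤20 members, global alignment of all
members (groups capped at 200) to the medoid, column-wise majority vote
with ties broken toward the medoid base, insertions emitted when more
than half the members support one, then one polishing pass realigning
members to the draft.  Members whose per-base divergence to the medoid
exceeds 0.3 (raw ~7%-error reads sit near 0.13 pairwise) are excluded
from voting — this is what suppresses chimeric/PCR-artifact copies inside
a group.  The star-MSA design replaces external partial-order-alignment
and polishing binaries while preserving the contract that identity grows
with depth.

Percent identity is measured as `100·(1 − edit_distance / max(lengths))`
under global alignment; at a 7% per-base error a raw read sits near 93%,
a 5-read consensus above 99%.

## Isoform matching and novel isoforms

Annotated transcripts are loaded from GTF (via `gffutils`), junctions
derived from adjacent exons, coordinates 0-based half-open internally.
A multi-exon molecule matches a transcript when junction counts are equal
and every donor/acceptor agrees within ±2 bases; terminal exon ends are
not compared (transcription start/end variation is the province of the
novel-isoform filters).  Strand concordance is required.  Mono-exonic
molecules — for which the junction rule is vacuous — match mono-exonic
models with overlapping spans and both ends within 100 nt (configurable).
Exactly one match is a unique call; several junction-identical models
give an ambiguous call counted at gene level only.

Unmatched molecules are collapsed by exact junction chain after snapping
each coordinate within ±2 onto an annotated splice site (mirroring the
match margin, so mapping jitter cannot split a candidate); chains that
snap onto an annotated transcript's chain are discarded as not novel.
Candidates need ≥5 supporting UMIs; 5'/3' ends and SNVs are ignored by
construction of the grouping key.  Classification: (i) all junctions
annotated (chain novel), (ii) all donor/acceptor sites annotated but ≥1
pairing novel, (iii) ≥1 unannotated site.  Validation requires all three:
every junction annotated or short-read-confirmed; strand-aware 5' end
within 50 nt (inclusive) of a CAGE interval; 3' end within 50 nt of a
polyadenylation interval.  Distances are measured to the nearest point of
the interval; a missing track leaves its flag undefined and the candidate
held.

## SNV / editing matrices

The voting unit is the consensus molecule.  Re-aligned molecules
contribute the aligned base at each listed site (deletions and clips do
not vote); per-cell ref/alt/other counts, per-group rates
alt/(ref+alt)·100 with 'other' excluded from the denominator, and 2×2
co-occurrence tables over dual-covering molecules (with conditional rates
and a Fisher exact p-value, reported but not used for filtering) are
derived from the molecule-level calls.  No minimum consensus depth is
imposed by default; `min_reads_per_umi` exposes one.

## Synthetic data

The generator builds one toy chromosome with 2–10 exon genes (exons
80–400 nt, introns 100–800 nt), full-length plus exon-skipping isoforms,
distinct cell barcodes kept at pairwise Levenshtein distance ≥4
(emulating whitelist separation), Poisson molecule counts per (cell,
gene), and unique UMIs per (cell, gene).  The guide emulates short-read
capture as an independent Bernoulli per molecule (the sequencing
saturation); an unrelated-experiment guide keeps the gene and
molecule-count profile but swaps in disjoint cells and fresh UMIs.

Reads carry the full architecture with a 20–60 nt poly(T), independent
per-base errors (default 7% total: 55% substitutions, 25% insertions,
20% deletions — the middle of the 5–10% error band of current long-read
chemistry), 50% reverse-complemented, and optional chimeric concatemers
(two molecules joined with an internal adapter next to an internal
poly(T)).  Everything derives from one integer seed via a single
`numpy` generator; all outputs are byte-reproducible.

What the simulator does **not** model: homopolymer-dependent and
quality-correlated error profiles, transcript-abundance realism, intronic
or intergenic reads, degraded/internally-primed cDNA, barcode-sharing
doublets.  Passing benchmarks therefore demonstrate the correctness and
calibration of the algorithms under the stated error model, not
performance on any particular instrument's error spectrum.

Benchmark problem sizes were chosen to exercise the statistics at
desk scale: the assignment benchmark uses 50 cells × 200 genes at guide
saturation 0.9 with ~20,000 reads at 7% error; the consensus benchmark
uses 200 molecules × 5 reads on 500–1500 nt templates.

## Known limitations

* Homopolymer boundaries are intrinsically ambiguous: a cDNA ending in A
  merges into the poly(A) tail, so a few terminal bases of the insert can
  be mis-apportioned; consensus identity absorbs this at the ~0.1% level.
* The enumeration strategy is exponential in the edit budget and is
  automatically bypassed in favour of per-candidate alignment for deep
  searches over small sets.
* The guide index assumes the short-read data is already cell-filtered;
  no knee-point/empty-drop detection is performed.
* Novel-isoform discovery validates against provided tracks only; no
  internal-priming screen is re-applied at collapse time (chimera flags
  from the scan stage are relied upon upstream).
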