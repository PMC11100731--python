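# Methods

## The inference problem

Bone-marrow plasma cells (BMPCs) can arise along two routes: a germinal
center (GC) B cell differentiates directly into a plasma cell, or it
first becomes a circulating memory B cell (MBC) that later differentiates
upon recall. The two routes predict different repertoire-level
signatures. MBCs exit GCs early, so their progeny carry less somatic
hypermutation (SHM); recall expansion happens outside GCs, so an
MBC-derived expanded clone consists of cells copying one identical
heavy-chain sequence (*isogenic*) or appears as unexpanded *singlets*.
Direct GC exports keep mutating as the clone is emitted, so a GC-derived
expanded clone contains non-identical members (*heterogenic*) and higher
SHM. Surface CD19, measured by oligonucleotide-tagged antibody (ADT)
counts, indexes the same axis: the model under test is that CD19-high
BMPCs are enriched for GC exports and CD19-low BMPCs for MBC progeny.
The pipeline computes every ingredient of that argument — QC, isotype,
SHM, clonal structure, CD19/SHM bins — and the rank statistics relating
them.

## Pipeline definitions

**QC.** A cell is retained iff mitochondrial fraction < `mito_max`
(default 0.05, exclusive), `rna_min ≤ total_rna ≤ rna_max` (defaults
200/4,000, inclusive — interpreted as total UMI counts; a detected-genes
reading is accommodated by supplying that column instead), and all
configured lineage-marker genes have zero counts (any expression
excludes; the threshold is configurable). Removed cells are attributed
to their first failing rule in the fixed order mito → rna → lineage, so
removal counts partition the removed set.

**Isotype.** A VDJ constant-region call is authoritative. Otherwise the
GEX fallback takes the argmax subclass m over the nine IGHC genes and
assigns it iff count(m)/Σcounts > 1/2 (strict) and count(m) > 20
(strict); argmax ties, exact halves and exact 20s are unassigned — the
conservative reading of "more than". The benchmark harness recomputes
GEX-only calls for cells that also carry a VDJ call; accuracy is the
fraction of *GEX-assigned* cells matching VDJ truth (GEX-unassignable
cells are tabulated separately, not counted as errors), and per-subclass
specificity is reported alongside.

**SHM.** `100 × mismatches / comparable positions` between the observed
and germline heavy-chain strings at equal aligned length. Positions
where *either* string is not A/C/G/T (N, gap) are excluded from both
numerator and denominator; the computation covers all comparable aligned
positions supplied, not the V region only. Zero comparable positions is
an error, not 0%.

**Clonotyping.** Records are partitioned by (IGHV gene, IGHJ gene, CDR3
length) — allele suffixes (`*01`) stripped, because clonal identity is a
gene-level property — then single-linkage clustered with an edge where
normalized CDR3 amino-acid hamming distance ≤ 0.15. The configured
cut-off of 0.85 is interpreted as *similarity* (distance semantics are
switchable): a normalized hamming *distance* threshold of 0.85 would
merge nearly all same-length junctions, whereas 85% similarity is the
standard clonal-grouping operating point. The clustered string is the
configurable junction column (default `junction_aa`), compared
full-length. Barcodes carrying multiple heavy chains keep the row with
the most isotype evidence (constant-region call present, then longest
sequence), logged. Clone ids are assigned in order of each component's
smallest member barcode, so they are invariant to input order.

**Clonal structure.** Singlet ⇔ size 1; isogenic ⇔ size ≥ 2 with one
unique sequence; heterogenic ⇔ size ≥ 2 with ≥ 2 unique sequences.
"Unique" compares full heavy-chain nucleotide strings exactly — CDR3-only
equality would misclassify trunk-mutation variants as isogenic. The
≥ 5-cell filter applies to family-level composition and ranking analyses
only, never to structure classification itself, and is used for both the
k = 20 and k = 100 extreme-family selections. Families are ranked by the
median of member SHM (robust for small families; the mean is also
emitted), ties broken by clone id. A family is predominantly CD19-low
iff strictly more than 30% of its binned members are low *and* strictly
fewer than 30% are high (symmetrically for high; otherwise neither).

**Normalization, binning, statistics.** ADT counts are `log1p`-
transformed and Z-scored within sequencing batch using the sample (n−1)
standard deviation; a zero-variance batch is an error naming the batch.
Binning is global across donors after batch normalization (per-donor
binning is available): cells are ranked ascending with ties broken by
barcode lexicographic order — so bin sizes are always exactly
⌊0.3n⌋ / n−2⌊0.3n⌋ / ⌊0.3n⌋ and order- and monotone-transform-invariant
— with a logged warning when ties straddle a boundary. Rank tests use
exact enumeration when the pooled sample is tie-free, has n ≤ 10 and at
most 50,000 group assignments (degenerate many-singleton-group
configurations exceed that combinatorially and fall back to the
approximation); otherwise the normal/chi-square approximations with tie
correction. Post-hoc all-vs-all comparisons after Kruskal-Wallis are
Dunn rank z-tests with tie correction; after Friedman, pairwise z-tests
on within-block mean ranks; both Holm-adjusted, and the output records
the procedure used (the exact post-hoc behavior of point-and-click
statistics packages is not claimed to be matched). A fully constant
pooled sample returns statistic 0, p = 1 ("degenerate" method tag)
rather than NaN. Cells lacking a CD19 measurement or VDJ record are
excluded from the respective binning, never imputed.

## The synthetic generator

`SimConfig` defaults define the simulated study conditions: 2,000 cells
from 9 donors (2/3 with allergy, 3 donors per sequencing run), a
clone-size power law P(s) ∝ s^−2.5 truncated at 50 (about half of all
cells end up as singlets), origin mix 0.5, SHM targets 4 ± 1.5%
(MBC) vs 8 ± 2% (GC) of heavy-chain length, Poisson(2) private
mutations per GC clone member, CD19 effect 1.5 Z units, IGHC emission
Poisson(100) for the true subclass vs Poisson(0.5) ambient for the other
eight, 10% VDJ dropout, 2%/1%/1%/2% planted mito/RNA-low/RNA-high/
lineage QC failures, and a 0.5 log-unit *JCHAIN* elevation in MBC-origin
cells. Per-origin isotype priors lean IgM/IgG for MBC progeny and IgA
for GC exports, matching the expected prevalence patterns; donor-level
variability of the priors is exposed as an optional Dirichlet dispersion
(default off — no value is asserted).

Construction guarantees, not just tendencies:

* Germlines concatenate one of 12 synthetic IGHV and 6 IGHJ templates
  (fixed panel generated once from a hard-coded seed, named with allele
  suffixes to exercise allele stripping) around a random junction.
* Clone CDR3s (10–18 aa) are rejection-sampled to pairwise hamming
  distance ≥ 3 among same-length junctions, which exceeds the 0.15
  distance threshold at every allowed length — clone recovery is exact
  by construction, and the acceptance suite verifies partition equality
  at n = 5,000.
* Trunk mutations are placed at distinct positions with substituted
  bases, and GC private mutations only at trunk-free positions, so each
  cell's realized mismatch count equals its planted mutation count
  exactly. Multi-cell GC clones are forced to carry ≥ 2 distinct
  mutation loads; MBC clones copy the trunk sequence identically.
* The latent CD19 shift is pre-compensated for the origin-mixture
  variance (d = e/√(1 − p(1−p)e²)) so the *post-normalization* Z
  difference between origins matches `cd19_effect`; residual Poisson
  noise on the count scale biases the recovered effect by well under the
  ±0.15 check at n = 2,000 (measured ≈ 1.49 for a planted 1.5).

Identical configs (including seed) produce byte-identical output files.

What the generator does **not** emulate: real IMGT germlines and V(D)J
recombination, indels, light chains, class-switch variation within
clones, doublets, hashtag demultiplexing, UMI collapsing, cell-state
expression structure, or biologically driven isotype miscalls (membrane
vs secreted transcripts, pre-switch co-expression). Consequently,
passing tests demonstrate that the pipeline's rules are implemented
faithfully and recover planted effects of realistic magnitude — not that
real data would show these effect sizes, and not that the GEX isotype
rules would reach any particular accuracy on real cells. Under the
Poisson ambient model in particular, the strict majority rule converts
contamination into *unassignability* rather than miscalls, so benchmark
accuracy stays near 100% while the assignable fraction collapses as
ambient counts grow; both quantities are reported.

## Problem sizes and determinism

Test and acceptance runs use n between 600 and 5,000 cells and 20
replicates for directional-effect checks — sizes at which every planted
effect is comfortably resolved and the full suite completes in about a
minute. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline itself is deterministic given
its inputs (clone ids, bin assignments and tie-breaks are all anchored
to barcode order).

## Known limitations

* Clonotyping compares junctions only at equal length (no indel-aware
  distance) and does not auto-calibrate the threshold from the
  distance-to-nearest distribution; 0.85 similarity is a configurable
  operating point.
* Exact rank-test p-values are limited to small tie-free samples; the
  asymptotic approximations are standard but not identical to any
  specific commercial implementation.
* The per-cell table keeps one heavy chain per barcode; genuinely
  multi-chain cells (doublets, biallelic expression) are resolved
  heuristically.
* Friedman blocks require every donor to have cells in every bin;
  donors with empty blocks are dropped from that test.
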