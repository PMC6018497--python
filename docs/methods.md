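# Methods

This note documents the statistical procedures implemented in `holotools`,
the choices made where the procedures were underdetermined, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Coordinate and alphabet conventions

All genomic coordinates are 0-based half-open internally; VCF and GFF3
(1-based) shift by exactly one at import, BED passes through unchanged.
Protein alignments are strings over the 20 amino acids plus `X` (unknown)
and `-` (gap); `X` carries no residue identity and is treated as missing
everywhere: it counts toward a column's gap fraction and is excluded from
frequency numerators and denominators alike. Duplicate SNP records
collapse silently because the scan counts polymorphic *sites* (positions),
not calls. Overlapping CDS intervals merge with a warning (isoform overlap
is ubiquitous in real annotations); zero-length genes are skipped, not
fatal.

## Convergence track

**Gap filter.** Columns whose gap fraction (`#'-' + #'X'`)/rows *strictly
exceeds* 2/3 are removed. The comparison is exact rational arithmetic on
counts (floats snap to the nearest simple rational), so a 3-row column
with exactly 2 gaps sits on the boundary and is retained. The filter is
idempotent, and a column map preserves the original coordinates of every
surviving column.

**Profiles.** Per group (plant BAS, plant CAS, animal LAS — or per animal
clade), per column: residue frequency = count / n_effective, where
n_effective counts non-gap, non-`X` residues in the group. Using the
non-missing count rather than group size keeps frequencies comparable
across unevenly gapped columns; per column they sum to 1 (or are all 0
where the group is entirely missing).

**Plant-like sites.** For a focal animal LAS sequence, each filtered
column where the focal residue is a real amino acid is evaluated:
plant-like iff freq(animal LAS) < 0.20 **and** (freq(plant BAS) > 0.55
**or** freq(plant CAS) > 0.55). Both inequalities are strict and are
evaluated on exact count ratios, so frequencies landing exactly on a
threshold are never called. Columns where the focal sequence has `-` or
`X` are skipped rather than reported as negative. Design choices that were
genuinely open:

* the focal sequence is *included* in the animal denominator (the literal
  reading of a percentage "in animal LAS genes"); the calls carry all
  three frequencies so the alternative is easy to audit;
* BAS and CAS are profiled separately and combined disjunctively;
* motif grouping is a reporting convention, not part of the site
  definition: maximal runs of plant-like calls with consecutive members
  ≤ 3 filtered columns apart, discarding runs shorter than 2. Raw site
  calls are always reported alongside motifs, in both filtered and
  original column frames.

**Ancestral deduction.** Per column, each animal clade (non-bilaterian,
protostome, deuterostome) votes its strict within-clade modal residue; a
tied or empty clade abstains. A residue wins with ≥ 2 votes; otherwise the
column is `X`. Strict modes keep the rule invariant under sequence order.
Per-column supporting clades are recorded.

**Divergence.** p-distance under pairwise deletion (columns with `-` or
`X` in either sequence excluded; ancestral `X` columns are thereby
excluded automatically, and the undetermined fraction is reported
alongside each estimate), Poisson correction d = −ln(1 − p), and a
bootstrap SE from resampling the comparable columns with replacement
(default 1000 replicates, seeded). Replicates that saturate (p = 1) are
dropped with a warning rather than mapped to infinity, keeping the SE
finite; p = 0 pairs short-circuit to SE 0. The per-species table is
sorted by d descending; per-sequence bootstrap seeds are derived from one
master seed via `SeedSequence.spawn`, so the table is reproducible and
independent of row order.

## Polymorphism track

**Windows.** Per chromosome, windows start at 0, s, 2s, … (defaults
W = 1 Mb, s = 50 kb); the terminal window is truncated at the chromosome
end and tested with its true length. Density is SNPs per kb.

**Enrichment.** One-sided Fisher's exact test with base pairs as trials —
the only construction consistent with a density per unit region — on the
2×2 table contrasting the window (or CDS) against the *rest* of the
chromosome, with the window excluded from the background so the cells are
disjoint. A window spanning its entire chromosome has no background and
returns p = 1 with a warning. Raw p-values are reported and the fixed
cutoff 1e-4 gates significance; a Benjamini–Hochberg q-value column is
emitted for reference but never gates the calls.

**Hotspot regions.** Significant windows merge when overlapping or exactly
bookended; merged spans < 500 kb are discarded. Because a 1-Mb window
becomes significant long before it fully enters a dense tract, plain
window-union regions overshoot each true boundary by a large fraction of
the window length. An optional (on by default in the pipeline drivers and
CLI) refinement therefore re-examines each merged region at step
resolution: per-step-bin SNP counts are classified against the midpoint
between the chromosomal background rate (measured outside all candidate
regions) and the region's densest bin, and the region is trimmed to the
maximal run of dense bins around that densest bin, again subject to the
500-kb minimum. With the default rates the bin classification error is
negligible and recovered boundaries are step-exact. This refinement is
also what makes sub-window (≥ 500 kb but < 1 Mb) regions possible at all.

**HPGs.** Per gene, the same one-sided test on CDS base pairs vs the rest
of the chromosome; significant iff raw p < 1e-4.

## Genome-size track

The estimator is G = N / m, where m is the modal depth of the k-mer
histogram after excluding the low-depth error component and N is the
total k-mer count Σ depth·count. The error component is defined as all
depths below the first local minimum of the counts (the first depth at
which counts stop falling); a histogram whose counts never rise has no
interior coverage peak and is an error. By default N also excludes the
error component — the standard practice, since error k-mers are not
genomic sequence — and a flag retains it; including a planted error
component of mass E changes the estimate by exactly E/m. Peaks are found
on raw counts without smoothing: histograms at realistic scale are smooth,
and smoothing would blur the exactness guarantees used in validation.

## Synthetic-data generators

**Substitution model.** A 20-state uniform-replacement process: on a
branch of expected length d, each column substitutes with probability
1 − exp(−d) to a residue drawn uniformly from the other 19. Every
substitution event is observable against the parent, so the expected
p-distance after one branch is exactly 1 − exp(−d) and the Poisson
correction −ln(1 − p) is an unbiased inverse — the property that makes
parameter-recovery validation of the divergence estimator exact in
expectation. This is deliberate: the generator matches the estimator's
model class, so recovery failures indicate implementation defects, not
model mismatch.

**Alignment scenario** (defaults): 10 BAS + 10 CAS + 12 LAS (clades
4/4/4), 700 columns, every branch 0.1 substitutions/site (plant stems
included), 2 % per-cell gap rate, 30 planted columns, focal lineage
`deuterostome_1`. At each planted column all plant sequences share one
non-root residue, the focal animal carries it, and every other animal is
forced off it, so the planted contrast (animal frequency 1/12 ≈ 0.083,
plant frequency 1.0) clears the 0.20/0.55 thresholds with margin;
boundary behaviour is exercised separately with hand-built profiles.
Planted columns are kept gap-free so the planted truth is exact. A
`focal_rate_multiplier` (used at 3× in the divergence analysis) emulates
the accelerated sea-cucumber LAS lineage. Truth records the root
sequence, planted columns/residues and realized per-sequence p-distances.

**SNP scenario** (defaults): one 20-Mb chromosome, background 0.001
SNPs/bp, five planted 1-Mb hotspots at 5×, genes tiled every 20 kb (two
1.5-kb CDS exons) *outside* the hotspots, three planted genes at 10× CDS
rate. Genes avoid hotspots so the two planted truth tracks stay disjoint
— a gene inside a 5× hotspot would be legitimately enriched and would
blur the gene-level truth. Elevated rates are layered as an extra
Bernoulli draw on top of the background with the exact complement rate,
so the combined per-base rate equals multiplier × background exactly.

**Histogram generator**: the main component is a discretised bell of
counts symmetric about the peak depth c with counts summing to exactly
G\*, so its mass is exactly G\*·c and the estimator inverts it without
error; the optional error component (mass E at depths 1–2) is separated
from the main component by an explicit zero-count valley so the automatic
cutoff isolates it exactly. The construction is deterministic.

**What the generators do not emulate:** real amino-acid exchangeabilities,
rate heterogeneity across sites, indel evolution or alignment error;
linkage disequilibrium, demography or calling artefacts in the SNP
landscape; heterozygosity and repeat structure in k-mer histograms (no
GenomeScope-class mixture). Passing the planted-truth validations
therefore demonstrates correctness of the implemented procedures under
their own model assumptions, not robustness to every property of real
data.

## Problem sizes and numerical choices

Validation scenarios are sized for interactive runs: 32×700 alignments,
a 20-Mb chromosome (~40k SNPs, 400 windows, 750 genes), 2000-column
divergence recovery at d\* ∈ {0.05, 0.2, 0.5} with 1000 bootstrap
replicates, and exhaustive Fisher-oracle enumeration over all 2×2 tables
with total ≤ 60. Threshold comparisons (gap fraction, plant-like
frequencies) use exact rationals; consensus and modal ties resolve to `X`
rather than an input-order-dependent pick; bootstrap SEs use the
unbiased (n−1) standard deviation. All randomness flows from explicit
`numpy` `Generator` seeds; nothing touches global random state.

## Known limitations

* No statistical significance is attached to plant-like site counts — no
  null model for convergent contrast is defined, so counts are
  descriptive.
* The ancestral rule is a majority heuristic, not likelihood-based
  reconstruction; columns without two-clade agreement are left
  undetermined rather than imputed.
* Fisher enrichment treats bases as independent trials; linkage makes the
  effective number of trials smaller, so real-data p-values are
  anti-conservative in proportion to local LD.
* The region boundary refinement assumes a roughly two-level (background /
  hotspot) density; gradual density ramps will be trimmed to the level-set
  of the midpoint threshold.
* The genome-size estimator implements the plain peak formula only; it
  inherits that formula's biases on heterozygous or repeat-rich genomes.
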