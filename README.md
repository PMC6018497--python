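# holotools

Statistical toolkit for three genome-analysis procedures motivated by the
evolution of saponin biosynthesis in sea cucumbers (holothurians):

1. **Lineage-contrast convergence scan** of oxidosqualene-cyclase (OSC)
   protein alignments. Sea-cucumber lanosterol synthases (LAS) cyclize
   2,3-oxidosqualene into parkeol — a triterpene precursor of defensive
   saponins — rather than lanosterol, and carry "plant-like" sequence
   motifs resembling plant β-amyrin synthase (BAS) and cycloartenol
   synthase (CAS). The scan formalizes this contrast: after removing
   alignment columns with more than two-thirds gaps, a column is a
   **plant-like site** for a focal animal sequence when the focal residue's
   frequency is **< 20 %** among animal LAS sequences but **> 55 %** among
   plant BAS *or* plant CAS sequences (both inequalities strict). Nearby
   sites group into plant-like motifs.
2. **Ancestral LAS deduction and divergence ranking.** The ancestral
   animal residue at each column is the amino acid that is the predominant
   (strict modal) type in at least two of three animal clades
   (non-bilaterian, protostome, deuterostome); otherwise the column is
   undetermined (`X`). Each species' divergence from this ancestor is the
   Poisson-corrected distance *d* = −ln(1 − *p*) on the proportion *p* of
   differing sites under pairwise deletion, with a site-resampling
   bootstrap (1000 replicates) standard error.
3. **Polymorphism hotspot scan.** SNP density (SNP sites per unit region)
   in 1-Mb sliding windows with a 50-kb step; each window — and each
   gene's CDS — is tested against the rest of its chromosome by a
   one-sided Fisher's exact test (base pairs as trials) at a fixed cutoff
   of p < 1e-4. Significant windows merge into hotspot regions (reported
   at ≥ 500 kb, optionally trimmed to step-resolution density
   boundaries); significantly enriched CDSs are **highly polymorphic
   genes (HPGs)**.

Plus a **k-mer genome-size estimator**: genome size = (total number of
19-mers) / (depth of the coverage peak), with automatic exclusion of the
low-depth sequencing-error component.

Because the original genome-scale inputs are far too large for routine
validation, the package ships first-class synthetic-data generators
(`holotools.synthetic`) that emulate each input with planted,
machine-readable ground truth — grouped alignments with planted convergent
columns, Bernoulli SNP landscapes with planted hotspots and HPGs, and
histograms constructed to invert the genome-size formula exactly. Every
pipeline is validated end to end against these planted truths.

## Worked example

The numbered scripts under `analysis/` run each pipeline on the default
synthetic scenarios and write their tables under `results/`:

```
$ python analysis/01_convergence_scan.py
alignment: 32 sequences x 700 columns (700 after gap filter)
focal deuterostome_1: 31 plant-like sites, 4 motifs
planted-site recovery: 30/30 (false calls: 1)
```

All 30 planted convergent columns are recovered; the one extra call is a
column where drift produced a genuinely plant-like contrast.

```
$ python analysis/02_ancestral_divergence.py
ancestral: 700/700 columns determined, 700/700 match the true root
most divergent: deuterostome_1 (d = 0.332 +/- 0.024); focal lineage ranked first: True
```

With the focal lineage evolving at 3× the background rate (emulating the
fast sea-cucumber LAS genes), the deduced ancestor matches the true root
at every determined column and the focal lineage tops the divergence
table, as expected for a branch of length 0.3.

```
$ python analysis/03_polymorphism_scan.py
40082 SNPs across 400 windows; 5 hotspot regions called
  planted hotspot chr1:2000000-3000000: best Jaccard 1.000
  ...
HPGs: called ['gene_0354', 'gene_0384', 'gene_0567']; planted ['gene_0354', 'gene_0384', 'gene_0567']; exact match: True

$ python analysis/04_genome_size.py
clean: peak 30x, G = 1,000,000 (error excluded), 1,000,000 (error included); true 1,000,000
with_error: peak 30x, G = 1,000,000 (error excluded), 1,100,000 (error included); true 1,000,000
```

All five planted 1-Mb hotspots are recovered with exact boundaries,
exactly the three planted genes are significant, and the genome-size
estimate inverts the construction exactly (including the error component
shifts the estimate by exactly error-mass / peak-depth = 100,000).

The same functionality is exposed as a CLI (`holotools converge ...`,
`holotools polyscan ...`, `holotools kmersize estimate`,
`holotools simulate ...`) for use on real FASTA/VCF/GFF3/BED inputs; every
run writes a `provenance.json` sufficient to reproduce its outputs.

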