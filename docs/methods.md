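# Methods

This note documents the models and procedures implemented in `tagarray`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where more than one reasonable option existed. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

Phased haplotypes are held as an integer matrix of shape
`(2·n_samples, n_sites)` with allele indices (0 = REF); rows `2i, 2i+1`
are sample `i`'s haplotypes. No missing data exists after load: the loader
rejects missing genotypes (an `impute_missing_as_ref` escape hatch exists
for user data and logs loudly), because every downstream formula assumes
complete haplotypes. VCF and site tables are 1-based; BED and all internal
interval arithmetic are 0-based half-open, converted only at I/O
boundaries. Multiallelic sites are loaded intact — the fine-mapping
triallelic exclusion must be able to see them — while LD operations accept
only biallelic sites.

## Linkage disequilibrium

r² is the squared correlation of allele indicators on phased haplotypes
(the `vcftools --hap-r2` statistic), computed within one population at a
time. Monomorphic sites give a *distinguished undefined value*, not 0:
treating undefined LD as zero would let selection silently "cover" targets
that are uncoverable in a population. Frequencies are accumulated in
double precision and r² is clipped to [0, 1] after a 1e-12 overshoot
check; the all-pairs matrix sets the diagonal of polymorphic sites to
exactly 1 (float associativity can otherwise produce 1 − 1 ulp, which
matters when a selection threshold is exactly 1.0). |D′| is reported
alongside; it equals 1 whenever a haplotype configuration is absent.
Cross-chromosome LD is never computed.

## Association ranking and regions

Associations are deduplicated by variant (keeping the smallest discovery
cohort, then smallest p-value) and ranked ascending by discovery sample
size — a small cohort at genome-wide significance implies a large effect —
with p-value and then variant id as tie-breaks so the ranking is a total
order. The top 500 (configurable) define priority loci of ±100 kb around
the index position, clipped at the chromosome start. Gene windows are the
spanning min–max interval over a gene's transcripts ±50 kb: priority genes
are contiguous loci and arrays target whole-gene regions, so a
multi-interval union would only punch unhelpful holes. Loci and gene
windows are merged (touching intervals coalesce) before selection. The LD
reference population for a locus follows its discovery ancestry: any
European-descent component → EUR; East/South-Asian-only → ASN; as
documented extensions (flagged in the output so users can override),
African-descent → AFR and Hispanic/Latino → AMR.

## Tag selection

Greedy maximum coverage over (population, target) pairs. Targets are
biallelic region sites with population MAF ≥ `tag_min_maf` (default 1%);
a pair is covered when the best r² from any on-array site within
`ld_window_bp` (default 250 kb, a cost cap — priority regions are
≤ 200 kb) reaches `tag_min_r2` (default 0.2); a site covers itself with
r² = 1. Candidates must pass the design-score filter when a score is
present. Each round picks the candidate covering the most uncovered
pairs, summed over populations (optional per-population weights change the
aggregation); ties break by larger mean MAF across populations, then
smaller position, then vid — deterministic output order. Selection stops
when no candidate adds coverage, so a selected site always contributes new
coverage and the count never exceeds the target count. The enhanced-region
goal of best r² ≥ 0.8 is *reported* (fraction of targets reaching it), not
enforced as a stopping rule. Greedy maximum coverage is within (1 − 1/e)
of optimal in general and the tests verify exact optimality on
block-structured panels against exhaustive minimum set cover.

## Fine-mapping proxy selection

For an index variant: candidate sites within ±100 kb ("200 kb total",
matching the locus definition; ±200 kb is available as a config switch),
excluding triallelic-or-more sites, then sites with MAF < 1% *in the LD
population* (where r² is computed — the natural frame, since a frequency
filter in a population where LD was not measured would be incoherent),
keeping those with r² ≥ 0.6 to the index; the index is always a member at
r² = 1. Both exclusion classes are counted per locus. A triallelic or
population-monomorphic index is a hard error rather than a silent skip.
Batch manifests report member counts with sample SD by default
(`ddof = 1`; population SD is config) and the pooled member MAF.

## Consequence consolidation and manifest assembly

Annotators disagree; each variant receives its most severe reported term
under an explicit, user-overridable severity table (default order:
stop_gained, frameshift, stop_lost, splice donor/acceptor, inframe indel,
missense, splice region, 5′UTR, 3′UTR, synonymous, intronic, intergenic).
The placement of UTR terms below missense is a choice, not a fact, and all
behavior re-derives from the table. Inside priority gene regions the
exome-enrichment rule admits every exonic-class term — synonymous and UTR
included, since synonymous variants can act through miRNA targets and
splice enhancers — with *no MAF floor*, so singletons and doubletons pass;
outside those regions the rule abstains. The probe design-score filter is
strict (`score > 0.5`; exactly 0.5 fails), and unscored sites fail unless
explicitly kept. Category overlap is resolved by a precedence list
(configurable; default follows the manifest row order), so each variant
lands in exactly one final category and after-counts sum to the number of
distinct variants.

## Imputation engine and leave-one-out evaluation

The evaluator is a haploid Li–Stephens-style HMM, self-contained so the
evaluation is reproducible and testable (it sits behind a small interface
so an external imputation tool can be substituted). States are reference
haplotypes; between adjacent scaffold sites the state switches to a
uniformly drawn haplotype with probability `1 − exp(−ρ·d)` (`d` in bp);
emissions match the observed allele with probability `1 − ε`. Defaults:
ε = 0.01 (absorbs mutation and genotyping error), ρ = 1e-6 per bp (a
conservative prior for real data of unknown recombination intensity; the
bundled validation experiment instead sets ρ = 1e-5 to match the known
switch intensity of the synthetic panels it evaluates — a matched-model
choice, exactly as one would set ρ from a genetic map on real data).
Posteriors come from a scaled forward–backward pass at scaffold sites and
are interpolated linearly in physical distance at evaluation sites
(genetic-map input is accepted where available); haplotype dosage is the
posterior-weighted reference allele and sample dosage the sum over the two
haplotypes, clipped to [0, 2]. An optional `ref_cap` bounds the reference
to an evenly spaced deterministic subset for speed. The evaluator itself
contains no randomness.

Leave-one-out accuracy: each sample's haplotypes are removed from the
reference in turn and its evaluation sites imputed from scaffold
observations only. Per population and site, accuracy is squared Pearson
correlation × 100 between imputed dosages and true 0/1/2 genotypes across
the population's samples (plain r is available; r² × 100 is the default
because scaffold *differences* are then percentage-point deltas).
MAF bins are population-specific and right-closed — [0.5%, 1%], (1%, 5%],
> 5% — so at 100 samples per population the lowest bin holds the
population's singletons and doubletons. Sites below the lowest edge or
with zero dosage/genotype variance are excluded and counted; populations
with fewer than 3 samples report NA. Scaffold comparisons require the
reduced scaffold to be a subset of the full one and evaluation sites to be
disjoint from both, and difference the two accuracy tables cell-wise.

## Synthetic panel generator

The generator emulates a phased multi-population reference panel:

- **Frequencies** — ancestral `p ~ Beta(0.5, 0.5)` (U-shaped spectrum),
  population frequencies Balding–Nichols
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` with per-population differentiation
  `F` (defaults 0.05 for the African-descent panels up to 0.15 for ASN,
  matching the ordering of continental FST estimates).
- **Haplotypes** — per population, `n_founders` founder haplotypes;
  each sample haplotype is a founder mosaic with switch probability
  `1 − exp(−switch_rate·d)` between adjacent sites (default 1e-5/bp,
  ~100 kb segments), plus a small per-site flip rate (1e-4) for private
  noise.
- **Founder structure** — founder alleles are thresholded from a latent
  Gaussian field, AR(1) along the chromosome with correlation
  `exp(−d / founder_ld_scale)` (default 30 kb), *shared across
  populations*: founder `h` is one ancestral haplotype viewed through each
  population's drifted frequencies. Marginally each founder allele is
  still Bernoulli(population frequency).

The founder-field structure is the load-bearing choice. With independent
founder alleles, pairwise sample r² is bounded near `1/n_founders`
(the founder pool itself has no LD, and sample LD only reflects shared
founder segments), and rare variants are either absent (a single carrier
founder among 20 implies ~5% frequency) or pure flip noise in linkage
equilibrium — a panel in which low-frequency variation is *unimputable by
construction*, which no array content can change. Real rare variants ride
shared haplotype backgrounds across populations; the latent-field
generator reproduces exactly that: with 120 founders a single-carrier
variant sits near 0.8% frequency on the same founder background in every
population that carries it. Defaults (500 sites, 200 kb, six populations
of 100 samples) are the standard test condition throughout.

What the generator does **not** emulate: admixture LD, selection,
realistic demography, genotyping error, strand issues. Passing tests
demonstrate internal correctness and qualitative behavior of the design
procedures on LD-structured multi-population data, not calibrated accuracy
on any real cohort.

## The scaffold-comparison experiment

`tagarray.validation` freezes the end-to-end evaluation: on each synthetic
panel, a base scaffold emulating a GWAS backbone is designed by running
the tag selector over common targets (MAF ≥ 5%) at the r² = 0.6 level and
truncating the selection order at the first prefix whose *mean* best-r²
over all (population, target) pairs reaches 0.6 — a backbone aims for mean
coverage quality of common variation, not a per-target minimum. Custom
content is then selected on top of that fixed backbone with the standard
augmentation parameters (MAF ≥ 1%, r² ≥ 0.2), and both scaffolds are
evaluated by leave-one-out imputation on all remaining sites with the
matched-model ρ. Two simpler base scaffolds were tried and discarded: a
uniform thinning of panel sites leaves common variants far below their
accuracy ceiling, so the > 5% bin gains as much as the rare bins and the
frequency profile of a backbone-vs-custom comparison is not reproduced,
while a minimum-r²-0.6 backbone saturates a 500-site panel and leaves
almost nothing to augment. The frequency profile of the comparison
depends on the backbone already being good, on average, for common
variation — which is what a backbone is. Problem sizes (five seeds × 600
samples × 500 sites, two scaffolds each) keep the full experiment around
two to three minutes.

## Numerical and degenerate-input choices

- Forward–backward scales per site; posterior rows renormalized, checked
  to 1e-9 in tests.
- r² overshoot beyond 1 + 1e-12 is an error, not a clip.
- Evaluation sites that are themselves on the scaffold come back at their
  observed dosage and are flagged, not errors.
- A chromosome holding evaluation sites but no scaffold sites is an error.
- Empty association input yields an empty ranking with a warning; a
  region containing no polymorphic site yields an empty selection with a
  warning; a fine-mapping index absent from the panel is skipped and
  listed.
- Ties everywhere break deterministically (documented orderings), so the
  whole pipeline is byte-reproducible from (config, seed).

## Known limitations

- Coverage is pairwise-r²-based; imputation-aware tag scoring is out of
  scope.
- The imputation engine is haploid-path Li–Stephens with physical-distance
  interpolation; it is a measurement instrument for scaffold comparisons,
  not a production imputation tool.
- Population assignment is user input; no ancestry inference is performed.
- Genome build handling is the caller's responsibility (no liftover).
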