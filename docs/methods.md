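# Methods

## Study design being modelled

The package targets the standard genetic work-up of a small family in
which a rare trait segregates as if autosomal dominant with full
penetrance: exome sequencing of the available members, a co-segregation
filter over the joint VCF, functional annotation of the survivors,
SNP-array CNV screening, and a gene-set burden comparison. The built-in
family structure has three generations: grandparents, the affected
father and his ungenotyped sibling, the sibling's spouse, the mother,
and four grandchildren — the affected proband, her unaffected sister and
two unaffected paternal cousins. Six members are sequenced (father,
mother, proband, sister, both cousins); the connectors (grandparents,
the father's sibling and their spouse) exist in the pedigree but carry
no genotype data, exactly as in real studies where only some relatives
consent or survive. Whether the cousins descend from the father's
brother or sister is not determined by the data, so
`family_pedigree(connector_sex=...)` parametrises it; autosomal
transmission probabilities are invariant to the choice, which the
default (`"male"`) therefore sets arbitrarily.

## Filter cascade

Gates, in reporting order: site quality (caller FILTER = PASS),
coverage, segregation, exonic, novelty, consequence. Decisions worth
stating:

* **Coverage** means genotype-called, not depth-thresholded: the
  upstream caller's ability to emit a genotype is the observable the
  pipeline has. The default minimum is *n* − 1 of *n* samples (5 of 6
  for the built-in family).
* **Segregation** requires heterozygosity in every affected genotyped
  member — a dominant rare trait is expected het, and requiring hom-alt
  would contradict the model — and no alt allele in any *called*
  unaffected member. A missing genotype in an unaffected member does
  not disqualify (the coverage gate already caps missingness at one
  sample by default); a missing genotype in an affected member fails
  the pattern, conservatively. Ungenotyped pedigree members are
  ignored; genotype presence is resolved by sample-id matching.
* **Novelty** matches panels at allele level (chrom, pos, ref, alt) by
  default; site-level matching is available but discards novel alleles
  at known positions.
* **Consequence** keeps nonsynonymous SNVs, stop gain/loss and
  frameshift indels; synonymous and in-frame indels are "variants of
  unknown significance" and drop.
* Multi-allelic records are split per ALT on read, genotypes recoded
  against each ALT.
* The gates commute on membership; only the per-stage counts depend on
  the order. A property test verifies this over random gate orders.

## Score classification

SIFT ≤ 0.05 deleterious, PolyPhen2-HDIV ≥ 0.95 damaging, PhyloP > 0
conserved (0 is not conserved). Only the two protein-level predictors
feed `any_deleterious`: base-level conservation is reported but does not
by itself call a variant deleterious — all three validated candidate
substitutions sit at conserved bases, yet only two are protein-level
deleterious, and conflating the two notions would erase that
distinction. Null scores (e.g. SIFT/PolyPhen on indels) give null
verdicts and never count. The lysine screen flags substitutions whose
reference or alternate residue is K; it is a surrogate for full
ubiquitination-site prediction, which is out of scope.

## CNV consensus

Coordinates are 1-based inclusive throughout (length = end − start + 1);
every output header says so. Sample QC uses the two callers' native
rules (caller A: LRR SD < 0.35 ∧ BAF drift < 0.002 ∧ |waviness| < 0.04;
caller B: LRR SD < 0.3 ∨ BAF SD < 0.15); a sample must pass both to
contribute. Call-level filtering excludes calls with < 3 SNPs or
confidence/log Bayes Factor < 10. Split adjacent same-state calls from
one caller are unioned when their gap is ≤ `max_gap` (default 1000 bp,
roughly one inter-probe spacing on a ~700k-marker array; no canonical
value exists, so it is exposed as configuration). The ≥ 50% overlap
between callers is interpreted **reciprocally** by default — both
fractions must reach the threshold — because one-way overlap lets a tiny
call validate an arbitrarily large one; one-way is available by flag.
Consensus coordinates are the intersection (innermost boundaries), so
every consensus interval is contained in all of its source calls — an
invariant the class itself enforces.

Rarity against the DGV-like catalogue uses one-way overlap (fraction of
the family CNV covered): catalogue records vary over orders of
magnitude in size, and reciprocal overlap would misclassify a common
CNV nested in a large catalogue record as rare. A CNV is common iff a
record covers ≥ 50% of it or the supporting-variant counts of all
overlapping records sum to ≥ 20 (boundary 20 counts as common; a
per-record rather than summed criterion is available by flag, since the
catalogue convention is ambiguous).

## Burden test

Qualifying variants per individual are the rare exonic protein-altering
records that individual carries (site-quality + exonic + novelty +
consequence gates; the segregation gate is deliberately not applied —
the test compares individuals, not the co-segregating subset). Counts in
each interactor tier are compared between the affected (n = 2) and
unaffected (n = 4) groups with Welch's unequal-variance two-sided
t-test; the pooled Student form is available by flag because with such
small groups the choice is material. Identical constant groups return
t = 0, p = 1; constant groups with unequal means have no finite t and
raise (the pipeline reports the tier as having no finite statistic
rather than fabricating p). Group members are relatives, so t-test
independence holds only approximately; the test is a screen. A
calibration property test (2000 replicates of Poisson(20) burdens,
2 vs 4) checks the empirical type-I error at α = 0.05 stays within
±0.02 — Poisson(20) reflects a realistic per-individual qualifying
burden in a several-thousand-gene interactor set.

## Synthetic data generator

The generator is a statistical stand-in for the study's unreleased raw
data, producing every input the pipeline consumes.

* **Genotypes** arise by gene dropping: founders drawn Binomial(2, f)
  per site (Hardy–Weinberg), non-founders inherit one allele from each
  parent uniformly. Sites are independent — the cascade operates per
  site, so linkage is irrelevant to its correctness, and this is the
  main deliberate departure from real exomes (no LD, no shared
  haplotype blocks). Allele frequencies default to Beta(0.3, 3), rare-
  skewed.
* **Site quality**: each record fails the generic PASS flag with
  probability 0.63, matching the observed fraction of raw calls removed
  by caller quality filters in a six-exome joint call at full scale
  (784,444 → 287,977 ≈ 37% passing). The true criteria of such filters
  are caller-internal and are not modelled.
* **Exonic fraction** defaults to 0.15 (≈ 505/3266, the exonic share
  observed among co-segregating variants in an exome+flank capture);
  consequence weights default to a realistic exonic mix (50%
  nonsynonymous, 40% synonymous, small stop/indel classes).
* **Panels**: a site enters the combined known-site list with
  probability 1 − (1 − f)^(2·4769) — the chance at least one chromosome
  of a 4769-individual reference panel carries the allele — then
  scatters across the two panel files. Rare sites are thus
  realistically panel-absent.
* **Planted trait variant**: heterozygous in exactly the configured
  carriers, fully called, exonic nonsynonymous, panel-absent — by
  construction it satisfies the cascade's preconditions, so recovery
  failures indicate pipeline defects, not simulation noise.
* **False-positive indels** emulate caller artifacts that survive
  filtering and later fail wet-lab validation: a configurable fraction
  of records become indels mimicking the co-segregation pattern,
  flagged in the truth sidecar so tests can count them.
* **CNV call sets**: true segments (~20–120 kb, log-normal) per sample;
  both callers see every segment with Gaussian boundary jitter
  truncated below a quarter of segment length (so consensus remains
  attainable, mirroring callers that disagree on boundaries but not
  grossly); with configurable probability a caller splits a segment
  into two adjacent calls; caller-private low-quality noise calls
  exercise the call filter. Array intensity tracks (LRR/BAF) are not
  simulated — only caller-output-level calls and summary QC metrics.
* **Interactor tiers** default to 5961 high- and 2178 low-confidence
  genes, the size of a ubiquitin-C interactor list split by confidence.
* **Determinism**: one seed fixes every output byte-for-byte; a test
  asserts file-level identity across reruns.

Because the generator omits LD, sequencing error beyond uniform
missingness, and realistic depth variation, passing tests demonstrate
the *logic* of the pipeline — gate correctness, consensus algebra,
count bookkeeping — not its behaviour under real-exome artifact
structure.

## Validation strategy and problem sizes

Every stage is checked against an independent oracle implemented only
in the test suite: a per-variant brute-force rule checker for the
cascade (50 seeds × 150-variant studies), per-base set intersection for
interval overlap (1000 random pairs), closed-form Welch formulas (100
random samples, agreement to 1e-12), and exact transmission-pattern
enumeration (3^10 genotype vectors) for the gene-dropping sharing
fraction (50,000 sites, agreement within 3 Monte-Carlo SEs). Planted-
variant recovery is asserted to be 100% over 100 clean simulations with
zero alt-allele leakage into called unaffected genotypes. These sizes
keep the full suite around ten seconds while leaving Monte-Carlo
standard errors far below the asserted tolerances.

The father+proband-exclusive sharing fraction depends on the allele-
frequency spectrum of the sites considered: the exact enumeration gives
≈ 16% in the rare-variant limit, falling with frequency; under the
default rare-skewed spectrum the simulated value is ≈ 5–6%, the same
order as the ≈ 10% back-of-envelope expectation for this family
structure. The package documents this as an order-of-magnitude check,
not an equality.

## Known limitations

* Only the dominant inheritance model is implemented (the config enum
  is extensible; recessive/X-linked/compound-het are not provided).
* Headline full-scale variant counts from any particular real study are
  not reproducible here: they require the original exomes, which were
  never deposited. The synthetic defaults emulate their *ratios* where
  those are informative (site-pass fraction, exonic fraction, tier
  sizes).
* The burden test's relatedness caveat above; no permutation or
  kinship-adjusted alternative is provided.
* VCF writing emits a minimal GT:DP v4.2 file; richer FORMAT fields are
  out of scope.
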