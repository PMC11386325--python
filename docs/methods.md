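# Methods

This note documents the models implemented in `gdassess`, the defaults
chosen where the underlying methodology leaves room, and what the test
suite's synthetic validations do and do not establish about real data.

## Coordinates and inputs

All internal coordinates are 0-based half-open (BED convention); VCF's
1-based positions are converted on read. Only biallelic SNPs are kept;
multi-allelic and non-SNP records are counted and skipped. Genotypes are
collapsed onto a 4-state alphabet (hom-ref / het / hom-alt / missing);
phase and half-calls are ignored. Sample counts outside 2–25 raise a
warning, not an error: the estimators remain defined, but single-genome
"population" summaries should be interpreted as individual values.

Scaffolds shorter than 100 kb (including typical mitochondrial
sequences) are removed before windowing; the boundary is inclusive
(exactly 100 kb is retained). The callable mask is the intersection of
the non-repeat complement, the mappability-1 intervals, and the
length-filtered scaffolds. Analysis windows are non-overlapping 50 kb
tiles; the trailing partial window is kept, flagged, and included in
population means by default (configurable), since its per-site
statistics are already normalized by its own effective length.

## Effective number of sites

Per-site θ̂_W and π divide by an "effective number of sites" per window.
Two definitions are supported: the callable-mask length inside the
window (default) and the count of sites with genotype data
(`sites_with_data=True`). The default matches the usual mask-based
normalization of windowed pipelines; the alternative is appropriate when
the input VCF already encodes per-site callability.

## Estimators

Estimation operates on called genotypes, not genotype likelihoods. This
is a deliberate design choice: the estimators' definitions are
likelihood-agnostic, genotype input keeps the toolkit deterministic and
desk-scale, and likelihood-based SFS machinery is a separate concern
best left to specialized callers. At the depths where genotype calls are
unreliable the absolute values of H and θ̂_W will be biased relative to
likelihood-based estimates; comparisons across populations processed the
same way remain meaningful.

- Sites with call rate below 0.8 (fraction of chromosomes with a called
  genotype) are dropped from S, the folded SFS, π and D.
- θ̂_W uses S / a₁(n) with the window-modal called chromosome count n,
  keeping the S/a₁ form exact in the presence of missingness; π uses the
  per-site called count in 2x(n−x)/(n(n−1)).
- Tajima's D uses the standard a₁…e₂ constants from the modal n. D is
  undefined at S = 0; undefined windows are excluded from window means.
- n = 2 × individuals assumes diploid autosomes; sex chromosomes are out
  of scope.
- Heterozygosity H is per individual: het-site count divided by callable
  sites; population H is the arithmetic mean across individuals.

A note on the neutral expectation of D: although E[π − S/a₁] = 0 exactly
under neutrality, E[D] itself is slightly negative in finite samples
because the normalizing denominator co-varies with S. Monte-Carlo runs
with both the built-in simulator and an independent coalescent simulator
put the expectation near −0.07 for n = 10 and θ = 5. Validation of
neutrality should therefore test the numerator (as the unit suite does),
not insist on mean D = 0 at high replicate counts.

## ROH model

The ROH caller is an explicit two-state genotype-based HMM rather than a
re-implementation of any particular production caller's
genotype-likelihood/allele-frequency model; the segment semantics are
the same and the model is fully deterministic and self-contained.

- State AZ (autozygous) emits heterozygotes at `p_het_in_roh` = 0.005 —
  a small residual accounting for genotyping error and mutation within
  identical-by-descent tracts.
- State HW emits heterozygotes at the site's expected rate 2p̂(1−p̂) from
  the sample allele frequency (default), or a fixed 0.25 when
  frequencies are disabled. Missing genotypes emit probability 1 in both
  states (uninformative).
- Transitions scale with physical distance: P(switch over a gap of g bp)
  = 1 − (1 − r)^g with r = `transition_per_bp` = 5 × 10⁻⁷, i.e. an
  expected tract scale of ~2 Mb. Computation is in log space
  (`g·log1p(−r)` and `log(−expm1(·))`) so megabase gaps do not underflow.
- Decoding is exact Viterbi; called segments span the first through last
  AZ site ([first, last + 1)). With fewer than two sites the path is
  all-HW.

F_ROH>100kb and F_ROH>1Mb divide the summed lengths of segments at least
100 kb / 1 Mb long by the assessed length: by default the callable
length of the ≥100 kb scaffolds, optionally the genome span. When no
scaffold reaches 1 Mb, F_ROH>1Mb is reported as undefined (None) rather
than 0 — an assembly too fragmented to contain a megabase segment cannot
support the inference.

## Heterozygosity projection and categorization

H_T = H_O (1 − 1/(2N_e))^T is evaluated in log space
(`exp(T·log1p(−1/(2Ne)))`), which matches naive evaluation to 12
significant digits across N_e ∈ [10, 10⁹], T ∈ [0.1, 1000] while being
safe for extreme inputs. T = horizon / generation time is real-valued;
the horizon defaults to 100 years to align with Green Status assessment
practice.

N_e can be supplied directly, derived from census size as N_e = N_c ×
ratio (the 10% and 100% extremes bracket strict and lenient
assessments), or from θ_W/(4μ) under mutation–drift equilibrium.

The decision tree fires rules in a fixed order and records exactly one
provenance string per assignment:

1. ratio rule: H_T:H_O ≤ 0.90 → CR, ≤ 0.95 → EN, ≤ 0.975 → VU;
2. N_e floors may only worsen the result: N_e < 100 → CR, < 500 → EN,
   < 1000 → VU;
3. when N_e cannot be derived, or the size-based rules leave the taxon
   at LC and a reference table is available, relative H_O applies: H_O
   below the maximum H_O of genetically Threatened members of the same
   Order (Family as fallback) → Threatened (conventionally reported as
   VU in summaries);
4. otherwise LC.

Choices 1–2 deserve comment. The published logic pins 0.95 → "CR or EN"
and 0.975 plus the N_e < 1000 floor → VU; the CR/EN split at 0.90 and
the EN/CR floors at 500/100 are this package's defaults, chosen to
mirror the ladder structure (500 echoes the widely used minimum-viable
N_e reference) and exposed in `CategoryThresholds`. The relative-H_O
route uses the *maximum* H_O of threatened relatives, not a mean, so the
threshold can only rise as new assessments accumulate — a stability
property, at the cost of sensitivity to a single outlier relative. The
long-generation-time trigger (default t > 15 y) is recorded in
provenance; the binary collapse counts VU, EN, CR and the relative-H_O
determination as Threatened, LC and NT as Non-Threatened.

## Green Score

G = Σ W_S / (W_F·N) × 100; the GD correction multiplies each unit's
weight by min(GD_S/GD_LC, 1). The cap means the correction can never
raise a score, with equality exactly when every unit is at least as
diverse as the reference. GD_LC is a user-supplied scalar (helper:
arithmetic mean over a reference list).

Two weight presets ship because the published material is internally
inconsistent: the stated definition is absent 0 / present 3 / viable 6 /
functional 9 with W_F = 9 (`main-text`), but the worked towhee examples
only reproduce under viable 9 / functional 12 with W_F = 12 (`box1`).
Both are preserved; `box1` pins only the viable and functional weights,
so its `present` weight keeps the main-text value 3. Scores print to 3
decimals, matching the precision of the worked examples.

## Coalescent simulator

The fixture generator implements the standard Kingman coalescent with
infinite-sites mutation: while k lineages remain, an exponential waiting
time with rate k(k−1)/2 (coalescent units), mutations Poisson with rate
θ/2 per unit branch length, uniform positions de-duplicated by
resampling. Windows are simulated independently with no recombination
within a window — matching the windowed estimators' replicate structure
and keeping the closed forms E[S] = θ·a₁(n) and E[π] = θ exact.
Haplotypes 2i and 2i+1 form individual i. Autozygous tracts are injected
by replacing a sample's heterozygous genotypes with hom-ref inside the
tract (any homozygote is equivalent for the genotype-based HMM).

What the simulator does **not** emulate: recombination and linkage
structure, demographic history (bottlenecks/growth — so Tajima's D on
fixtures only exercises the neutral case), sequencing error, depth
heterogeneity, missingness patterns, or reference bias. Passing the
recovery tests therefore demonstrates estimator correctness under the
model assumptions, not robustness to the bioinformatic noise of real
resequencing data.

Default fixture conditions: 10 diploids (the 2–25 range midpoint scale),
θ = 5 per 50 kb window (per-site 10⁻⁴, typical mammalian diversity;
recovery tests also run at per-site 0.002, the scale of the most diverse
taxa), seeds fixed per test. Validation sizes — 2000 replicate windows
for closed-form recovery, 200 random instances for Viterbi-vs-
enumeration, 10 Mb genomes with a 2 Mb injected tract for end-to-end
F_ROH recovery — were chosen to give Monte-Carlo standard errors well
below the tested tolerances.

## Numerical conventions

- Undefined statistics are represented as `None` (θ̂_W and π at zero
  effective sites, D at S = 0, F_ROH at zero assessed length,
  F_ROH>1Mb without megabase contiguity) and excluded from means, never
  silently zeroed.
- Interval sets are normalized on construction (sorted, merged,
  non-abutting); set algebra is a linear sweep over sorted arrays and is
  validated against per-base boolean arrays and bedtools in the tests.
- Window-modal n breaks ties toward the smaller chromosome count.
- Viterbi ties (measure-zero with continuous emissions) resolve toward
  the AZ state via argmax order; the enumeration oracle uses the same
  order.

## Known limitations

- Genotype-based estimation is biased at low depth relative to
  likelihood-based methods (see above).
- The categorization thresholds beyond those explicitly published are
  package defaults, not community standards; treat categorical output as
  decision support, not an official assessment.
- The relative-H_O route depends entirely on the supplied reference
  table's coverage of the taxon's Order/Family.
- No LD-based N_e estimation is included; supply N_e from an external
  estimator if census data are unavailable and μ is unknown.
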