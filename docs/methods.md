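# Methods

## The question and the measure

Populations differing in genome composition differ strikingly in how
variable gene expression is between individuals. The unit of analysis is
the per-gene coefficient of variation, CV = sd/mean of a gene's
normalized expression across the individuals of one population (sample
SD, n − 1 denominator). A population is summarised by the distribution
of CVs over all expressed genes — its kernel-density curve and the
curve's peak position. The driving hypothesis is *genotype
heterogeneity*: in a backcross, different individuals carry different
ancestry genotypes at each locus, and a genotype-dependent expression
shift converts that genetic mixture into inter-individual expression
variance. Inbred and F1 populations are genotype-homogeneous (all-HOM
and all-HET respectively) and so lack this variance source.

## Generative model (simulator)

The simulator produces the data the analysis assumes, with known truth.

**Ancestry.** Each of the G genes doubles as an ancestry marker, placed
at strictly increasing, evenly spaced map positions ((j + ½)·L/m Morgans
for the j-th of m markers on a chromosome of genetic length L; default
24 chromosomes × 83 markers, L = 1 Morgan). Crossovers follow the
Haldane map function r = (1 − e^(−2d))/2 between adjacent markers, no
interference. A BC_n individual carries one intact recurrent-parent
haplotype plus a gamete formed by n successive meioses from the F1;
composing the per-meiosis crossover chains, a locus is HET iff every
meiosis transmitted the donor-side haplotype, giving per-locus HET
frequency 0.5^n. **Convention:** the per-locus HOM fraction in BC_n is
1 − 0.5^n (0.96875 in BC5), while the recurrent-*allele* genome
fraction — which also counts the intact recurrent haplotype — is
1 − 0.5^(n+1) (≈ 98.4% in BC5); both are tested.

**Expression.** Counts are negative binomial via a gamma–Poisson
mixture: mean μ_gi = baseline_g · lib_i · batch_{g,b(i)} ·
2^(Σ β_r·[genotype_i(r) = HET]) over the gene's regulators r, variance
μ + α μ². Dispersion α = 0 is treated as the noiseless limit (counts =
round(μ)). Baselines are log-uniform on [100, 2000] expected counts.
Dispersion defaults to α = 0.003: with the CPM means involved this puts
the inbred CV distribution near 0.08, the magnitude reported for inbred
fish colonies in this kind of study. Library-size factors are log-normal
(σ = 0.2); batch effects are per-(gene, batch) log-normal factors
(σ = 0.15), giving the normalization stage real structure to remove.

**Regulatory architecture.** A target gene may have a *cis* regulator —
drawn from its own chromosome within 0.1 Morgan (cis regulation is
local, so a cis-regulated gene's expression tracks its own ancestry
through linkage; the window widens to the chromosome only if empty) —
and/or a *trans* regulator drawn from another chromosome. Effects β are
log2 fold-changes of the mean when the regulator locus is HET
(homozygous-recurrent is reference).

**Allelic reads.** Only reads covering interspecific polymorphic sites
are allele-assignable: an informative depth is binomially thinned from
the count (fraction 0.5 by default — the paper-scale average
informative-site coverage per gene is unknown, so this is a free,
documented parameter), then split binomially with parent-1 probability
equal to the gene's allelic ratio (0.5 default) in HETs and 0 in HOMs.
The split is sequencing-error-free; real data would add a small
cross-assignment rate, which the genotype caller's ambiguous band is
designed to absorb.

**F1 stabilization.** The dominance/"homeostasis" hypothesis — hybrids
inheriting a dominant stabilizing allele show *less* variability — is
modelled as a per-gene flag that multiplies dispersion by 0.1 in F1
populations only.

**Seeding.** A single integer seed expands through
`numpy.random.SeedSequence.spawn` into independent substreams per stage
(ancestry, architecture, nuisance factors, counts), so outputs are
bit-reproducible and stages can be regenerated in isolation.

**What the simulator does not emulate:** sequence-level artifacts
(mapping bias, allele-specific mappability), multi-allelic variation
(allelic ratio is a single P1 fraction), covariates such as age or sex,
expression-level-dependent dispersion trends, and selection on the
backcross (the real melanoma-bearing animals were selected). Passing
tests therefore demonstrate statistical correctness of the pipeline
under the stated model, not robustness to these real-data features.

## Analysis conventions

- **Normalization scale.** CPM → log2(CPM + 1) → batch removal; CV is
  computed on the linear scale 2^x − 1 (floored at 0). Genes with mean
  CPM ≤ 1 are excluded from CV analyses.
- **Batch removal.** Per gene, batch-indicator directions are first
  orthogonalized against population indicators (when protection is on),
  the joint least-squares fit's batch component is subtracted, and the
  gene is recentred to its original grand mean. This equalizes per-batch
  means (up to the protected structure), is idempotent, and cannot erase
  population differences even when population and batch are confounded.
  Single-sample batches are allowed but logged.
- **Genotype calling.** depth < 10 → MISSING; minor-allele fraction
  ≥ 0.15 → HET; parent-1 fraction ≤ 0.05 → HOM_RECURRENT; the gap
  between the bands is ambiguous → MISSING. The source study states that
  genotypes were inferred from allele-specific expression without giving
  thresholds; these defaults are conservative and configurable. Calls
  depend only on fractions above the depth floor, so they are invariant
  to depth rescaling. Accuracy is reported over non-MISSING calls with
  the call rate alongside.
- **Density estimation.** Gaussian KDE, Silverman bandwidth, 512-point
  grid on [0, 1.1·max]; peak = grid argmax with ties resolved toward the
  smaller CV; a zero-variance sample gets a narrow analytic bump at its
  value.
- **F-test.** Two-sided by doubling the smaller tail of F = var₁/var₂ on
  (n₁−1, n₂−1) df; genes with both variances zero are untestable and
  reported as such, not classified.
- **Scan.** Markers must be genotyped in all individuals with ≥ 3 per
  genotype class (the class-size floor the study applies to its DE
  filter, extended to the scan because a 1–2 sample class makes ANOVA
  degenerate). Self-pairs are excluded — a marker's association with its
  own expression is definitionally cis. MISSING genotypes are dropped
  pairwise. BH runs within each marker across its targets, as the
  method prescribes; a global-BH option exists for sensitivity analysis.
  Markers sharing a genotype pattern (tight linkage) are computed once;
  with two classes F = t² (pooled), which the tests verify to 1e−10.
  Zero within-class variance yields an infinite F with the smallest
  representable p and the case is flagged by that sentinel.
- **Differential expression.** Welch's t-test between a gene's HET and
  HOM individuals (safer than pooled-variance under the variance
  heterogeneity this analysis itself documents), BH across tested genes.

## Evaluation conventions against simulated truth

- **Recovery** is exact-pair: the true (regulator, target) pair itself
  must be significant at q < 0.05.
- **False discoveries are counted locus-aware.** With 14 individuals,
  linked markers carry (nearly) identical genotype vectors, and a marker
  adjacent to a true regulator is genuinely associated with its target —
  linked-marker redundancy, visible as "vertical lines" in association
  maps, is a property of the cross, not an error of the scan. A
  significant (marker, target) record counts as true when the marker is
  the regulator, lies within 0.25 Morgan of one on the same chromosome,
  or has a genotype pattern within Hamming distance 1 of one (including
  the complement; association is sign-free).
- **The FDP summary is the per-marker median.** BH within a marker
  controls that marker's expected false-discovery proportion; it does
  not bound the pooled proportion across markers. When each marker has
  ~1 true target among 2,000 tested, each rejecting marker's expected
  false count (~0.05–0.1) is of the same order as its true count, so
  the pooled pair-level FDP is structurally ~0.2–0.4 even though every
  marker's FDR is controlled — the aggregate proportion is not the
  quantity this FDR orientation promises. The evaluation therefore
  reports the median (and mean) per-marker FDP as the primary control
  metric, with the pooled pair-level proportion published alongside for
  transparency.
- **Stratified-CV null control.** A genotype stratum has fewer samples
  than the pooled population, and CV estimates from fewer samples are
  slightly smaller and noisier — a pure sample-size artifact. The null
  check compares each stratum's CV distribution against genotype-blind
  random subsets of matched size (the same size-matching device used for
  the inbred-vs-F1 peak comparison), which isolates the genotype
  contribution; the directional (left-shift) statements still use the
  pooled CVs.

## Problem sizes

Validation runs use panels of ~1,000–2,000 genes and the study's
population sizes (20/6 inbred, 6 F1, 14 BC1, 13 BC5), with 20 seeds for
recovery and type-I summaries and 10 seeds for the stratification null;
these sizes give binomial standard errors comfortably inside every
asserted margin while keeping the whole validation suite to a few
minutes on one CPU.

## Known limitations

- Genotype calling assumes an error-free allelic split; systematic
  allele-mapping bias would shift the HOM band and should be handled
  upstream or by widening the ambiguous band.
- The scan tests one marker at a time; genes regulated by several loci
  in linkage are attributed marker-by-marker, and no linkage-aware
  marker pruning or multi-locus model is attempted.
- Per-marker BH (the prescribed orientation) controls FDR marker-wise;
  consumers wanting a genome-wide guarantee should use the global-BH
  option.
- The CV is undefined for genes with non-positive mean on the linear
  scale and unstable just above the expression floor; the floor
  (mean CPM > 1) is deliberately conservative.
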