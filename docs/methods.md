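# Methods

`lethalmap` implements the statistical machinery of a balancer-chromosome
screen for naturally occurring recessive lethal mutations on the
*Drosophila melanogaster* second chromosome, together with a forward
simulator of the whole screen used for testing and calibration.

## Screen model

A balanced subline carries one wild second chromosome over the CyO balancer.
Crossing balanced siblings exposes the wild chromosome as a homozygote: if it
carries at least one recessive lethal mutation, the straight-winged (+/+)
class dies and all survivors are curly-winged. A subline is scored lethal
when fewer than 3.3% of offspring are wildtype — 10% of the expected
one-third straight class — and, in strict practice, when at least 35
curly-winged and 0 straight-winged offspring were counted
(`call_line_lethality`; both thresholds are parameters, the strict rule is
the default, and a relaxed fraction-only rule is available).

### Distinct-chromosome counting

Each wild male contributes two chromosomes but typically 1–2 sublines, so the
number of distinct chromosomes tested is estimated by per-fly rules
(`count_distinct_chromosomes`): one subline counts 1; a male's
lethal/non-lethal pair counts 2; a male's two non-lethal sublines count 1.5
(either one or both chromosomes were sampled, equally likely — the expected
value is used deterministically rather than randomized); a male's two lethal
sublines count 1 or 2 according to an allelism cross, with one subline of an
allelic pair excluded; female-derived sublines are recombinants, so exactly
one subline per female is retained uniformly at random and the rest are
excluded from numerator and denominator. The female-retention and
allelic-discard draws use a dedicated seeded stream and every exclusion is
logged. Males with more than two sublines (rare) are handled by the same
logic generalized: allelic components among the lethal sublines, capped at
two chromosomes per male, with any non-lethal subline pinning down the second
homologue.

The lethal fraction carries a binomial standard error and a normal 95% CI,
clipped to [0, 1] because the normal approximation can overshoot at extreme
proportions.

### Zero-truncated Poisson null model

If lethal loss-of-function mutations are single-locus and land on
chromosomes as Poisson(λ) events, the non-lethal proportion estimates the
zero class, P0 = e^(−λ), so λ = −ln(P0), and a lethal chromosome carries on
average λ/(1 − e^(−λ)) lethal mutations (the zero-truncated mean). Crossing
X1 lethal chromosomes to a deficiency panel that scans a fraction *c* of the
chromosome should therefore map X1 · c · λ/(1 − e^(−λ)) mutations. The 95%
CI of P0 is pushed through this transform with X1 held fixed; because the
transform is decreasing in P0 the endpoints swap order and are sorted.
Reported integers use round-half-to-even, and z = 1.96 is a fixed constant
rather than a quantile call, matching the screen's own arithmetic. The
coverage fraction defaults to the per-line average fraction of the
chromosome actually crossed rather than the panel union; both are computable
from a `DeficiencyPanel` and the choice is an explicit argument, as is X1.

**The CI bounds the expectation, not a realized screen.** Because only the
sampling error of P0 is propagated, the interval is a confidence interval
for the *expected* mapped count. A single screen's realized count adds
Poisson realization noise, so its spread around the estimate is wider:
writing the point estimate as n·c·λ̂ (using X1/(1 − P0) = n),

    Var(realized − estimate) = n·c·λ + n·c²·(1 − P0)/P0 − 2·n·λ·c².

In replicate simulations the realized mapped count falls inside the
expectation CI in roughly half (or fewer) of screens, which is the expected
behaviour of an expectation CI, not a defect of the estimator.
`mapped_prediction_interval` adds the realization variance above and is
calibrated: ~93–95% of simulated screens fall inside it. Observing a count
*far below* either interval remains the model's diagnostic for unmappable
(multigenic or gain-of-function) lethality.

`msb_equilibrium` provides the mutation-selection-balance yardstick for a
recessive deleterious allele, q = √(μ/s); for a recessive lethal (s = 1) and
a point-mutation rate of 10⁻⁹ this is of order 10⁻⁵ per locus.

### Complementation mapping and allelic sets

A deficiency (or single-gene knock-out, scored identically) cross maps a
lethal when 0 straight-winged and ≥35 curly-winged offspring are scored; a
single straight survivor complements; anything else is inconclusive. When a
line fails to complement two *overlapping* deficiencies, the overlap-connected
cluster counts as one distinct region (`distinct_regions_per_line`), a
deliberately conservative de-duplication; merging is restricted to the
deficiencies the line itself mapped to, so an unmapped deficiency bridging
two mapped ones does not join them. Overlap means ≥1 shared base; abutting
intervals do not overlap. Coordinates are 1-based inclusive in memory and
converted to 0-based half-open only at the BED boundary.

Allelism crosses between lethal lines form a graph whose allelic edges
(0 straight, ≥35 curly) define allelic sets as connected components.
Complementation can be transcript-specific, so intransitive triads (A–B and
B–C allelic, A–C tested and complementing) are surfaced as warnings and never
silently merged away. Set sample frequencies divide the set size (after
female-duplicate exclusions) by the distinct-chromosome sample size
(default 555), reported to one decimal percent.

### Landscape analysis

Per-deficiency mapping frequency is mapped mutations / (deficiency size ×
crosses completed). Annotation tracks (recombination rate in cM/Mb, coding
intervals, GC content) are averaged over deficiencies by overlap-length
weighting; where a track has gaps (real recombination maps do near telomeres
and centromeres) the mean is over covered bases, with the covered fraction
available. Coding annotations are merged before counting so duplicated exon
entries cannot double-count. Correlation is Pearson with a two-sided t
p-value (Spearman optional); rows with NaN fields — e.g., a terminal
deficiency whose size cannot be determined — are dropped first.

### Variant filtering, depth ratios, kinship

Per-caller variant tables merge on exact keys for SNVs (conflicting
reference alleles at one site raise an error) and with ±10 bp / ±10% length
tolerance for structural variants (caller breakpoint jitter). Candidate
lethal mutations must be HIGH or MODERATE impact, inside the fine-mapped
interval, and absent from every sequenced lethal line that did not map there;
a strict mode additionally requires presence in every set member. Strict mode
is the default — it is correct for identity-by-descent sets — but recovery
studies run per-line, because independently arising mutations in the same
fragile gene are distinct variants and a shared-in-set requirement would
empty the candidate list by construction. Every excluded variant carries its
reason, and candidates plus exclusions partition the input.

Heterozygous terminal deletions are detected as the ratio of mean per-base
depth in a peri-telomeric window (default 2L:5,000–11,000) to a mid-arm
control (2L:10,000,000–12,000,000); carriers sit near 0.5 and non-carriers
near 1.0, with 0.75 as the default (strictly-below) threshold — a midpoint
chosen because published carriers cluster at 0.48–0.60 and non-carriers at
0.96–1.03; the threshold is a parameter since classification is really by
comparison.

Kinship uses the KING-robust between-family estimator,
φ = (N_het,het − 2·N_AA,aa)/(N_het(i) + N_het(j)), which does not assume a
homogeneous population — necessary because every line shares the CyO
balancer, inflating absolute coefficients; only relative values are
interpreted. A zero heterozygosity denominator yields NaN, never a silent 0,
and the matrix diagonal is left blank. For balanced stocks sequenced as
wild/CyO heterozygotes, presence/absence variant tables code carried
variants as heterozygous (`genotypes_from_variant_tables`).

## The synthetic screen

The generator (`synthetic_data`) emulates the data-generating process the
analysis assumes. Defaults are the screen's own conditions:

| parameter | default | rationale |
|---|---|---|
| `chromosome_length` | 48 Mb | 2L + 2R scale |
| `lambda_true` | 0.639 | implied by a 47% lethal fraction (−ln 0.53) |
| `n_flies` | 410 | ~555 sublines at the subline-count mix below |
| `sublines_per_fly_weights` | 0.68/0.29/0.03 over 1/2/3 | mostly 1–2 sublines, <5% more |
| `female_fraction` | 0.15 | a minority of collections used wild females |
| `gene_catalog_size` | 2,000 | lethal-capable loci tiled over the chromosome |
| `coding_fraction` | 0.25 | coding share of chromosome bases |
| gene fragility | rank^(−0.5) power law, permuted | insertion-site preference; yields tens of multi-line sets with the largest near 5–8 lines |
| `n_deficiencies` | 70 | kit size |
| `deficiency_size_range` | 160 kb – 1.6 Mb, log-uniform | printed kit range; log-uniform mean (~625 kb) reproduces 67–73% panel coverage |
| panel placement | one per equal slot, jittered | deficiency kits are curated tiling paths, not uniform scatters |
| `offspring_mean` | 60 (Poisson) | the ≥35-offspring scoring threshold is almost always met |
| `miss_probability` | 0 | scoring demands 0 straight-winged; escapers opt-in for robustness tests |
| `ibd_fraction` | 0.05 | occasional related flies caught days apart |

Lethal-mutation counts per chromosome are Poisson(`lambda_true`); mutation
genes follow the fragility weights, positions are uniform within the gene,
and classes mix TE insertions (55%), premature stops (18%), deletions (17%)
and splice-site changes (10%) — TE-dominated, as observed. Male sublines
carry one of the fly's chromosomes uniformly; female sublines carry a
single-uniform-crossover recombinant (the reason rule (e) deduplicates female
sublines; one breakpoint is enough to make the point and keeps recombinants
analytically simple). Cross outcomes follow Punnett-square logic: the
balancer-homozygote class always dies, surviving classes are equally likely,
so the balancer-free class is one third of scored offspring when it survives
and zero (bar escapers) when an uncomplemented lethal kills it. Offspring
totals are Poisson(`offspring_mean`); the crossing protocol does not pin
down this distribution, so it is an implementation choice exposed in the
config.

Variant tables for lethal lines contain the line's causal mutations as
HIGH-impact records (identical events in identity-by-descent copies produce
identical records), one shared background set per IBD group, and private
Poisson-count background noise that is 80% MODIFIER / 18% LOW / 1.5%
MODERATE / 0.5% HIGH. Depth tables draw per-window Poisson depths, halved
across the peri-telomeric window for deletion carriers.

Each simulation stage (catalog, population, sublines, panel, crosses,
variants, depths) draws from its own seeded stream, so changing one stage's
parameters never perturbs another's output, and identical (config, seed)
runs are byte-identical.

**What the simulator does not emulate:** read-level sequence data, TE
sequence evolution or piRNA suppression dynamics, multigenic synthetic
lethality, gain-of-function lethality, haploinsufficiency, segregation
distortion, or viability intermediate between lethal and normal. Passing
tests therefore demonstrate that the estimators are correct under the
single-locus LOF model with binary lethality — they do not validate those
assumptions for real populations.

## Calibration studies and problem sizes

The test suite runs the null model against replicate simulated screens of
5,000 chromosomes at λ ∈ {0.2, 0.64, 1.5} (200 replicates each for the
expectation-CI study, 120 for the prediction-interval study). These
calibration runs use uniform gene fragility: the null model assumes
uniformly placed mutations, so its calibration is tested under its own
assumptions; the default power-law fragility adds variance in
mutation-weighted coverage that the model does not claim to capture (with
skewed fragility the fraction of mutations inside the panel differs from the
base-pair coverage fraction by a few percent per panel). End-to-end
candidate-mutation recovery runs at the screen's own scale (410 flies,
~555 sublines, 70 deficiencies) and requires the planted causal mutation to
be the unique candidate in ≥95% of gene-resolved allelic sets.

## Numerical and design choices

- The zero-truncated mean is continuous at λ = 0 (limit value 1).
- P0 endpoints outside (0, 1) raise with the offending endpoint named; the
  degenerate SE = 0 case returns a zero-width CI at the point estimate.
- `ztp_mean(λ) ≥ max(1, λ)`; `expected_mapped` is monotone in each argument.
- Ties in the per-line overlap sweep are broken by (start, end) sort with a
  stable mergesort, so duplicate deficiency entries and panel reorderings
  cannot change counts.
- The X1 used for the expected mapped count is an explicit argument (the
  distinct lethal count is the default recommendation, and is what
  reproduces the published expectation).
- Depth-ratio windows are parameters; the defaults are the published
  peri-telomeric/control pair.

## Known limitations

- The expectation CI vs prediction interval distinction above: consistency
  of one observed screen with the expectation CI is a weak test, and
  replicate-level calibration requires the prediction interval.
- The distinct-region count is conservative by construction: two lethal
  mutations falling in one overlap cluster are counted once, deflating
  realized counts by ~1% at λ ≈ 0.6 under the default panel and more as λ
  or panel overlap grows.
- Rule (c)'s deterministic 1.5 makes `n_total` an expectation, not an
  integer-valued count; variance from this choice is ignored in the
  binomial SE.
- The allelic-set frequency denominator treats the distinct-chromosome
  sample size as fixed; uncertainty in that denominator is not propagated.
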