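# Methods

## Problem and model

`ctcnt` analyses recombinants produced by bacterial natural transformation
between two diverged strains — in particular *Bacillus subtilis*
cell-to-cell natural transformation (CTCNT), where live donor cells supply
the transforming DNA. When the donor and recipient chromosomes differ at a
dense set of single-nucleotide positions, each recombinant genome is a
mosaic whose ancestry can be read off marker by marker: a *transferred
segment* is a contiguous run of donor-specific alleles, interpreted as one
homologous-recombination event of donor DNA.

The pipeline has four analysis stages plus a generative model:

1. **markers** — build the informative-marker map (positions where the two
   strains' homozygous SNV alleles differ) and score each recombinant as
   donor / recipient / missing at every site.
2. **segments** — call transfer events as maximal donor-state runs.
3. **tracts** — consolidate nearby segments into recombination tracts, an
   estimate of the number of independent DNA-uptake events.
4. **summarize** — per-clone and cohort statistics, cohort union coverage,
   co-inheritance (linkage) analysis, transformation-efficiency arithmetic.
5. **simulate** — synthetic donor/recipient cohorts with planted transfers,
   used as the test surface for everything above.

## Segment calling

Scanning informative sites in increasing coordinate order, a run starts
where two consecutive donor-state sites are seen (`min_seed = 2`), extends
over further donor sites, and ends at the last donor site before a
recipient-state site. Runs whose hull length (first to last donor site,
inclusive) exceeds `min_length = 500` nt are reported; the comparison is
strict (`> 500`), so a 2-site run with hull 401 bp is discarded and one
with hull 501 bp is kept.

Two rules deserve emphasis:

- **Missing sites are transparent.** A site filtered for quality, depth,
  heterozygosity or a third allele neither supports nor interrupts a run.
  Rationale: filtering happens *before* run calling, so an unreliable call
  cannot witness an interruption.
- **Circular chromosomes.** A run reaching the last informative site and a
  run starting at the first one, with no recipient-state site between them
  across the replication origin, are merged into one origin-spanning
  segment before the seed/length filters; lengths are computed modulo the
  genome. `circular=False` (CLI `--linear`) disables this.

Segment boundaries are reported at donor-state marker positions (the run
hull), not at midpoints of flanking gaps: the true breakpoint falls
somewhere in the marker-free gap outside the hull, so the boundary error
is bounded by the local inter-marker spacing (~56 bp on average at the
default marker density). An optional `max_interrupts > 0` lets a run
absorb that many recipient-state sites before terminating; the default is
0 (a single recipient site ends the run).

## Tract consolidation

Clustered segments in one clone plausibly derive from a single long donor
molecule fragmented before or during integration. Segments are grouped
greedily left-to-right into tracts subject to three criteria, evaluated at
every append: inter-member gap < 20 kb, running occupancy (summed member
length / current span) ≥ 50%, and span < 500 kb. A segment that cannot be
appended closes the tract and starts the next one; singleton tracts are
always valid. Greedy append-time evaluation was chosen because it is
deterministic and order-canonical; an exhaustive enumeration over all
contiguous partitions of up to 8 segments confirms in tests that the
greedy result always satisfies the same per-prefix feasibility rules. An
alternative "post-hoc split" reading (occupancy evaluated only on final
tracts) exists but is not implemented as a mode; the append-time rule is
the package's contract.

A tract never wraps the origin unless one of its member segments does; if
one does, the scan starts at the wrapped member (its start is shifted
before position 1), which keeps gap and span arithmetic linear.

## Summary statistics and linkage

Per-clone reports give event count, maximum / mean / total transferred
DNA in kb and the percentage of the donor genome, with kb and percentages
rounded to 2 decimals (raw bp retained internally); the cohort overall
mean pools clones (sum of totals / sum of event counts). Cohort union
coverage counts overlapping intervals once, via a wrap-aware
sort-and-sweep checked against a per-bp bitmap oracle.

Co-inheritance of a query marker B among clones selected at marker A is
the fraction of selected clones also donor-converted at B, with an exact
Clopper–Pearson 95% CI. "Converted at a locus" means donor state at the
informative marker nearest the locus (ties broken toward the lower
coordinate); distances on circular genomes are minor-arc. Under the
generative model (Poisson(λ) segments, uniform starts on a circle of
length G, exponential lengths of mean L), coverage counts of fixed points
are Poisson with

    μA = λL/G         (one point)
    μ1(d) = μA·e^(−d/L)   (two points at distance d, same segment)

and splitting coverage into independent both/only-A/only-B components
gives the closed form

    P(B | A) = [1 − 2e^(−μA) + e^(−2μA + μ1(d))] / [1 − e^(−μA)]

which equals 1 at d = 0 and decays to the distance-independent *double
transformation* (gene congression) plateau 1 − e^(−μA) as d → ∞. The
`linkage_decomposition` operation estimates the plateau from points at
distance ≥ 500 kb (the empirical breakpoint beyond which co-inheritance is
flat), either as their mean or from the single farthest point — both
modes are provided because a plateau is sometimes quoted from one distant
marker pair; the excess over the plateau at each distance is the
single-segment linkage contribution.

Transformation efficiency is reported as transformants per μg of donor
DNA: colonies / (plated volume in ml × DNA concentration in μg/ml).

## Synthetic-data generator

The generator emulates the sequencing-based study design, not reads:

- **Marker map.** Inter-site gaps i.i.d. geometric with mean 56 bp on a
  4,011,967 bp circular chromosome (defaults), a discretised Poisson
  process matching the observed ~70,909 evenly distributed SNPs between
  the donor and recipient strains; a `fixed_grid` mode gives exact
  spacing for deterministic tests. Donor/recipient alleles are random
  distinct bases.
- **Transfers.** Each clone receives N ~ Poisson(λ) segments (default
  λ = 15, consistent with observed single-marker-selection clones), with
  uniform starts on the circle and exponential lengths of mean L̄
  (default 30 kb, the order of observed mean segment/tract sizes).
  Exponential is the minimal one-parameter length law compatible with the
  empirical summaries; lognormal and fixed alternatives are configurable.
  Segment independence within and between clones is a modelling choice —
  the data cannot rule out correlated uptake.
- **Genotype.** A site is donor iff covered by ≥ 1 planted segment;
  overlapping plantings are allowed and their union defines donor state
  (a marker-based caller cannot distinguish overlapping events either).
  Truth is stored in continuous coordinates; the expected caller output
  for a planting is its *marker hull*, computed by a helper so tests
  compare like with like. An optional `missing_rate` hides sites to
  exercise missing-transparency; default 0.
- **Selection.** Auxotrophic-marker selection is rejection sampling: a
  clone is accepted when every selected locus is covered by a planted
  segment *and* its nearest informative marker is donor-state (the second
  condition guarantees selection is visible in the genotype; with 56-bp
  spacing and kb-scale segments it is almost always implied by the
  first). The acceptance probability for one locus is 1 − e^(−λL̄/G),
  used as an analytic cross-check of the sampler.
- **Reproducibility.** One root seed is split into per-clone child
  streams (`numpy.random.SeedSequence.spawn`), so a cohort is bit-identical
  across runs and earlier clones are invariant to the number requested.

What the generator does **not** model: read-level noise and coverage,
indels and structural variation, accessory (strain-specific) regions,
prophage masking, and any mechanistic coupling between transfer events.
Passing tests therefore demonstrate correctness of the calling,
consolidation and summary algorithms under the stated generative law —
not robustness to alignment artefacts or reference bias in real data.

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED output is 0-based
  half-open; VCF is v4.2 with GT-only genotypes (1/1 donor, 0/0
  recipient, ./. missing, recipient as the reference).
- The `> 500` nt length filter is strict; exposed as a config constant.
- Divergence profiling counts informative sites in tiling 10-kb windows
  on the shared coordinate system. This coordinate-matched form is exact
  for synthetic pairs without structural differences; it deliberately
  replaces alignment-based fragment comparison, which is out of scope.
- A clone VCF record absent at a map site scores *missing* by default
  (filtered upstream); `absent_state=RECIPIENT` supports variants-only
  VCFs where absence means reference.
- Interval unions use a short sort-and-sweep because wrap-aware circular
  semantics do not fit off-the-shelf interval containers.

## Problem sizes used in tests and the acceptance script

Genome-scale checks run one 12-clone cohort at the full 4.01-Mb genome
(λ = 15, L̄ = 30 kb, one selected locus) for planted-segment recovery, a
300-clone cohort (λ = 20, L̄ = 30 kb) for parameter recovery, and 600,000
Monte-Carlo clones (λ = 3, L̄ = 50 kb; ≥ 20,000 accepted after selection)
for the co-inheritance cross-check; oracle equivalence uses 1,000 random
≤ 200-site tracks, 300 random clones of ≤ 8 segments for the exhaustive
partition oracle, and 50 random 100-kb multi-clone sets for the bitmap
union oracle.

## Known limitations

- Mean called-segment length is a biased estimator of the simulated mean
  segment length: overlapping plantings merge (a boolean-model "busy
  period" effect that grows with λL̄/G), the > 500 nt filter removes the
  shortest runs, and hulls shrink each boundary by part of one marker
  gap. At λ = 20, L̄ = 30 kb the net bias is on the order of +6–10%, as
  quantified in the parameter-recovery test against the planted union
  components.
- Tract criteria are heuristic; whether clustered segments truly derive
  from one uptake event is not statistically tested.
- The closed-form co-inheritance ignores the rare possibility of a
  segment covering two loci via the longer arc of the circle.
- Plasmid transfer is representable only as presence/absence per clone;
  segments are called on the chromosome.
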