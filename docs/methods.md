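# Methods

`sweepscan` implements a demography-aware genome scan for recent positive
selection in a two-population design (a putative sweep population and a
reference population, with an optional outgroup), together with the
demography-free empirical-outlier comparator, downstream fixed-site and
gene-set analyses, and a synthetic-data generator that emulates the whole
study design so the pipeline can be exercised and falsified end to end.

## Summary statistics

All statistics are computed in sliding windows (default 100 kb, 10 kb
step) over biallelic SNVs at which every sample is called, and are
per-site averages over the window's *callable* base pairs (the
intersection of the window with a user-supplied callable mask). Windows
with fewer than 30 kb callable are discarded. Samples may be haploid or
diploid; everything is counted in chromosomes, so a haploid reference
haplotype enters alongside diploid individuals.

With derived/alternate counts `c` out of `n` chromosomes at each site:

- **π** (nucleotide diversity): `Σ c(n−c)/C(n,2)` over sites, divided by
  callable bp. **π_between**: `Σ [c₁(n₂−c₂) + (n₁−c₁)c₂]/(n₁n₂)` per
  callable bp.
- **F_ST** = (π_between − π_within)/π_between with π_within the
  arithmetic mean of the two populations' diversities (Hudson/Slatkin
  diversity form). Undefined when π_between = 0; negative values are kept.
- **Tajima's D** per population from S and the summed pairwise diversity,
  with the standard 1989 normalizing constants; undefined when S = 0 (and
  degenerate for n ≤ 3, which cannot occur in the supported designs).
- **Δπ** = ln(π_reference/π_sweep). When π_sweep = 0 it is replaced by
  half the smallest attainable nonzero value for the window,
  0.5/(callable·C(n_sweep,2)), so the statistic saturates rather than
  diverges. Natural log; any base is a monotone rescale and leaves
  p-values unchanged.
- **ΔTD** = TD_reference − TD_sweep; undefined when the sweep population
  has no segregating sites in the window.

All three contrasts are oriented so that a sweep in the sweep population
(diversity loss, excess rare variants, elevated differentiation) falls in
the **right** tail.

## Null model and FDR calibration

The neutral null is built by coalescent simulation (msprime) of
independent, fully callable 100 kb windows with recombination, under a
configurable demographic model (population tree with piecewise-constant
sizes, optional migration and pulses). Null windows are pushed through
exactly the same window-statistic code as observed data, so every
convention (estimators, undefined-value rules, the Δπ epsilon) is shared.
Two modes exist: fixed parameters, and posterior draws (each row of a
draw table re-parameterizes the model and contributes an equal number of
replicates).

Per statistic, each observed window gets an upper-tail empirical p-value
`p = #{null ≥ obs}/N` (no continuity correction — p may be exactly 0, and
such windows get q = 0, which is the intended behaviour for ranking).
Benjamini–Hochberg q-values are computed once per statistic across all
retained windows genome-wide; windows with undefined ΔTD keep their other
q-values but are excluded from the composite. The composite score is
`CMS(1−FDR) = (1−q_Δπ)(1−q_FST)(1−q_ΔTD)` ∈ [0,1]. Windows are classified
four ways by whether min q ≤ α (default 0.01) and whether CMS clears the
minimum of the top-ranked regions' maxima.

Windows with q ≤ α for at least one statistic are merged into regions
whenever the gap between the growing region envelope and the next window
is ≤ 200 kb (transitive, across statistics). Regions are ranked by the
maximum CMS over their member windows (ties: longer region first, then
coordinates; tied scores also get an average display rank). Regions whose
member windows all lack a defined CMS remain called regions but are
excluded from the CMS ranking. An optional diversity-panel validation
fails any region whose mean panel diversity over member windows is not
below the mean over non-member windows within a 500 kb flank.

The comparator ranks windows by per-statistic percentile (maximum-rank
tie convention, so the best window has percentile exactly 1), multiplies
the three percentiles, re-ranks the product ("joint percentile"), and
flags the top 1%. No demographic model enters, which is exactly why the
two methods disagree; the package quantifies the disagreement
(`compare_region_sets`, and the fraction of top-1% windows whose minimum
q exceeds α).

## Fixed sites and enrichment

Alleles are polarized by the outgroup (ancestral = allele fixed in the
outgroup; polymorphic outgroup ⇒ unknown). Candidate fixed sites have
every sweep-population chromosome derived and every reference +outgroup
chromosome ancestral; they are retained when their derived-allele
frequency in a broader diversity panel is ≥ 0.75, and their
functional-class composition inside vs outside outlier regions is tested
with a Pearson χ² (no continuity correction).

Genes within 25 kb of the peak-CMS window of the top 100 (optionally
panel-validated) regions form the input set for term enrichment: fold
enrichment `(k/n)/(K/N)` and a hypergeometric upper-tail p per term, BH
correction across terms, reported at FDR ≤ 10%. The plain hypergeometric
tail is used rather than any modified score, so published fold
enrichments are formula-exact while p-values are method-specific.

## Synthetic data

The generator emits a complete bundle — mixed-ploidy VCF, callable-mask
BED, GFF3 genes, gene→term TSV, panel window-diversity TSV, planted-site
panel frequencies and functional classes, the model YAML and a manifest —
deterministically per seed.

**Demography (bundled default).** An ancestral canid-like population of
15,000 splits 10,000 generations ago into a "wolf" lineage (constant
15,000) and a "dog" lineage that passes through a domestication
bottleneck (2,000 between 3,000 and 2,500 generations ago) before
recovering to 5,000; mutation and recombination are 1e-8/bp/generation;
an outgroup (10,000) diverges 40,000 generations ago from a root sized so
that its presence leaves the focal pair's marginal history unchanged.
The bottleneck strength was chosen once so that the site-frequency
spectrum is visibly distorted genome-wide while neutral windows only
rarely lose most of their diversity: under a substantially harsher
bottleneck, neutral windows frequently mimic completed sweeps and no
calibrated scan — this one or the original design — could separate signal
from drift at desk scale. Samples follow the scanned design: 5 dog
chromosomes (two diploids plus a haploid reference), 6 wolf chromosomes,
2 outgroup chromosomes.

**Sweep emulation.** Sweeps are emulated demographically, not by
forward-time selection: within each sweep locus the dog's recent size is
divided by `intensity` during a crash epoch from 2,500 to 250 generations
ago. The crash duration guarantees coalescence of the locus; the
250-generation recovery phase sets the locus diversity floor
(≈ 2μ·t ≈ 5×10⁻⁶), chosen so that the realized fold reduction in
diversity equals the default intensity of 100 — i.e. "intensity" reads
directly as the diversity reduction — while leaving roughly one expected
segregating site per 100 kb so ΔTD remains computable in most sweep
windows. The post-crash excess of young rare variants also produces the
negative Tajima's D of a completed sweep. Sweep loci are simulated
independently of the neutral background and spliced in; the independence
across the splice boundary is an approximation.

**What the generator does not emulate.** Genotyping error, mapping
artefacts, CNV/repeat-driven mask structure (the mask is random 1 kb tile
dropout at 10%), variable recombination/mutation rate along the genome,
gene conversion, partial and soft sweeps, and linkage between sweep loci.
Panel diversity is drawn directly (lognormal around 3×10⁻⁴, reduced
12.5-fold in sweep loci) rather than simulated from panel genomes, and
planted fixed-derived sites with panel frequencies straddling the 0.75
threshold are injected from a dedicated random stream so the fixed-site
truth table is reproducible from the config alone. Passing tests
therefore demonstrate the statistical machinery on idealized data; they
do not certify performance on real resequencing data.

## Problem sizes and numerical choices

The default desk scale is 2 × 10 Mb contigs (~2,000 windows), 10 injected
sweeps (width 100 kb, intensity 100, one per 2 Mb), and a 5,000-replicate
null; a full scan runs in well under a minute after ~40 s of simulation.
Empirical p-values use binary search on the sorted null; BH is the exact
step-up with undefined entries excluded from m; region merging measures
gaps between interval boundaries on the half-open envelope, and a gap of
exactly 200 kb joins. Determinism: every stage is reproducible from a
single integer seed; simulation seeds are spawned from per-purpose
substreams so adding one output does not shift another.

## Known limitations

- **Null size governs the attainable p-value quantum.** With N null
  replicates, p-values are multiples of 1/N, and BH at α = 0.01 across
  ~2,000 windows effectively requires windows to exceed *all* N null
  draws. At N = 5,000 the probability that some neutral window of a
  20 Mb genome does so is ≈ 0.1–0.35 (the sliding-window maximum inflates
  it beyond the independent-window estimate), so family-wise discovery
  control under the global null is only loose at this scale; at the
  original design's N = 200,000 the same probability is below 1%. For the
  same reason, whether a given intensity-100 sweep clears the FDR
  threshold can depend on the random depth of the particular null draw's
  extreme tail.
- **Saturation.** Once a window's sweep-population diversity reaches the
  epsilon floor, Δπ carries no further signal, and a neutral window that
  happens to coalesce entirely within the bottleneck is statistically
  indistinguishable from a completed sweep — an identifiability limit of
  window summary statistics at 5 chromosomes, not an implementation
  artefact.
- Observed windows have 30–100 kb callable while null windows are fully
  callable 100 kb; per-site statistics are comparable and no rescaling is
  applied, at the cost of slightly heavier observed tails.
- BH is applied to strongly dependent overlapping windows; no correction
  beyond BH is attempted.
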