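# Methods

This note documents the models and procedures tagarray implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Data model and conventions

Haplotype panels are phased 0/1 matrices (two rows per sample) over
biallelic variants sorted by (chromosome, position, id). Multiallelic VCF
records are skipped — not split — because all downstream statistics (r²,
obsRSQ, MAF) are defined pairwise on biallelic markers; the skip count is
logged. Indels are treated exactly like SNPs once encoded as biallelic
ref/alt records. VCF positions are 1-based inclusive, BED intervals
0-based half-open, and every internal interval test uses the half-open
convention; a leading `chr` prefix is stripped for matching. Missing
genotypes in TSV matrices are the literal `NA` (−1 internally).
Manufacturer validation status travels with each variant (a `VS` INFO
field in VCF round trips) rather than through an external database
lookup.

## Linkage disequilibrium

r² is computed from phased haplotype counts, not from a genotype
composite estimator, because the intended input is a phased reference
panel. LD involving a monomorphic variant is undefined and is signalled
(exception in the scalar API, NaN in the matrix API) instead of being
reported as 0: silently coercing it either way would misclassify
variants as covered or uncovered. Candidate tag–target pairs are
restricted to a window (default 1 Mb, configurable); tagging operates
within gene regions and the window keeps the pair enumeration linear in
practice.

## Tag selection

Tagging runs in prioritized rounds; the default schedule is
(r² ≥ 0.9, validated only), (r² ≥ 0.8, validated only),
(r² ≥ 0.9, non-validated allowed), applied to targets with MAF ≥ 0.05.
Within a round the selection is greedy set cover: repeatedly add the
eligible candidate covering the most still-untagged targets. Design
choices:

- A candidate that is itself a target tags itself with r² = 1, in the
  first round whose pool admits it.
- Markers selected in earlier rounds tag remaining targets *for free* at
  the start of each later round (they are already on the array), before
  any new marker is added.
- Ties are broken by validated status, then higher mean r² to the newly
  tagged targets, then smaller genomic position, then id — selections are
  fully deterministic.
- Targets below the MAF floor are dropped from tagging with a logged
  count; callers decide whether to keep them in coverage denominators.
- Multi-population designs run the selection per population and report
  the union of the selected sets along with each population's own
  assignment table (requiring a tag to pass in all populations
  simultaneously can be emulated by intersecting per-population r²
  tables, but the union is the default because it matches how a combined
  design serves each cohort).

Greedy set cover is not optimal in general, but on desk-scale LD
instances (≤ 12 candidates × 12 targets) the test suite verifies it
against exhaustive minimum-cover search.

The density report divides the flanked region length by the marker count
and rounds half up (deterministic, independent of the platform's
banker's rounding).

## Imputation engine

The built-in engine is a Li–Stephens haplotype-copying HMM. States are
the K reference haplotypes; between sites at map distance d the copied
haplotype switches with probability ρ(d) = 1 − exp(−switch_rate · d),
landing uniformly on the K haplotypes; a typed site emits the observed
allele with probability 1 − error_rate on match and error_rate on
mismatch. This transition family composes exactly across distance
(T(d₁)T(d₂) = T(d₁+d₂)), so untyped sites are silent states and their
posterior copying distribution combines the forward vector at the left
flanking typed site and the emission-weighted backward vector at the
right flanking typed site. The imputed allele probability is the
posterior-weighted mean of reference alleles; diploid dosage sums the
two haplotypes of each held-out sample; typed sites pass through as the
measured genotypes.

Numerics: forward and backward vectors are rescaled per site; forward
and backward log-likelihoods agree to 1e-9 and per-site posteriors sum
to 1 to 1e-9 (both tested). Map distance is the variant-index distance
within the reference panel — a uniform map, chosen because no genetic
map accompanies the input; a physical-distance map would slot into the
same ρ(d).

Defaults: `switch_rate = 0.01` per site (about one expected switch per
100 consecutive typed sites at desk-scale panel sizes) and
`error_rate = 0.001`; both configurable. Held-out samples are assumed
already phased (they come from the phased panel); the engine does no
phasing and accepts no genotype likelihoods.

Production imputation tools implement richer models (dynamic effective
population size, reference compression). The engine here preserves the
*evaluation protocol* while staying self-contained; any external program
can replace it through the adapter contract (reference VCF + typed VCF +
site list in, dosage TSV out), which enforces the same [0, 2] bounds and
typed-site pass-through.

## Hold-out coverage protocol

Per population, eligible samples (minus supplied relatedness exclusions,
which are inputs — no kinship estimation is performed) are randomly
permuted under the given seed and cut into consecutive groups of 10; a
smaller remainder group is kept rather than discarded, so every eligible
sample is evaluated exactly once. Each group is restricted to the array
sites and imputed against the panel minus that group and minus the
exclusions; dosages are pooled across groups.

obsRSQ is the *squared* Pearson correlation between pooled dosage and
measured genotype (the "RSQ" convention; the signed/unsquared variant is
available behind a flag). It is undefined when the measured genotype
does not vary among evaluated samples; undefined variants are excluded
from both numerator and denominator of coverage and counted separately,
because counting them as either covered or uncovered would bias the
estimate. When the measured genotype varies but the dosage is constant,
the dosage is uninformative and obsRSQ is 0. Threshold comparison uses
≥. Coverage summaries stratify by population, MAF stratum (defaults
≥ 0.01 and ≥ 0.05, using panel MAF in the evaluated population) and
region class (flanked regions plus a genome-wide class), and an empty
stratum reports NaN, never 0.

Seeded runs are bit-reproducible end to end; evaluation may be split by
chromosome and recombined without changing any number (the per-variant
computation is independent across variants).

## Sample and marker QC

Sample rules are applied in a fixed order — scan failure, then
DQC < 0.82 (strict), then stage-1 call rate < 0.97 (strict) — so each
failing sample carries exactly one primary reason and the reason counts
are disjoint. Negative controls are segregated and excluded from all
pass-rate denominators; they are not scored (the quantitative
"separation from background" criterion is upstream of this pipeline).
Plate summaries report per-plate pass rate and mean stage-1 call rate
over DQC-passing scans.

Marker QC consumes probeset classifications as inputs; computing them
from raw intensities is out of scope. Best-probeset selection ranks
PolyHighResolution > NoMinorHom > MonoHighResolution > Hemizygous > OTV
> CallRateBelowThreshold > Other, breaking ties by higher call rate then
probeset id. The strict filter removes Other, CallRateBelowThreshold,
OTV and Hemizygous and keeps MonoHighResolution only for validated or de
novo markers; conditional keeps for OTV (when the off-target variant is
itself genotyped) and Hemizygous (after visual inspection) sit behind
flags because both require evidence this pipeline does not see.

Replicate reproducibility and reference concordance compute match
fractions over mutually called genotypes only; concordance averages per
sample by default (per-genotype pooling behind a flag) and can restrict
to markers above a reference call-rate floor (default 0.95). MAF bins
are monomorphic, (0, 0.01), [0.01, 0.05), [0.05, 0.5], with MAF taken
from observed genotype counts ignoring missing calls.

## Synthetic data

The simulator is a founder-mosaic model: founder haplotypes drawn
site-wise from a founder MAF law (uniform MAF on [0.05, 0.5] by default,
or a U-shaped Beta(0.5, 0.5) frequency law), descendants copying
founders with per-adjacent-site switch probability (default 0.01) and
per-site flip probability (default 0.001). Defaults simulate 100
samples × 200 sites over 1 Mb from 20 founders — small enough to run the
full hold-out protocol in seconds, structured enough that LD decays with
distance and imputation quality responds to array density. Population
structure is founder-frequency drift per population: sufficient to
produce per-population coverage differences in the protocol's output,
not calibrated to any real demography.

What the simulator does **not** emulate: coalescent genealogies,
recombination hotspots, mutation-age/frequency correlation, sequence
context, genotyping intensity error. Consequently, passing tests
demonstrate that the *protocols* are implemented correctly and respond
in the right direction to density, noise and LD — they do not predict
the absolute coverage an array achieves on a real cohort, which depends
on the real panel and the production imputation engine.

The pilot QC fixture is deterministic and reproduces a published pilot's
printed marginal counts exactly (646,247 markers across 7 × 3
classification/validation cells; 636 samples with 1/8/5 failures; 7
negative controls); its call-rate column holds nominal per-class values,
as only classification and validation status drive the decision rules.
The call-corruption utility replaces each called genotype with a
uniformly chosen *different* genotype at the requested rate, so the
expected concordance after corruption at rate q is exactly 1 − q.

## Problem sizes

The bundled analyses run, by design, at desk scale: simulated panels of
100–200 samples and 100–200 sites, hold-out groups of 10, tagging
instances up to a few hundred candidates, and brute-force oracles on
≤ 12 × 12 set-cover instances and ≤ 4-typed-site/3-haplotype HMMs. The
full test suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

- The built-in engine's absolute obsRSQ values are not calibrated to any
  external imputation program; only protocol-level properties transfer.
- Greedy tagging is verified minimal only on small instances; on large
  instances it carries the usual ln(n) set-cover guarantee, not
  optimality.
- Kinship, sex inference and batch effects are consumed as inputs, never
  estimated.
- The uniform genetic map ignores recombination-rate variation; supply a
  physical map through the switch-rate scaling if one is available.
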