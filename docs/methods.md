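# Methods

`herdgen` assesses the conservation status of a small closed livestock herd
from SNP-array genotypes: marker quality control, diversity statistics,
LD-based effective population size, genomic relationships, boar-anchored
family structure, and runs-of-homozygosity (ROH) inbreeding. This note
records the statistical models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Genotype model and coordinates

Genotypes are biallelic dosage codes counting copies of allele a2 (the
second allele of a `.bim` record): 0, 1, 2, or missing. Physical positions
are 1-based base pairs and are treated as opaque integers; no genome build
is assumed, and segment lengths are computed as `end − start` (the PLINK KB
convention), not `end − start + 1`. The difference shifts F_ROH at the 1e-6
level but matters for exact comparisons with PLINK output. Chromosome
labels 1–18 are autosomes and 19/20 the sex chromosomes, matching an
18-autosome karyotype such as the pig. Only the SNP-major PLINK 1 binary
dialect is supported; individual-major files are rejected rather than
silently transposed. The text dialect carries no allele-order metadata, so
the `.ped` reader fixes a1/a2 as the lexicographically sorted observed
alleles — binary files are the lossless interchange format.

## Quality control

Four marker filters run **sequentially** — call rate ≥ 0.90, MAF ≥ 0.01,
Hardy–Weinberg exact p ≥ 1e-6, autosomes only — with each stage's removal
count taken on the survivors of the previous stage, so
`retained = input − Σ removals` holds exactly and the report's arithmetic
is reproducible. PLINK's internal filter order differs, so per-stage counts
(not the final retained set) can differ from a PLINK log. The HWE test is
the standard exact test on complete genotypes (two-sided, no mid-p),
computed with the usual stable recurrence over heterozygote counts and
verified exhaustively against full enumeration for all configurations with
n ≤ 25. Individuals are never filtered (array QC for a fully pedigreed herd
keeps every animal).

Diversity statistics: P_N = M/N with "polymorphic" meaning both alleles
observed (MAF > 0), He = mean over markers of 2p(1−p) (plug-in estimator;
the 2n/(2n−1) small-sample correction is available behind a flag), Ho =
mean per-marker fraction of heterozygous calls among non-missing calls.
Missing calls are excluded from numerators, denominators and allele counts
throughout.

## LD decay and effective population size

r² between two markers is the squared Pearson correlation of unphased
dosage vectors over pairwise-complete individuals (composite LD). Pairs on
the same chromosome are binned by physical distance (default: 10
log-spaced bins from 50 kb to 5 Mb, half-open `[lo, hi)`); bins holding
more than `max_pairs_per_bin` (default 10 000) eligible pairs are
downsampled uniformly with a seed, which keeps 40 K-marker panels at desk
scale. Base pairs map to Morgans with a fixed 1 cM/Mb (configurable) —
array chips ship no linkage map, and this is the conventional default.

Each bin yields one Ne estimate through the Sved relation
`N_e = (1/4c)(1/r² − 1)` with `t = 1/(2c)` generations as the ancestral
time it addresses. With n genotyped individuals the expected sampling
inflation of r² is about 1/(2n); it is subtracted before inversion
(floored at ε = 1e-6; a floored estimate is flagged as effectively
unbounded). No mutation-rate term is used. The headline Ne is the
largest-distance (most recent t) usable bin; because bin placement is a
free choice, trajectory-level output is the primary product and exact
parity with any particular LD-software default is not promised.

Calibration (test suite): on Wright–Fisher populations of true size 50,
genotyping the whole population, the headline estimate averaged 53 over 10
replicate seeds (inside ±30%). The 1/(2n) correction is validated where
sampling actually occurs — 25 individuals genotyped out of 100 — where it
reduces the mean absolute bias roughly threefold; when the entire
population is genotyped there is almost no sampling inflation left to
remove and the correction slightly overshoots.

## Genomic relationships

G is VanRaden's first method, `G = ZZᵀ / (2Σ p_j(1−p_j))` with `Z = X −
2p`, allele frequencies estimated from the sample itself (a conservation
herd has no external base population), missing dosages mean-imputed (zero
after centering), monomorphic markers skipped. The method and frequency
source are recorded in the matrix metadata. The IBS distance is
`D_ij = Σ|x_i − x_j| / (2 m_ij)` over pairwise-complete markers; a pair
sharing no genotyped marker is an error, not a silent NaN. D is symmetric
with zero diagonal and values in [0, 1]; the triangle inequality holds on
complete data and is checked empirically (not guaranteed) under missing
data.

## Family structure

The boars' IBS submatrix is clustered with classic Saitou–Nei neighbor
joining: join the pair minimizing `Q_ij = (r−2)D_ij − ΣD_i − ΣD_j`, ties
broken by the smallest node-index pair, negative branch lengths clamped to
zero with the deficit moved to the sibling edge (clamping is recorded in
tree metadata). Trees serialize to newick and reproduce additive input
distances exactly (tested to 1e-9 on random 4–12-leaf trees).

The number of lineages k is a **user input**: how many families a herd
tree shows is a result about the herd, not a rule, and published herd
analyses delimit lineages by inspection. A largest-gap heuristic over
internal branch lengths is available but never applied silently. Cutting
removes the longest edges (internal edges preferred, ties by insertion
order) greedily, skipping removals that do not split a leaf-bearing
component, until k lineages exist — this handles the k = leaf-count corner
an "internal edges only" rule cannot.

Sows join the lineage with the largest **mean** G to its boars (a maximum
rule is available); a sow whose maximum G over all boars falls below the
threshold (default 0.1, the usual "unrelated for mating purposes" cut)
forms a separate unrelated family. Lineage ties go to the lowest index.
Boar lineages are defined on a boars-only tree and extended to sows via G;
an all-individuals tree is also written for reporting.

## ROH detection and F_ROH

Detection follows the PLINK `--homozyg` sliding-window scheme with the
defaults: scanning window 50 SNPs; window "good" if ≤ 1 heterozygous and
≤ 1 missing call; a SNP is eligible if ≥ 5% of windows containing it are
good; runs of eligible SNPs split at inter-SNP gaps > 1 Mb; emitted
segments need ≥ 30 SNPs, ≥ 1 Mb, and ≥ 1 SNP per 1000 kb. A chromosome
shorter than the window degenerates to a single whole-chromosome window.

Two deliberate refinements beyond PLINK's window-only behavior:

* the het/missing caps are also enforced on the **final segment**; a
  candidate run that would exceed them is split left-to-right at the
  offending call (which is dropped), so no emitted segment ever contains
  two heterozygous calls — set `segment_level_caps=False` for strict
  window-level emulation;
* run ends are trimmed so every segment starts and ends on a homozygous
  non-missing call.

The detector is verified by exact segment-set equality against a literal
rule-by-rule oracle on 200 random small chromosomes. Class summaries use
half-open edges [1, 5), [5, 10), [10, ∞) Mb — a 5 Mb segment is "5~10",
a 10 Mb segment is ">10". Per-chromosome reporting uses the marker map's
maximum position as the chromosome length, not a build table.

`F_ROH = Σ L_ROH / L_auto` per individual, with the pig (Sscrofa 10.2)
autosomal length 2,450,713 kb as the default denominator; individuals
without segments contribute 0 to the population mean when the sample list
is supplied.

## Synthetic data

The generator emulates the study conditions end to end with exact ground
truth: an 8-family closed-nucleus pedigree (defaults 4 boars + 22 sows per
family per generation, 3 generations ≈ 208 genotyped animals), founder
haplotypes drawn per marker from a Uniform(0.05, 0.5) MAF distribution on
18 chromosomes of 136 Mb (≈ 2.45 Gb genome) with 500 markers each, and
gene dropping with Haldane recombination (Poisson crossovers at 1 cM/Mb,
no interference — chosen for exact Poisson math in tests). Ancestry is
tracked per transmitted haplotype, so true autozygous segments are exact
coalescences within the simulated pedigree — precisely the recent-base
quantity F_ROH estimates. A stated fraction of matings (default 0.25) are
forced between full or half sibs, planting pedigree inbreeding up to
~0.3; path-counting pedigree F is computed for every individual.
Genotyping missingness is injectable (default 0.02; genotyping error
default 0), so QC has work to do. A Balding–Nichols `founder_fst` option
differentiates family founder frequencies for family-recovery experiments;
0.25 is the "well-separated" setting at which recovery is robust.

What the generator does **not** emulate: ascertainment bias of array
content, genotype-intensity error models, mutation, selection, and
background LD older than the founder generation (founders are drawn in
linkage equilibrium; LD in the emitted data comes from pedigree structure
or from the Wright–Fisher generator's drift). Consequently passing
recovery tests demonstrates the estimators' correctness under their own
model assumptions, not robustness to chip ascertainment or deep
population history.

Problem sizes in the shipped tests (18×500 markers for the inbreeding
herd, 4×250 for Wright–Fisher Ne with 100 generations, 6×300 for family
recovery) were chosen as the smallest configurations at which the
recovery statistics are stable across seeds; all generators are
bit-reproducible given a seed.

## Degenerate inputs and numerical conventions

Monomorphic markers: HWE p = 1, MAF 0, undefined r² (excluded from LD
bins and flagged), skipped in G. All-missing markers: undefined MAF/He/Ho,
fail call-rate QC. Tie-breaks are deterministic everywhere (NJ pair
choice, lineage numbering by smallest leaf index, sow-assignment lowest
lineage). The exact-test tie comparison uses a 1e-12 relative tolerance so
equal-probability configurations are included on both sides. Distance-bin
edges are half-open; a pair exactly on an edge joins the bin whose lower
bound equals it.

## Known limitations

* Per-stage QC counts are order-sensitive by design and will not match
  logs from tools that filter in a different order.
* The headline Ne depends on the bin layout and the bp→Morgan map; only
  the trajectory is a stable product.
* IBS triangle inequality can fail under adversarial missingness
  patterns (pairwise-complete deletion); it is checked, not guaranteed.
* NJ is O(n³) and the pipeline's all-individuals tree is practical to a
  few hundred samples — the intended scale of a conservation herd.
* F_ROH sensitivity is bounded by marker density: at 3.7 SNPs/Mb a
  segment needs ≥ ~8 Mb to reach 30 SNPs, so short (old) autozygosity is
  systematically missed, as with any medium-density array.
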