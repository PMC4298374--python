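# Methods

## Problem setting

A single needle biopsy samples one region of a spatially heterogeneous
tumor. In clear-cell renal cell carcinoma (ccRCC), the prognostic tumor
suppressors *PBRM1*, *SETD2*, *BAP1* and *KDM5C* are frequently mutated in
only part of the tumor, so a single-site assessment can miss a mutation
that is present elsewhere. This package models the multi-region biopsy
design: several cores per tumor are sequenced on a five-gene panel
(*VHL* plus the four genes above), mutations are classified by their
regional distribution, per-tumor clonal trees are reconstructed, and the
number of cores needed to detect a mutation with a target certainty is
computed from a binomial sampling model.

## Variant inclusion filter

A raw call is analyzed when all of the following hold, in this order of
attribution for exclusion tallies:

1. **consequence** — missense, nonsense, or indel (frameshift/in-frame);
   synonymous and unclassified calls are excluded;
2. **depth** — total coverage at the site ≥ 10 reads;
3. **VAF** — alt reads / depth ≥ 5%; both thresholds are inclusive
   ("at least" semantics);
4. **dbSNP** — single-base substitutions present in the germline SNP
   database are excluded; indels are never dbSNP-filtered.

Each excluded call is charged to its *first* failing rule so tallies are
reproducible and partition the input exactly. An optional
`min_alt_reads` knob (default 0 = off) supports stricter QC for panels
where very low absolute read support is suspect. Filtering is idempotent,
and tightening any threshold can only shrink the retained set.

The 5% VAF rule is applied per core; each core is an independent biopsy
and no pooling across cores happens before filtering.

## Shared/nonshared classification and presence matrices

Within one tumor, a mutation is **shared** (truncal) when it is detected
in every core and **nonshared** (subclonal) when it is absent from at
least one core. Mutation identity for collapsing observations across
cores is the exact `chrom:pos:ref:alt` key, not the gene: one tumor can
carry two distinct mutations of the same gene in different cores, and
these remain separate matrix rows. Cohort summaries (mutation rates,
ubiquity) are gene-level: a patient or core is positive for a gene when
it carries at least one mutation of that gene. A core with no surviving
calls is kept as an all-zero column — a wild-type biopsy is evidence, not
missing data.

## Clonal trees (perfect phylogeny)

The clonal model is a perfect phylogeny on binary characters: every
mutation arises exactly once, is never lost, and the ancestral state is
fully wild-type. Under this model a single rooted tree fitting all cores
exists iff the mutations' region-sets are pairwise nested or disjoint (a
laminar family); `check_compatibility` returns every overlapping-but-
unnested pair, and `build_clone_tree` refuses incompatible matrices with
that conflict list rather than silently repairing them.

Construction orders region-sets by containment: all-core mutations form
the trunk; each maximal set under containment opens a branch; every core
attaches as a leaf at the smallest region-set containing it, so the
mutations accumulated along its root path equal its observed mutations.
Numerical/structural conventions:

* trunk mutations are mutually unordered and are carried as a set on the
  trunk edge, printed canonically (*VHL*, *PBRM1*, *SETD2*, *BAP1*,
  *KDM5C*, then alphabetically, then by variant key);
* nonshared mutations with identical region-sets are indistinguishable by
  presence data and collapse onto one edge;
* child branches are ordered by their earliest-declared region, making
  rendering deterministic;
* single-region tumors are degenerate but legal: their only mutation
  state is "shared".

Each tumor is assigned one of five branching categories: a single shared
mutation only, multiple shared only, shared + nonshared, nonshared only,
or no mutations. The categories partition any cohort.

Serialization is annotated Newick (leaves = region ids; per-node comments
carry edge mutations, and the root comment carries the patient id and the
region declaration order, making parse → render lossless) and Graphviz
DOT (one node per clone, one box per region).

## Intratumor prevalence and biopsy power

The intratumor prevalence `p` of a gene is estimated by pooling biopsies
across mutation-positive patients:

    p̂ = (# positive biopsies) / (# biopsies of patients with ≥ 1 positive biopsy)

Patients with no positive biopsy are assumed to truly lack the mutation
and are excluded from numerator and denominator. The estimator is pooled,
not per-patient-averaged, and a tumor with two distinct same-gene
mutations contributes once per positive biopsy.

Given `p` and assuming biopsies are independent and uniformly placed, the
probability that at least one of `n` biopsies detects the mutation is

    P(n) = 1 − (1 − p)^n.

`min_biopsies(p, t)` returns the smallest `n` with `P(n) ≥ t` (the target
is inclusive; the closed form `ceil(log(1−t)/log(1−p))` is corrected by a
local search against float edge cases and always agrees with linear
search). For a gene panel the answer is the maximum over genes, so every
gene individually reaches the target. With the panel prevalences
{PBRM1 0.75, SETD2 0.70, BAP1 0.58, KDM5C 0.55} and a 90% target the
panel answer is 3 biopsies; at 41% prevalence (independent-cohort BAP1) a
single gene needs 5.

One documented edge: at 53% prevalence, `1 − 0.47³ = 0.896`, which is
colloquially "90% with three samples" but falls short of the inclusive
target; the exact solver returns 4. The package reports the exact answer
and leaves the rounding to the caller (`P(3)` rounds to 90% at 5-point
precision).

**Estimator bias.** Excluding all-negative patients truncates the
binomial at zero, so the estimator's expectation is `p / (1 − (1−p)^n)`,
an upward bias of `p(1−p)^n / (1 − (1−p)^n)` for `n` biopsies per
patient. At `n = 4` the bias is ≈ 0.016 at `p = 0.6` and ≤ 0.01 for
`p ≥ 0.65`; it is a property of the estimator's exclusion rule, not an
implementation artifact. The test suite therefore validates two things
separately: (i) *recovery* — `|p̂ − p| < 0.02` on 2000 simulated mutant
patients × 4 biopsies at `p ∈ {0.70, 0.80, 0.90, 0.95}`, the regime where
truncation is negligible relative to the recovery budget; and (ii) the
*exact conditional mean* — at low prevalence (`p = 0.3`), `p̂` matches
`p/(1−(1−p)^n)` within 3 standard errors of the truncated-binomial
variance, which quantifies the cost of the "undetected ⇒ absent"
assumption.

## Synthetic cohort generator

The generator emulates the study design, not a tumor-growth process:

* **cohort**: 14 patients, 3–5 cores each (uniform), five-gene panel;
* **clonal structure**: per gene, a truncal mutation with the gene's
  truncal rate, else a subclonal mutation with its subclonal rate.
  Default rates (VHL 0.64 truncal / 0 subclonal; PBRM1 0.21/0.14;
  SETD2 0.07/0.14; BAP1 0.07/0.14; KDM5C 0.07/0.21) reproduce the
  qualitative cohort structure: VHL common and always ubiquitous, the
  chromatin modulators rarer and mostly subclonal. Subclonal region-sets
  are drawn from one random hierarchical partition of the cores, so every
  tumor's truth is laminar by construction and a perfect phylogeny always
  exists. An optional `double_hit_rate` emits two distinct same-gene
  mutations in disjoint region-sets (the double-BAP1 pattern);
* **read counts**: each core is a pure single-clone sample; a carried
  mutation's alt count is Binomial(depth, 0.5 × purity) — the
  heterozygous-diploid model with default purity 0.7 — and depth is
  Poisson around 950× (the panel's median coverage), floored at 1. Cores
  outside a mutation's region-set draw alt reads at the sequencing error
  rate (default 10⁻³ per base). A call row is emitted only when at least
  one alt read is observed;
* **decoys**: germline SNPs (dbSNP-flagged SNVs at ~50% VAF in every core
  of their patient; Poisson mean 1 per patient), synonymous somatic calls
  (mean 0.5 per patient), and sub-threshold artifacts (missense with VAF
  forced strictly below 5%; mean 0.5 per biopsy). Every decoy violates at
  least one inclusion rule by construction, so a correct filter removes
  all of them while keeping every true call that meets depth and VAF.

What the generator does **not** model: copy-number alterations (so the
heterozygous-diploid VAF is an idealization), clonal admixture within a
core (each core is a pure clone — the presence/absence abstraction),
spatially correlated biopsy placement, and read-level artifacts beyond a
uniform error rate. Passing recovery tests therefore demonstrate the
pipeline's correctness under the stated abstraction, not robustness to
copy-number noise or heavy admixture in real tumors.

## Validation problem sizes

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to each tolerance: 10⁵ draws per cell for the binomial-power
oracle (3-SE criterion), 2000 patients × 4 biopsies for estimator
recovery (SE ≈ 0.005 against a 0.02 budget), 500 random laminar and 500
non-laminar matrices (≤ 6 mutations × ≤ 5 regions) for the
perfect-phylogeny round trip, and a 14-tumor noise-free cohort for exact
end-to-end recovery. The brute-force tree-existence oracle enumerates all
rooted clone trees on up to one node per distinct region-set plus a root,
which is exhaustive after contracting non-target nodes.

## Known limitations

* Prevalence is operationalized as "fraction of biopsies", a surrogate
  for fraction of tumor volume; with 3–5 cores per tumor the pooled
  estimate is coarse and the truncation bias above applies.
* The tree model cannot order trunk mutations or separate equal
  region-sets; branch lengths and clone fractions are out of scope.
* Incompatible matrices (possible with noisy real data, e.g. a shared
  mutation dropped by coverage in one core) are refused, not repaired;
  callers must relax the filter or drop conflicting rows explicitly.
* Sub-regions of a physically single core (distinct mutations of one gene
  found in one core's halves) are treated as additional declared regions
  supplied by the caller, not inferred.
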