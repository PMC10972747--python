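# Methods

## Problem and scope

`ccfevo` reconstructs the clonal composition and phylogeny of a tumour
from two or more sequenced samples of the same patient (different sites,
or different time points under therapy). Inputs are per-sample somatic
mutation tables with read-level evidence, allele-specific copy-number
segments, and per-sample purity/ploidy estimates; variant calling,
copy-number segmentation and purity estimation themselves are upstream
of this package. Outputs are per-mutation cancer cell fractions (CCFs),
an audited filter report, CCF clusters per sample pair, a labelled clone
tree with a phylogeny class, signature exposures for clonal and
subclonal mutation subsets, and ploidy/whole-genome-doubling calls.

## Cancer cell fractions

A mutation present on `m` of `CN_t` tumour copies, in a sample of purity
`p` contaminated by normal cells of copy number `CN_n` (2 on autosomes;
1 on male sex chromosomes if configured), has expected allele fraction
under clonality

    E[VAF] = m p / (p CN_t + (1 − p) CN_n),

and `CCF = VAF / E[VAF]`. Assumptions: the segment's copy-number state
is clonal within the sample (within-sample subclonal CN segments are
annotated and their apparently clonal mutations excluded from
clustering); read sampling is binomial; purity is known. The
multiplicity `m` is not identifiable per site, so the default is the
`m ∈ {1..major_cn}` minimising `|CCF − 1|` (clonality as the null);
`enumerate_multiplicities` exposes the feasible set and the pipeline
re-evaluates it when clusters conflict with phylogenetic rules (a
cluster centred well above CCF 1 has its members' CCFs moved to the next
multiplicity solution and clustering is re-run once). CCFs are not
truncated at 1: the clustering must see super-clonal noise mass.
Zero-depth records, positions outside the segmentation and homozygously
deleted sites are flagged, never silently dropped.

## Filter battery (fixed order)

1. **Artifact filters per sample.** Calls with VAF < 0.2 fail if the
   forward–reverse strand score `1 − |f − r|/(f + r)` is below 0.2, or
   if `min(C_tumour, C_normal) × VAF < rc` (default rc = 10; per-sample
   overrides supported). SNMs strictly closer than 10 bp to any indel
   call fail. Calls in the outer 1.5% of the chromosome, in centromeric
   windows (bundled hg19 table), or with > 10% low-MAPQ reads are
   excluded from phylogeny.
2. **Unified list and rescue.** Mutation calls from all samples are
   unified; a call failing the stringent criteria in one sample is
   reintroduced there (with its observed VAF) if it passes all stringent
   criteria in another sample and has at least one variant read locally.
   Rescue never removes calls and is idempotent.
3. **LOH conflicts.** On the unified segmentation (union of all samples'
   breakpoints, each unified segment carrying every sample's
   allele-specific state), a mutation on a segment with LOH in some but
   not all samples, observed only (CCF < 0.2) in samples lacking the
   LOH, is excluded as ambiguous — its absence may reflect the deletion
   rather than true privacy. Segments whose within-sample subclonal CN
   state includes an LOH clone exclude their mutations entirely.
4. **Power trim.** The CCF increment of a single mutated read,
   `(1/depth)/E[VAF]`, is modelled per sample as log-normal; mutations
   beyond z = 1.96 (2.5% per tail) in either sample are cut. The
   log-normal is fitted robustly (median, MAD-derived sigma) so the trim
   is nearly stable under re-application (~2% on a second pass instead
   of the nominal 5%); with fewer than 10 mutations the trim is skipped
   with a warning.
5. **Private-mutation test.** For a mutation called in exactly one
   sample, the null is that it is shared at the observed allele fraction
   `v`; the probability of seeing fewer than `k` variant reads (default
   k = 1) among the other sample's `D` reads is `P(X < k)`,
   `X ~ Binomial(D, v)` (`(1 − v)^D` at k = 1). Benjamini–Hochberg at
   5% across the pair's candidates; rejected calls are truly private,
   everything else (including zero-coverage sites) is excluded as
   ambiguous. BH is applied per patient per sample pair, the unit on
   which the test is defined.

## Two-dimensional CCF clustering

Retained mutations are binned into a 2D histogram (bin width 0.05,
range [0, 1.5]² so super-clonal mass stays visible; private mutations
accumulate on the axes). The histogram is smoothed with a tensor-product
penalized smoothing spline: a discrete second-difference (P-spline /
Whittaker) roughness penalty along both axes with one common parameter
λ. The penalty eigendecomposition gives the exact hat-matrix trace, so λ
is selected by generalised cross-validation; the GCV denominator
inflates the model degrees of freedom by γ = 2 because plain GCV
systematically undersmooths sparse Poisson count grids. Strict
8-neighbour local maxima above 5% of the surface maximum are cluster
centres (reported at bin centres); peaks on an axis are private
clusters with the off-axis coordinate snapped to 0.

Assignment is nearest-centre by Euclidean distance under the kind
constraint (shared mutations only to shared clusters, private mutations
only to their axis), ties toward the larger summed-CCF centre then
lexicographic label. Private mutations with no axis centre seed one at
their median CCF if at least four exist. Clusters below the four-
mutation minimum are dissolved and members re-assigned.

**Variance-aware refinement.** Each mutation's CCF carries a known
binomial sampling variance `VAF(1 − VAF)/depth/E[VAF]²`. A single
clone's cluster scatters within those variances; two merged clones are
overdispersed. Each cluster is therefore tested with a chi-square
statistic on the variance-weighted residuals (level 1e−4); flagged
clusters are split by a two-component EM with per-mutation variances,
splits accepted only if both halves hold ≥ 4 mutations and separate by
≥ 0.1. Symmetrically, same-kind clusters whose union passes the test
are merged (smoothing can fragment a broad clonal cloud). This is the
package's realisation of noise deconvolution from the CCF error
estimates; on design simulations no pure cluster (0/161) was falsely
split. Clustering is deterministic for fixed input and configuration.

## Clone tree, classes, composition

Cluster centres are clone CCFs. Clusters with every coordinate within
ε = 0.1 of 1 merge into the most recent common ancestor C0 (they are
indistinguishable at tolerance); lacking one, the highest shared
cluster is promoted with a warning flag. All rooted trees over the
clusters are enumerated under ancestry monotonicity (child ≤ parent + ε
per sample) and the sum rule (sibling sum ≤ parent + ε per sample); the
tree with the fewest branching events wins (maximum parsimony — linear
evolution preferred over branched), remaining ties broken by attaching
each clone to its admissible parent of smallest CCF (deepest
attachment), then lexicographically. Minimal branching is applied
globally across samples. For large cluster sets the enumeration is
restricted to parents earlier in the decreasing-CCF order, and beyond
that a greedy deepest-attachment fallback is used. If no admissible tree
exists, the violated constraints are reported and multiplicity
re-evaluation is attempted once. Clones are labelled C0, C1, … in
depth-first order with larger-CCF children first.

Classes: A single clone; B chain of two; C chain of three or more; D one
branching event below C0; E one branching at C0; F at least two
branching events (a branching event = a node with ≥ 2 children).
Per-sample composition reports each clone's CCF and terminal fraction
(CCF minus children's summed CCF, floored at 0). The relapse-seed call
returns the deepest clone, present above ε in both a pre and a post
sample, that is ancestral to every terminal clone of the post sample.

Patients with more than two samples are analysed pairwise; the
representative pair maximises (number of subclones, then subclonal
mutations). The patient-level tree groups mutations by their tuple of
pairwise cluster labels (absence from both samples of a pair is an
informative token; mutations excluded anywhere are dropped), takes
per-sample median CCFs as group centres, discards groups undetectable
in every sample, agglomerates groups with the overdispersion-merge rule,
and reconstructs the tree over the n-sample centres. Class F requires
three or more samples in practice: from one pair, flattened
single-branching alternatives of a two-branching truth are admissible,
so pairwise analyses top out at class E.

## Signatures

SNMs are tallied into the standard 96 trinucleotide channels
(pyrimidine-strand convention; contexts from an input column). Exposures
are non-negative least squares against a COSMIC-layout catalogue;
backward selection repeatedly removes the signature whose removal
increases the cost least, while the refitted cost stays within 2%
(relative) of the full fit. Cohort prevalence keeps signatures active in
≥ 5 cases; the platinum signatures SBS31/SBS35 are force-included for
post-treatment subclonal fits. Eligibility: clonal fits need > 300
mutations, subclonal fits > 20 (both strict); skipped subsets are
reported. Indel summary ratios (indel/substitution, deletion/insertion)
return missing — not 0 — on empty denominators. The bundled catalogue
(`synthetic_catalog`) is a deterministic synthetic stand-in (sparse
Dirichlet profiles seeded per name); real analyses should load actual
COSMIC files, which the reader accepts in the same layout.

## Ploidy and whole-genome doubling

High ploidy is mean copy number ≥ 2.8 (inclusive). The LOH fraction is
the length-weighted fraction of autosomal segments with minor copy
number 0 (sex chromosomes excluded: hemizygosity confound). The WGD rule
— high ploidy and `ploidy > 2.9 − 2 × LOH fraction` — is a documented
reconstruction of ploidy/LOH-based doubling assignment and is fully
configurable; acquired WGD between time-ordered samples is
`post.wgd and not pre.wgd` (doubling loss is not modelled).

## Damage classification

Missense mutations (full-length protein) are `point_missense`; nonsense,
splice, frameshift, large in-frame indels (≥ 3 codons, configurable) and
structural events are `gene_damaging`; anything else (e.g. synonymous)
is explicitly `unclassified`. Consequence annotation is an input.

## Synthetic-data generator

The generator emulates the targeted study conditions: 2–3 samples per
patient, purity 0.85, exome-like depth (Poisson around 127× by default;
recovery experiments use 120×), ploidy ~2.5 via single-copy gains on
part of the genome, mutation loads log-uniform in 50–500 (clonal) and
10–200 (subclonal; recovery experiments use 50–200 so every clone is
clusterable), clone CCF matrices obeying the sum rule by construction,
and per-clone trinucleotide spectra drawn from configurable signature
mixtures. Optional artifact channels add FFPE-like strand-biased low-AF
noise calls, indels adjacent to real SNMs, and sample-specific LOH that
deletes minor-allele mutations. Reads are binomial at
`E[VAF] × CCF`; strand counts split binomially at 1/2. Fixed seeds give
byte-identical tables.

Target-class draws are rejection-sampled for *identifiability*: the
exact clone CCFs must reconstruct to the true topology under the
pipeline's own ε/parsimony rules, since a configuration whose flattened
tree is admissible with fewer branchings is unrecoverable by any method
preferring linear evolution. Class F uses a structured draw — the
internal branching clone is near-fixated (~0.8) in its children's home
samples so the sum rule blocks flattening onto C0 — because generic
stick-breaking almost never yields such configurations. Branch-point
children are anchored to distinct "home" samples (leaves become private,
internal children keep presence everywhere); entries below 0.15 are
snapped to 0 and draws are rejected unless clones are pairwise separated
by ≥ 0.25 and every nonzero CCF is ≥ 0.2.

What the generator does *not* emulate: mapping artifacts with genuine
positional structure, subclonal copy-number evolution, germline
contamination, mouse-read contamination of xenograft samples,
overdispersed (beta-binomial) read counts, and purity estimation error.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated noise model, not robustness to
every failure mode of real exome data.

## Validation experiments (problem sizes)

`ccfevo.experiments` fixes the scales: the global-null false-discovery
simulation uses 500 replicates × 2,000 shared clonal mutations at depth
Poisson(120) and purity 0.85; class recovery runs 50 seeds per class
A–F (two samples, three for F) at the same conditions with clone
separation ≥ 0.25 and ≥ 50 mutations per clone; the tree oracle check
enumerates all admissible trees for 200 random configurations of up to
six clusters; exposure recovery uses 50 seeds of 600-mutation
catalogues. These sizes keep each experiment in the minutes range on a
single core while leaving the Monte-Carlo error well below the margins
being asserted.

## Known limitations

- Clones separated by less than ~2 standard errors of their CCFs cannot
  be separated at realistic depth; the variance-aware split extends but
  does not abolish this resolution limit.
- Multiplicity selection by `argmin |CCF − 1|` misassigns mutations in a
  narrow VAF window on polyploid segments, leaving small satellite mass
  between multiplicity solutions.
- The sum-rule tolerance ε = 0.1 trades false conflicts against false
  admissibility; with very noisy centres, flattened trees can become
  admissible and parsimony will choose them.
- Pairwise analyses cannot resolve two branching events (class F needs
  ≥ 3 samples).
- The WGD decision boundary and the per-read power-score formula are
  reconstructions; both are configurable.
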