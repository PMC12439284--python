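# Methods

`kinlagoon` reconstructs fine-scale kinship structure in a single continuous
population genotyped at codominant microsatellite loci: pairwise relatedness
by maximum likelihood with null-allele handling, family delineation by
average-linkage clustering of the relatedness matrix, and rank-based tests of
whether genetic relatives are spatially aggregated. This note records the
models, the defaults and why they were chosen, and what the synthetic
validation data do and do not establish.

## Pairwise relatedness model

For a non-inbred dyad, the genotype pair at an autosomal locus depends only
on the IBD-mode probabilities k = (k0, k1, k2) — the probabilities that the
two individuals share 0, 1 or 2 alleles identical by descent. Relatedness is

    r = k2 + k1 / 2 .

Per locus we evaluate the three conditional probabilities of the observed
genotype pair, (a, b, c) = P(G1, G2 | mode 0, 1, 2), under Hardy–Weinberg
proportions at the estimated allele frequencies:

- mode 0: the genotypes are independent, a = P(G1) P(G2);
- mode 2: the true genotypes are identical, c = P(G1) · 1[G1 = G2];
- mode 1: generative sum over the shared allele s (a population draw), with
  each genotype's remaining allele forced to its other observed allele.

Loci are treated as unlinked, so the multilocus likelihood is

    L(k) = prod_l ( k0 a_l + k1 b_l + k2 c_l ) ,

maximised over the full probability simplex (no triangle constraint
k1² ≥ 4 k0 k2; estimates for truly unrelated pairs therefore pile up at the
k0 = 1 boundary, giving the familiar small positive mean r̂ for unrelated
dyads). The maximiser is found by EM: starting from the interior point
(1/3, 1/3, 1/3), each update replaces k_m by the mean posterior probability
of mode m across typed loci. This is a standard mixture EM, monotone in
L(k); iteration stops when no component moves by more than 1e-8 (cap 2000
iterations). A dense grid search over the simplex (step 0.01) is exposed as
an independent cross-check and agrees with the EM route to within 0.02 in r
on simulated dyads. Per-locus (a, b, c) triples are computed once per unique
genotype pair per locus and cached, and the per-locus triple is rescaled by
its maximum (the maximiser of L is invariant to per-locus scaling), which
keeps the computation linear in the number of pairs and numerically stable.

Pairs with no shared typed locus get an undefined r (NaN); pairs sharing
fewer than 5 typed loci (configurable) are flagged low-confidence but still
estimated, since the upstream analysis imposed no minimum.

## Null alleles

Microsatellite null alleles make visible/null heterozygotes look like
homozygotes and null homozygotes look like missing data. The package models
one designated null allele per locus:

1. **Frequency estimation.** An EM estimator treats each apparent homozygote
   AA as a mixture of the true homozygote (posterior weight
   p_A / (p_A + 2 p_0)) and the A/null heterozygote, and renormalises
   expected allele counts. This maximises the HWE likelihood of the apparent
   genotypes; a configurable share of missing cells can be included as null
   homozygotes (default 0: technical dropout and null homozygosity are not
   distinguishable, and the homozygote excess alone identifies p_0). The EM
   solution is pinned against a dense grid search of the same likelihood in
   the test suite.
2. **Dyad likelihoods.** Each observed apparent genotype is marginalised over
   its compatible true genotypes (an apparent homozygote may be a
   visible-by-null heterozygote) before conditioning on the IBD mode, using
   the full frequency vector including the null.

## Duplicate samples

Pairs with r̂ above 0.95 are treated as repeat samples of one individual.
Above-threshold pairs define a graph; each connected component keeps exactly
one member — the one with fewest missing loci, ties broken by smallest id —
so chains of near-identical samples collapse to a single survivor.

## Family delineation

The de-duplicated relatedness matrix is transformed to the distance 1 − r
(undefined pairs are placed at distance 1, i.e. treated as unrelated) and
clustered by UPGMA. Every fusion node N joining clusters C1 and C2 of sizes
n1 and n2 is scored with the cross-cluster mean relatedness

    rbar_N = (1 / (n1 n2)) * sum_{i in C1} sum_{j in C2} r_ij ,

deliberately the mean over cross-pairs only (the index sets of the defining
double sum), not over all pairs inside the node; the all-pairs mean is also
computed as a diagnostic. Families are extracted top-down from the root: a
node whose rbar_N reaches the threshold (default 0.25, the theoretical
half-sib kinship) emits its entire leaf set as one family and is not
descended into — the largest qualifying clusters, regardless of what deeper
nodes would do. Leaves never form families alone, so the output is a
partition into families of size ≥ 2 and singletons. Raising the threshold
can only shrink or split families (tested property).

UPGMA heights are exact running averages via scipy's average-linkage
implementation; merge order and heights are pinned against a naive O(n³)
re-averaging oracle on 200 random matrices. Ties in the input distances are
broken by the library's deterministic ordering; on continuous relatedness
values ties do not occur.

## Spatial analysis

Geographic distances are great-circle (haversine) distances on a sphere of
mean radius 6371.0088 km. Unordered pairs are binned into relatedness
classes; the default edges {0, 0.0625, 0.125, 0.25, 0.5, 0.6, 0.75, 1}
include the recognised kinship cut points (1/16, 1/8, 1/4, 1/2) plus 0.6 and
0.75, with half-open bins and the last bin closed. Because the unrelated
mass dwarfs the high-relatedness classes, each of R = 1000 iterations
subsamples every class **without replacement** to the size of the smallest
class before running a tie-corrected Kruskal–Wallis test on pair distances.
(Resampling each class to its own size with replacement would leave the
smallest class unchanged every iteration; the stated goal of the procedure
is balance, so subsampling is the default and with-replacement is a flag.)
The result is summarised by the median p and the 2.5–97.5 percentile
interval; the effect is called robustly significant when the median p is
below 0.05 and the interval does not cross 0.05. When the omnibus test is
significant, Dunn's z-tests (joint ranks, tie-corrected variance, two-sided,
Bonferroni-multiplied by the number of class pairs) are run on the same
balanced subsamples and summarised by the elementwise median adjusted p —
the procedure's source did not specify the post hoc sample, and the median
over balanced subsamples keeps the post hoc power matched to the omnibus
test.

Pairs sharing an individual are not independent observations. As in the
standard versions of this design, the pair is nevertheless the unit of
analysis; this is a documented caveat, not corrected.

The family-dispersion permutation test asks whether family members are
spatially closer than chance: the observed statistic is the mean
within-family pair distance pooled over families, and the null permutes the
multiset of family labels (including singleton non-labels) across
individuals; the one-sided p (families more compact) includes the observed
arrangement in the tally.

## Synthetic data generator

The generator produces what the analysis assumes: founders drawn from HWE at
Dirichlet-distributed allele frequencies on a repeat-motif ladder, offspring
receiving one uniformly chosen allele per parent, families (full-sib,
half-sib, parent–offspring) embedded in an unrelated background, a
segregating null allele per locus, independent per-cell missingness,
duplicated samples (same true genotype and coordinates, independent
missingness), and coordinates in a ~10 × 10 km lagoon-scale arena with
family members scattered isotropically (scale `kin_sigma_km`) around a
uniform family anchor.

Defaults encode the study conditions: 21 loci with 4–21 alleles, Dirichlet
concentration 0.265 per allele (solving E[1 − Σp²] ≈ 0.67 for allele counts
uniform on 4..21, the observed mean expected heterozygosity), null-allele
and missingness rates 0.05 each (no empirical rates are reported; these are
package choices at the low end of what microsatellite panels show). Depth
and shell width are drawn to match the reported field distributions
(depth ≈ N(4.9, 7.4²) clipped to [0, 26] m; width increasing weakly with
depth around 24 cm).

What the generator does **not** emulate: genotyping error and allele
miscalling, mutation, linkage, inbreeding, age structure, multi-generation
pedigrees, and uneven spatial sampling effort. Passing tests therefore show
that the estimators and the extraction rule behave correctly when the
model's assumptions hold; they do not bound the additional noise real panels
carry (scoring error in particular inflates apparent relatedness variance).

## Validation scenarios and problem sizes

- **Estimator calibration**: 500 dyads per relationship class at 21 loci,
  mean He ≈ 0.67. Mean r̂ lands within ±0.05 of the theoretical 0.25 (HS) and
  0.5 (FS, PO), unrelated mean in [0, 0.08], and RMSE shrinks from 7 to 21
  loci.
- **Family recovery**: 50 planted full-sib families of 5 among 200 unrelated
  individuals; extraction at 0.25 reaches an adjusted Rand index above 0.8
  against the planted pedigree (the seed-pinned value is a regression test).
- **Spatial signal**: a population of 30 half-sib families of 4 and 70
  full-sib pairs scattered at arena scale (kin_sigma 3 km — i.e. effectively
  no family-level aggregation, matching the analysed system, where family
  membership showed no spatial pattern) plus 180 unrelated individuals and
  12 co-located repeat captures, which populate the extreme class r > 0.75.
  The balanced bootstrap calls the class effect robustly significant, Dunn
  separates the top class from every other class, and all lower classes
  remain mutually indistinguishable. The repeat captures are retained in the
  pair set for this scenario: they are the mechanism that gives the extreme
  class its distinct spatial signature. With tight family aggregation
  instead, the 0.6–0.75 class is full-sib-dominated and exactly as close
  spatially as the top class, and no rank statistic can single the top class
  out — the observed pattern requires dispersed families.

These sizes keep the full validation suite within a few minutes on one CPU;
the estimator and pipeline code paths are identical at full survey scale
(a 1205-individual matrix is ~725k pairs, well within the cached, vectorised
EM's reach).

## Numerical choices and degenerate inputs

- EM over k: fixed interior start, tol 1e-8 on the max component change,
  2000-iteration cap; per-locus triple rescaling; impossible pairs (zero
  likelihood everywhere) report r = 0 with a warning.
- Frequency EM: tol 1e-6, 1000 iterations, warning + last iterate on
  non-convergence; estimates renormalised against float drift.
- Monomorphic loci: He = 0, HWE not testable (None), F_IS undefined and
  excluded from multilocus sums.
- Monte-Carlo exact HWE test: conditional on observed allele counts, tally
  includes the observed table (p > 0), float-slack 1e-9 on the log-probability
  comparison so ties count as at-least-as-extreme.
- Holm adjustment: step-down with cumulative-maximum monotonicity, capped at
  1, returned in input order.
- All stochastic stages take explicit seeds; identical seeds give
  byte-identical genotype tables and identical bootstrap p-vectors.

## Known limitations

- The dyad model assumes non-inbred individuals and an outbred reference
  population (observed multilocus F_IS in simulated sib-structured samples is
  positive simply because relatives share alleles).
- Null-allele frequencies estimated from homozygote excess absorb any other
  source of heterozygote deficit (Wahlund effect, scoring bias).
- Family extraction is a hard partition; a half-sib chain linking two true
  families can merge them, and low-information pairs can attach singletons
  to a family.
- The balanced bootstrap controls class-size imbalance but not the
  non-independence of pairs sharing members.
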