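# kinlagoon

Kinship structure of a continuous marine population from codominant
microsatellite genotypes: maximum-likelihood pairwise relatedness with
null-allele handling, family delineation by UPGMA clustering of the
relatedness matrix, and rank-based tests of whether relatives are spatially
aggregated. Written for population geneticists working on benthic
invertebrates (the motivating system is a fan mussel population sampled
across a Pacific lagoon), but applicable to any single-population
multilocus codominant dataset with per-individual coordinates.

## The method

For each pair of individuals the IBD-mode probabilities k = (k0, k1, k2)
(sharing 0/1/2 alleles identical by descent) are estimated by maximising the
multilocus likelihood

    L(k) = prod_l ( k0 a_l + k1 b_l + k2 c_l ),      r̂ = k2 + k1/2

where (a_l, b_l, c_l) are the conditional probabilities of the observed
genotype pair at locus l under Hardy–Weinberg proportions, with observed
apparent homozygotes marginalised over possible null-allele carriers
(per-locus null frequencies estimated by EM from homozygote excess). Pairs
with r̂ > 0.95 are collapsed as repeat samples. The matrix 1 − r̂ is
clustered by UPGMA, and every fusion node N merging clusters C1, C2 (sizes
n1, n2) is scored with the cross-cluster mean relatedness

    r̄_N = (1 / (n1 n2)) Σ_{i∈C1} Σ_{j∈C2} r_ij .

Families are the largest clusters with r̄_N ≥ 0.25 (the theoretical
half-sib kinship), extracted top-down. Finally, pair distances
(great-circle, km) are compared across relatedness classes with a balanced
bootstrap (each class subsampled to the smallest class, R = 1000
Kruskal–Wallis tests summarised by median p and 95% percentile interval)
and Dunn's Bonferroni-adjusted post hoc tests; a permutation test asks
whether family members are closer together than random label assignments.

A synthetic pedigree-genotype generator (families planted in an unrelated
background, segregating null alleles, missingness, duplicated samples,
spatially anchored families) makes the whole pipeline verifiable without
field data; see `docs/methods.md` for models, defaults and caveats.

## Worked example

The shipped config simulates a lagoon population (20 full-sib families of 5,
10 half-sib families of 4, 120 unrelated individuals, 5 duplicated samples,
21 loci, He ≈ 0.67) and runs every stage:

```bash
kinlagoon run --config configs/demo_simulated.yaml
```

The JSON report printed at the end contains, among others:

```
"filter":       {"retained": 265, "removed": 0}
"diversity":    {"mean_Na": 8.90, "mean_Ho": 0.601, "mean_He": 0.674,
                 "multilocus_Fis": 0.111}
"relatedness":  {"n_pairs": 34980, "pct_r_above_025": 2.34,
                 "pct_r_above_05": 0.363, "n_r_above_075": 9}
"deduplicate":  {"duplicate_pairs": 5, "retained": 260}
"families":     {"n_families": 76, "largest_family": 5,
                 "pct_in_families": 85.4, "n_families_gt3": 22,
                 "mean_within_family_r": 0.398}
"spatial":      {"median_p": 0.0108, "p_ci": [0.0018, 0.1120],
                 "significant": false,
                 "dispersion_observed_km": 2.46,
                 "dispersion_null_km": 5.40, "dispersion_p": 0.001}
```

Reading: all 265 simulated individuals pass the 75% amplification filter;
the panel shows ~8.9 alleles per locus and expected heterozygosity 0.674;
of 34,980 pairwise comparisons only 2.3% exceed r = 0.25; all 5 planted
duplicate pairs are found at r > 0.95 and collapsed; family extraction at
r̄_N ≥ 0.25 recovers 76 families covering 85% of individuals (the planted
sibships plus small spurious pairs, as expected at this marker count); the
balanced Kruskal–Wallis is not robustly significant by the median-p/CI rule
(the interval crosses 0.05), while the family-dispersion permutation test
detects the planted kin aggregation (observed within-family distance 2.5 km
vs 5.4 km under permuted labels, p = 0.001, kin scatter 1 km).

Each stage is also a standalone subcommand (`simulate`, `filter`,
`diversity`, `relatedness`, `families`, `spatial`, `ranks`) writing
TSV/CSV/Newick intermediates, and everything is importable as a library
(`import kinlagoon`).

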