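# Methods

`nestkin` infers alternative breeding strategies in nesting ducks —
extra-pair copulation (EPC), conspecific nest parasitism, renesting and
cross-nest shared fathers — from three inputs: diploid biallelic SNP
genotypes (VCF), aligned mtDNA control-region sequences (FASTA), and a
nest table mapping samples to nests and roles.  This note documents the
models, the estimators, the synthetic-data generator that stands in for
field data, the numerical choices, and the known limits of what the
tests demonstrate.

## Evidence model

Two independent channels distinguish the strategies:

* **Maternal channel.** mtDNA is maternally inherited verbatim, so an
  egg whose haplotype differs from the incubating hen's cannot be hers.
  Nuclear maternity is checked with the opposing-homozygote count: a
  true mother and offspring can never be homozygous for different
  alleles at an error-free site, while an unrelated hen-egg pair is
  opposing-homozygous at a rate of `2 p^2 (1-p)^2` per site (~12% per
  site at p = 0.5), orders of magnitude above any plausible genotyping
  error.  An egg is called *parasitic* only when **both** channels point
  away from the resident hen; a single foreign-looking channel yields
  *ambiguous*, never a silent call, because the two channels can
  genuinely disagree (a parasitizing hen may share the host's haplotype,
  and low-information genotypes can fail maternity spuriously).

* **Paternal channel.** Within a clutch of maternity-verified eggs,
  full sibs share both parents and half sibs share only the mother, so
  the clutch partitions into paternal sib-groups.  A nest whose resident
  eggs span two or more paternal lineages is multi-paternal (EPC).

## Estimators

**Relatedness (Ajk).** The unadjusted Yang et al. estimator, as
implemented by VCFtools `--relatedness`: for samples j, k and sites i
with alt-allele frequency `p_i`,

    A_jk = (1/S) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with the one-sample form on the diagonal.  Frequencies come from
whatever sample set the caller passes (the pipeline uses the focal
hens+eggs set, matching the within-dataset convention of the original
analysis).  Expected values: ~0 unrelated, ~0.25 half-sib, ~0.5
first-degree.  Two consequences of within-dataset frequencies are worth
knowing: all pairwise values shift down by roughly `-1/(n_eff - 1)`
(with n_eff the number of founder lineages), so in a ~20-family focal
set full-sib dyads centre near 0.45 rather than 0.50; and values are
reported untruncated, so unrelated pairs scatter below zero.  Family
clusters are single-linkage components of the `A_jk > 0.35` graph —
0.35 sits between the half-sib and first-degree expectations.

**Supervised ancestry.**  Each focal bird is analysed one at a time
against the three labelled panels (black duck ABDU, wild mallard WMA,
game-farm mallard GFM), never jointly with its relatives — joint
estimation is confounded when the focal set is a web of families.  Two
estimators are provided:

* `supervised_q`: the ancestry vector q maximises the binomial
  admixture likelihood with panel frequencies held fixed, by EM from
  (1/3, 1/3, 1/3), stopping at a log-likelihood change < 1e-4 or 2,000
  iterations.  This is the cleanest contract (the estimate depends only
  on the focal genotypes and the frozen panel frequencies) and is the
  one verified against a 0.01-resolution grid search.
* `joint_analyze_samples` (used by the pipeline): panel genotypes enter
  the likelihood as binomial allele counts and the population
  frequencies are re-estimated each M-step with the focal sample's
  responsibilities included — the standard supervised-admixture
  formulation.  The distinction matters at low divergence: with
  50-bird panels at F = 0.02, the sampling noise of a panel frequency
  (sd ~ 0.05 per site) is comparable to the true between-population
  signal (sd ~ 0.06 per site), and holding noisy frequencies fixed is
  an errors-in-variables regression that attenuates a truly pure bird's
  MLE to q ~ 0.82.  Re-estimating frequencies jointly removes the
  attenuation (pure birds reach q ~ 0.99).  The joint EM is accelerated
  with SQUAREM (SqS3) extrapolation — identical fixed points, roughly
  an order of magnitude fewer EM maps — and stops when max |dq| < 1e-5.

  Standard errors are 10 site-bootstrap replicates (resampling sites
  with replacement, implemented as multinomial site weights so all
  replicates share one batched EM).  A bird is *genetically pure* for
  population k when `q_k + se_k >= 0.98`; otherwise the hybrid label
  concatenates every component with q > 0.10 in ABDU, WMA, GFM order.
  Paternal ancestry is inferred by subtraction over a paternal
  sib-group: `q_father = 2 q_offspring - q_mother`, clipped to the
  simplex and averaged, with the sib-group spread as its SE.  For a
  clutch from an unsampled mother the offspring mean is used as a proxy
  for both parents (the best available statement when neither parent is
  observed).

  Cross-validation over K is intentionally absent: K = 3 is fixed by
  the design (three labelled panels), so there is nothing to select.

**Dyad classification.**  For two offspring with genotypes g1, g2 at a
site with frequency p, the likelihood of a relationship R with
Cotterman coefficients (k0, k1, k2) is

    P(g1, g2 | R) = k0 P0 + k1 P1 + k2 P2

where P0 is HWE independence, P2 is identity, and P1 draws one allele
of g2 identical by descent from a uniformly chosen allele of g1.
Full-sib uses (0.25, 0.50, 0.25), half-sib (0.50, 0.50, 0), unrelated
(1, 0, 0).  Genotyping error enters as a 3x3 per-allele flip mixture
(default flip probability 0.5%, matching the generator).  Sites missing
in either sample or monomorphic are skipped; log-likelihoods sum over
sites (independent-sites assumption); exact ties resolve to the less
related relationship (conservative against false sibship).  Sib dyads
are only reported when the pair's Ajk clears the conventional 0.2
floor.

**Clutch partitioning.**  The paternal sib-groups of a clutch are the
connected components of the graph whose edges join egg pairs classified
full-sib (with Ajk > 0.2).  When the full-sib vs half-sib margin is
under 3 log-likelihood units the edge is decided by a paternal-allele
consistency ratio: at sites where each egg's paternal allele is
deducible from the hen's genotype, the probability that both alleles
came from one Hardy-Weinberg father is compared with two independent
fathers; positive log-ratio connects the pair.  The 3-unit margin is a
numerical choice (about a 20:1 likelihood ratio); partitions are
insensitive to it in simulation because most dyads are far from the
boundary.

**Cross-nest linking.**  Lineages in different nests merge when their
inter-nest egg dyads are predominantly half-sib with median Ajk in
(0.15, 0.40) and the paternal-allele ratio favours one father (a
promiscuous male); lineages of one hen's two clutches merge when the
cross-clutch dyads are predominantly full-sib (a renesting pair).  Pairs
whose cross-dyad median Ajk is at the unrelated baseline (<= 0.10) are
skipped without computing likelihoods.

**Population statistics.**  Nucleotide diversity uses the
missing-data-aware ratio-of-sums convention (`pi = sum_i D_i / sum_i
C_i` over called allele copies), and differentiation uses the
Hudson-type ratio-of-sums F_ST with unbiased within-group terms; both
match naive double-loop oracles to 1e-12.  The printed differentiation
bound the generator is calibrated against was produced by a different
(Phi_ST-style) program, so comparisons to it are qualitative.  The nest
network weights nest pairs by F_ST (negatives clamped to 0), extracts a
minimum-spanning-tree backbone, and reports the percolation threshold
(the largest edge weight that must be admitted for connectivity — the
maximum MST edge).  The sex-ratio test is an exact two-sided binomial
test on the parasitism-corrected offspring; the one-sample t statistic
on the 0/1 codes is reported alongside for comparability with
approximate analyses, but a t-test on binary data is a misapplied
approximation and the binomial p is the primary result.

## Synthetic-data generator

`synthgen` generates the complete study with known truth.  Defaults are
the study conditions the pipeline is designed for:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 2,000 | biallelic SNPs, independent (no linkage map) |
| `n_ref_per_pop` | 50 | reference birds per panel |
| `fst_abdu_wma` | 0.02 | Balding-Nichols F for ABDU and WMA (the low-divergence regime of wild mallard vs black duck) |
| `fst_gfm` | 0.10 | F for the distinct game-farm mallard cluster |
| `n_nests` | 19 | sampled nests |
| `clutch_min..max` | 5..13 | clutch size, uniform |
| `prop_epc` | 0.35 | fraction of nests with one extra-pair egg |
| `n_parasitized` | 2 | nests receiving 1-2 eggs from an outside hen |
| `n_shared_father_pairs` | 1 | nest pairs sired by one male |
| `n_renest_hens` | 1 | hens laying two clutches with the same father |
| `hybrid_hen_fraction` | 0.15 | F1 (ABDUxWMA) hens |
| `missing_rate` | 0.02 | per-genotype missingness |
| `genotype_error_rate` | 0.005 | per-allele flip probability |
| `mtdna_length` | 625 bp | control-region length |
| `n_nw`/`n_ow_haplotypes` | 7 / 1 | two-haplogroup pool, centres 15 mutations apart |

Site frequencies follow a Balding-Nichols model: ancestral frequencies
uniform on [0.05, 0.95], population frequencies Beta-distributed around
them with the population's F.  Independent draws at parameter F give a
pairwise Hudson F_ST of ~F between panels (the within-group estimator is
unbiased, so the ratio-of-expectations equals F exactly).  Founders
(hens, fathers, panel birds) are unrelated; F1 hybrids take one allele
per site from each parental population.  Eggs are Mendelian draws from
their true parents; observed genotypes add per-allele flips and
missingness; mtDNA passes from mother to egg verbatim.  Parasitizing
hens are unsampled and always carry a haplotype different from their
host's — so the generator does not exercise the same-haplotype
parasitism corner, which the classifier would (correctly) report as
ambiguous rather than parasitic.

What the generator does **not** emulate: linkage and LD structure
beyond injected duplicate sites, allele-frequency spectra of real
ddRAD data, site-specific error/depth profiles, population structure
within panels, later-generation backcrosses (hens are pure or F1), and
brood amalgamation.  Passing recovery tests therefore demonstrates the
logic and calibration of the inference chain under idealised
independent sites, not performance on a real ddRAD dataset.

## Numerical choices and degenerate inputs

* Thresholds printed to limited precision are compared with a 1e-4
  absolute tolerance (so a minimum allele frequency of 0.0056 retains a
  doubleton in a 180-sample set, which is what the threshold encodes).
* The parentage site set keeps sites with maf >= 0.45 (and <= 5%
  missingness): an maf floor of "0.5" is unattainable as a strict
  bound, so it is read as "maximally informative sites"; the floor is
  configurable and logged.
* LD pruning follows the two-SNP sliding rule (window 2, step 1, r^2 >
  0.5, random victim under the run's seed); pairs with a zero-variance
  member are kept (r^2 undefined, logged).  For chains of three or more
  mutually linked sites the sliding rule can remove adjacent sites in
  sequence, so the "at least half the sites survive" heuristic holds
  for disjoint linked pairs, not for pathological chains.
* Maternity needs >= 50 shared called sites; fewer yields an
  indeterminate (not rejected) verdict.  With indeterminate maternity
  an egg is ambiguous, and an all-ambiguous nest is indeterminate.
* Reference panel frequencies are clamped to [1/(2n+1), 1 - 1/(2n+1)]
  against log(0); the joint EM clips frequencies to [1e-4, 1 - 1e-4]
  and renormalises q onto the simplex after each SQUAREM extrapolation.
* A pair of samples with no usable site gets a missing (NaN) Ajk entry,
  never a silent zero.
* Haplotype comparison drops any alignment column carrying a gap or N
  in any sequence; haplogroup ties are unassigned with a warning; an
  unsampled hen's haplotype is the clutch majority, with ties flagged
  indeterminate.

## Purity recovery at the default study scale

One recovery property deserves its own statement.  At the default
conditions — 2,000 independent sites, panels of 50 at F = 0.02 between
ABDU and WMA, purity rule `q + se >= 0.98` — the Fisher information for
q at the simplex vertex is approximately `S * 4F`, giving a sampling sd
of ~0.08 for the pure bird's q.  The probability that a truly pure
bird's estimate plus its bootstrap SE clears 0.98 is then ~0.79 for any
(near-)unbiased estimator, and the measured rate is ~70-80%.  Calling
>= 95% of pure birds pure at this site count and divergence is
therefore not achievable by estimator improvements; it becomes
achievable with more sites (the original field analysis of this kind
used ~17,000 SNPs) or more divergent panels.  The complementary
property — F1 hybrids are never called pure — holds comfortably (an
F1's largest component stays far below the threshold).  The acceptance
suite asserts both as stated, so the pure-call bound fails honestly at
the default scale while every other recovery property passes.

## Problem sizes used in tests

Module tests use small random instances (tens of sites and samples)
against brute-force oracles.  Recovery tests run the full chain on
default-scale studies: 100 seeded replicates for strategy recovery and
parasitism false positives (a quarter of them at zero genotyping
error), 100 pure + 100 F1 simulants for purity calls, 2,000-site panels
for the F_ST calibration.  The acceptance script uses 60 pipeline
replicates and the same purity and calibration batteries; both the
suite and the script complete in a few minutes on one CPU.

## Known limitations

* Pairwise dyad likelihoods + graph clustering replace full-pedigree
  sibship MCMC; the substitution is transparent and deterministic but
  ignores higher-order pedigree constraints (e.g. three mutually
  half-sib eggs cannot all share distinct fathers pairwise).
* The mtDNA network is a minimum spanning network (all tied minimum
  spanning edges); median-joining's inferred median vertices are not
  implemented.  At the scale of interest (8 haplotypes, star-like
  topology) the two coincide for display purposes.
* The paternal-allele likelihood ratio ignores genotyping error (its
  deductions come from homozygous hens, where a single flip is
  required to mislead it; the effect is second-order at 0.5% error).
* Ajk values depend on the frequency reference; the pipeline's
  within-focal-set convention gives the familiar ~0.5 sib signature
  only approximately (downward bias of order 1/number-of-families).
* Sex-linked markers, imputation, phasing and multi-generation
  pedigrees are out of scope; inputs start at a filtered VCF.
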