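# Methods

`caprapop` re-implements, as a tested and reusable pipeline, the population-
diversity analysis workflow used in worldwide livestock SNP-array studies:
genotype quality control with Mendelian-error relatedness pruning, corrected
heterozygosities and F_IS with permutation significance, Weir–Cockerham F_ST,
hierarchical AMOVA, Reynolds distances with neighbor-joining export,
IBS-kinship multidimensional scaling, cross-population LD sharing, and
LD-based effective-population-size (Ne) trajectories. Because no genotype
data of the motivating scale are shipped with the package, every stage is
validated against a synthetic generator of hierarchically structured SNP
genotypes whose parameters are known exactly.

## Data model

Genotypes are held as a samples × variants matrix of allele-B dosages
(0/1/2, −1 missing), where allele B is the lexicographically larger of the
two alleles observed at a locus. This makes the coding deterministic and
independent of sample order; all frequency-symmetric statistics (expected
heterozygosity, F_ST, r²) are invariant under recoding d → 2−d, which the
test suite asserts. Positions are 1-based base pairs from the MAP file;
variants on chromosome "0" are treated as unmapped and excluded from
distance-dependent analyses only. Optional phased haplotypes are stored as a
(samples × 2 × variants) binary array whose per-locus sums must equal the
non-missing dosages.

PED/MAP reading follows PLINK text conventions: "0" allele tokens are
missing, half-missing pairs are treated as fully missing, and the family
column doubles as the population label so that write → read → write is
byte-identical. A monomorphic locus exposes only one allele in a PED file;
the unseen allele is coded with a placeholder on re-read (an inherent
limit of the format, documented in `genotype_io`).

## Quality control

The cascade runs in a fixed order: sample call rate ≥ 0.96 → SNP call rate
≥ 0.98 (recomputed after sample removal) → IBS-duplicate removal at
similarity ≥ 0.99 → monomorphic-variant removal → Mendelian-error
relatedness pruning → population exclusion and minimum-size (≥ 3) rules →
representative subsampling of populations above 50 individuals. Thresholds
follow PLINK's missingness convention ("higher than x" ⇒ keep at rate ≥ x),
switchable to strict inequalities.

Pairwise relatedness uses the count of opposing-homozygote loci (0/2
dosage pairs), which are impossible between parent and offspring: pairs
with fewer than 100 such loci are flagged as related, and a greedy cover
repeatedly removes the sample participating in the most flagged pairs
(ties: lower call rate, then later sample order). Between unrelated
individuals the expected count is ≈ 2·Σ p²q² per pair, several hundred at
5,000 polymorphic loci, so the rule separates cleanly at realistic marker
counts; the test suite verifies both directions on simulated trios. With
only a few hundred loci the rule degenerates (every pair looks "related") —
the pipeline does not guard against this because the motivating designs are
50K arrays.

The published "representative random sample" reduction algorithm is not
described at formula level; the stand-in here draws R = 100 seeded random
subsets and keeps the one minimising the Euclidean distance between subset
and full-population allele frequencies, which preserves the frequency
structure and is deterministic given the seed.

## Diversity statistics

Per population, statistics are computed over *usable* loci (< 5% missing
within the population) that are polymorphic within the population.
Observed heterozygosity is the mean fraction of heterozygous individuals;
expected heterozygosity is the unbiased gene diversity
h = n/(n−1)(1 − p² − q²) with n the non-missing gene copies. Two
summary-table corrections are applied verbatim from the source workflow:
H_O is multiplied by (polymorphic / usable) SNPs, and H_E by (A−1)/A with
A = 2 × the number of individuals in the whole working dataset. The H_E
correction referencing the dataset-wide rather than per-population allele
count is an oddity of that workflow, implemented as printed and flagged
here: at realistic sizes the factor is within 10⁻⁴ of 1.

F_IS is the ratio-of-averages 1 − H̄_O/H̄_E over the same loci (the
Nei-style estimator; the Weir–Cockerham variance-component alternative is a
documented possible extension). Significance comes from permuting gene
copies among individuals independently per locus — the randomised-mating
null, which fixes allele counts and hence H̄_E — with the two-sided
statistic |F_IS| and the add-one smoothing p = (1+k)/(B+1). Default B =
1,000; the calibration studies use B = 199 so the 0.05 level is exactly
attainable.

## Differentiation

Pairwise F_ST is the two-population Weir–Cockerham θ: per-locus components
a (among populations), b (among individuals), c (within individuals)
combined as Σa / Σ(a+b+c) over loci polymorphic in the pooled pair with at
least two individuals per side. The estimator is checked to ~10⁻¹⁶ against
an independent nested-ANOVA oracle that computes the same components from
raw mean squares. Negative θ are reported as computed; the zero floor is
applied only when formatting report tables. Significance permutes
individuals between the two populations.

Reynolds' distance uses the per-locus coancestry ratio
θ_l = Σ_u (p_Au − p_Bu)² / (2(1 − Σ_u p_Au p_Bu)); the "unweighted"
distance is the plain mean of θ_l over loci with non-zero denominator
(loci fixed for the same allele in both populations are skipped). The
ratio-of-sums pooling and the −ln(1−θ) transform are available behind
flags, since the source workflow states only "unweighted" and whether the
1983 least-squares small-sample correction was used is unknowable from the
text. Trees are produced by scikit-bio's neighbor-joining on the distance
matrix (values floored at zero for the triangle inequality's sake) and
exported as newick.

## AMOVA

Gene copies are the observational units; the squared distance between two
copies at a biallelic locus is the 0/1 allele difference, so sums of
squares are ordinary deviation sums. The design is fully nested — groups
(continents) ⊃ populations ⊃ individuals ⊃ copies — with 3-level
(no groups) and 4-level variants. Each locus is analysed separately with
pairwise-complete deletion of missing copies; variance components are
solved per locus from the expected-SS ("synthesis") coefficients of the
unbalanced nested random-effects model and summed over loci, the standard
convention for SNP AMOVA. Sums of squares are verified against an
independent oracle that computes every stratum via the pairwise-distance
identity SS = (1/n)Σ_{i<j} d²_ij, and total SS conservation holds to
10⁻⁹. Reported degrees of freedom use the complete-design convention
(total 2N−1).

Percentages divide each component by the sum of components *of that
design*, retaining negative components — so adding the among-groups level
changes the denominator rather than re-normalising, reproducing the
convention of the standard report tables. A consequence worth knowing: the
3- and 4-level percentages are not directly comparable. On balanced
designs the exact component-scale identity is

    σ²_AP(3-level) = σ²_AP(4-level) + σ²_AG(4-level) · m(G−1)/(P−1)

(m populations per group, G groups, P populations): with few groups the
grand mean absorbs part of the group variance, so the 3-level
among-populations component is systematically below σ²_AG + σ²_AP. The
test suite asserts this identity to machine precision.

Φ-statistics are component ratios (F_CT, F_SC, F_ST, F_IS, F_IT); a ratio
whose denominator stratum carries no variance is returned as NaN.
Permutation significance uses the level-appropriate scheme: individuals
among populations (within groups, for F_SC), whole populations among
groups (F_CT), and gene copies among individuals within populations
(F_IS).

## Kinship and MDS

Kinship is plain IBS similarity (mean of 1 − |d_i − d_j|/2 over jointly
non-missing loci) with unit diagonal; an allele-frequency-weighted kinship
is a documented possible extension. Individual MDS is classical Torgerson
scaling of d = 1 − kinship: double-centre, eigendecompose, scale
eigenvectors by √λ over positive eigenvalues; per-axis signs are fixed so
the largest-magnitude loading is positive, making output byte-reproducible.
"% of total variance" is relative to the positive-eigenvalue sum.

Population-level MDS first averages kinship over all sample pairs of two
populations (self-pairs included on the diagonal blocks) and embeds the
coancestry-style distance d_pq = (s_pp + s_qq)/2 − s_pq. This choice —
rather than 1 − s_pq — makes two populations with identical genotype
multisets exactly coincident and reduces to the individual embedding when
every population is a singleton.

## Linkage disequilibrium and Ne

r² is D²/(p_A q_A p_B q_B) from phased haplotypes when available,
otherwise the squared Pearson correlation of dosages; on phase-known
simulations the two agree within 0.05 on average. A scan keeps
same-chromosome pairs at ≤ 10 Mbp whose r² strictly exceeds 0.3. The
sharing distribution keys pairs by (chromosome, pos1, pos2) and counts,
per continent, the number k of populations whose scan contains each key;
the histogram over k, its percentages and mode mirror the cross-population
LD-sharing summaries of the motivating workflow, where weakly
differentiated population groups show high modal k and strongly
differentiated ones collapse to k = 1.

Ne trajectories fix the per-population sample size at 22 individuals
(populations below that are skipped; larger ones are reduced with the
representative subsample, whose frequency matching also keeps the
sampling-LD term close to its nominal 1/(2n) value). Physical distance is
mapped to recombination distance with a uniform 1 cM/Mbp map
(configurable). Pairs with MAF ≥ 0.05 are binned by c; each bin
contributes

    r²_adj = mean r² − 1/(2n),   Ne = (1/r²_adj − α)/(4c̄),   t = 1/(2c̄)

with α = 1 by default (α = 2 available), the no-mutation form of Sved's
expectation E[r²] = 1/(1 + 4Nc). Bins with no pairs or non-positive
r²_adj are omitted. At very small t (large c) the bin mean sits within
noise of the 1/(2n) sampling floor and the inversion is ill-conditioned —
single-replicate estimates there ranged over an order of magnitude in the
validation runs — so `recent_ne` reports the most recent bin at t ≥ 20
generations, where the Wright–Fisher studies recover Ne = 100 within
±20% on the mean of 10 replicates.

## Synthetic data

The generator is Balding–Nichols throughout: ancestral frequencies from
U(0.05, 0.5) (mirrored to both alleles), group frequencies from
Beta(p(1−F_CT)/F_CT, q(1−F_CT)/F_CT), population frequencies likewise
around the group values with F_ST_within; F = 0 copies the parent exactly.
Defaults (3 groups × 3 populations × 30 individuals, F_CT = 0.08,
F_ST_within = 0.10, F_IS = 0.05) are the study conditions of the
validation experiments; under them a within-group population pair has
expected θ = F_ST_within and a cross-group pair θ = F_CT +
F_ST_within(1−F_CT).

Genotypes come either from an infinite founder pool (independent Bernoulli
haplotypes; inbreeding as per-entry identity-by-descent with probability
F_IS) or from a finite pool of K founder haplotypes per population, which
induces block LD (individuals redraw a founder pair, the same founder
with probability F_IS). A `shared_pool` mode draws one pool per group and
derives each population's pool by flipping alleles with probability
`pool_divergence` (or by `pool_drift_rounds` rounds of founder
resampling) — the knobs behind the LD-sharing experiment. The sharing
histogram in this generator is U-shaped: pairs are either robustly shared
(pool-level LD, k = P) or private sampling noise (k = 1), so the modal k
jumps from P to 1 through the divergence transition rather than stepping
through intermediate values.

Trios transmit one whole parental haplotype per gamete — Mendelian-exact
and LD-preserving — so parent–child pairs have exactly zero opposing
homozygotes. The Wright–Fisher generator simulates discrete generations of
random mating (selfing allowed) with per-gamete recombination from the
uniform map (Haldane between adjacent SNPs, free across chromosomes),
starting from linkage equilibrium; 200 generations of burn-in equilibrate
all pairs with c ≥ 0.0025.

What the generator does *not* emulate: ascertainment bias of array SNP
discovery, genotyping error beyond random missingness, realistic
demography (bottlenecks, migration, admixture), mutation, or sex
chromosomes. Passing tests therefore demonstrate estimator correctness
and calibration under the stated models, not robustness to those
real-data complications.

## Validation experiments and problem sizes

`caprapop.validation` holds the protocols the test suite and
`scripts/acceptance.py` share; sizes were chosen to resolve each effect
comfortably while keeping the whole suite in minutes:

- **Oracle agreement** — 100 random tables (≤ 20 individuals, ≤ 20 loci):
  θ vs the nested-ANOVA oracle and AMOVA SS vs the pairwise-distance
  oracle, both far below the 10⁻⁹ tolerance.
- **Parameter recovery** — 10 seeds of the default 3×3×30 design with
  5,000 SNPs: 4-level F_CT, mean pairwise θ and mean F_IS within ±0.03 of
  truth (observed errors < 0.001 on the means).
- **Calibration** — 200 null pairs (25+25 individuals, 500 loci, 199
  permutations) for the F_ST test and 200 single-population HWE datasets
  (300 loci) for the F_IS test, nominal 0.05 level accepted in
  [0.025, 0.075]; power at F_ST = 0.15 with 1,000 loci over 50 simulations.
- **QC detection** — one 2×2×20 dataset (4,000 SNPs) with 5 trios, two
  low-call-rate samples, one duplicate, six low-call-rate variants and ten
  forced-monomorphic loci planted disjointly; every filter must remove
  exactly its offenders.
- **Ne recovery** — 10 Wright–Fisher replicates at Ne = 100 (3 × 10 Mbp
  chromosomes, 200 SNPs each, 200 generations), recent-bin estimate within
  ±35%.
- **LD sharing** — 6 populations × 50 individuals sharing a 6-founder
  pool, divergence δ ∈ {0, 0.01, 0.30}: modal k is P at δ = 0 and
  decreases monotonically to 1.

## Numerical choices and degenerate inputs

Beta parameters are clipped away from {0, 1} by 10⁻⁶ before sampling;
loci that drift to fixation are simply monomorphic downstream. Division
guards return NaN (undefined MAF / IBS with no joint loci / Φ with a
zero-variance denominator stratum) or skip the locus (Reynolds with both
populations fixed for the same allele, r² at monomorphic loci). Ties are
always broken deterministically (lexicographic allele coding, later sample
order in QC removals, label order in NJ input, positive-max-loading sign
in MDS). Every stochastic routine takes an explicit seed; the pipeline
derives per-stage sub-seeds by hashing the stage name with the global
seed, so toggling one stage never shifts another's stream.

## Known limitations

- F_IS is ratio-of-averages only; no Weir–Cockerham within-population f.
- Reynolds distances use the plain frequency formula; the least-squares
  sample-size-corrected estimator is not implemented.
- The Ne estimator is the Sved-form inversion with the 1/(2n) adjustment,
  not a reimplementation of any published tool's full correction chain
  (mutation adjustment, phase correction choices).
- AMOVA supports allele-difference distances on biallelic SNPs only.
- The CLI covers simulate / per-stage / run-all workflows; phasing,
  imputation, model-based clustering and migration-graph estimation are
  out of scope.
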