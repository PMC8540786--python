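# Methods

This note documents the statistical models, estimators and design choices
behind `ssrpopgen`, and what the synthetic-data validation does and does
not demonstrate.

## Data model

A `GenotypeTable` holds diploid, codominant calls: per (individual, locus)
an unordered pair of allele fragment sizes in bp, or a fully missing call
(partially missing calls are rejected). Allele identity is the exact
integer fragment size — no binning window is applied, because sizes are
assumed to come from fragment-analysis software that already produced
discrete calls. Missing data is encoded 0 in the CSV dialects (GenAlEx
convention) and −9 in the STRUCTURE export. Individual order is preserved
from input in every derived table, matrix and Q output. The dominant
SCAR119 band lives in per-individual metadata, not as a 21st codominant
locus; it is converted to a two-state pseudo-locus only inside the LD
machinery.

## Diversity statistics

All statistics are computed per locus per group on non-missing calls; no
imputation is performed.

* Ho — the direct proportion of heterozygous individuals.
* He — Nei's gene diversity 1 − Σpᵢ². `unbiased=True` applies the
  n/(n−1) gene-copy correction.
* PIC — Botstein's 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², with the conventional
  informativeness classes (>0.5 highly informative, 0.25–0.5 reasonably
  informative).
* Nₑ = 1/Σpᵢ², I = −Σpᵢ ln pᵢ.
* Ha — reported as the unbiased within-group expected heterozygosity
  averaged over groups. **Caveat:** "average heterozygosity" has no single
  operational definition across legacy packages; published tables produced
  by PopGene-era software are frequently not reproducible from any standard
  formula, so this column is defined explicitly here and should not be
  compared across tools without checking definitions.

## F-statistics

The default estimator is the plain Nei/Gst gene-diversity decomposition
with sample-size weights: H̄o and Hs are weighted means of the per-group
observed heterozygosity and gene diversity, Ht is the gene diversity of the
pooled (weighted-mean) frequencies, and

Fis = (Hs − H̄o)/Hs, Fit = (Ht − H̄o)/Ht, Fst = (Ht − Hs)/Ht.

These always satisfy (1 − Fis)(1 − Fst) = (1 − Fit) exactly, which the test
suite asserts. The default applies no small-sample correction, mirroring
the simplest textbook estimator.

`unbiased=True` applies Nei & Chesser-style corrections: the per-group
2n/(2n−1) factor on Hs, the Hs/(2ñr) sampling term on Ht (ñ the harmonic
mean group size), and the r/(r−1) correction on Dst = Ht − Hs. The last
term matters whenever the number of groups r is small: without it, the
expected Gst under a Balding–Nichols model with parameter F is
F(1 − 1/r)/(1 − F/r) — at r = 8 and F = 0.15 that is 0.134, a 10% downward
bias that has nothing to do with sample size. The corrected estimator
recovers F itself, and is therefore the right tool for parameter-recovery
validation; the recovery tests use it.

Gene flow uses the island-model inversion Nm = (1 − Fst)/(4Fst), with
Nm > 1 conventionally read as "gene flow present". Nm is validated against
this formula only; legacy published tables often contain Nm columns
internally inconsistent with their own Fst columns.

Per-group (single variety vs pooled collection) F-statistics use the only
construction that yields group-specific values from one partition:
Hs = group He, Ht = total He, H̄o = group Ho, combined across loci as
ratios of across-locus means. This is an interpretation, flagged as such;
legacy tables computed per-variety fixation indices in ways that cannot be
reconstructed from their published columns. The variance partition
("x% among / y% within") is the unweighted mean of these per-group Fst
values and its complement.

## Similarity, UPGMA, PCoA

Codominant calls are binarized into a band matrix (one column per observed
(locus, allele) pair; heterozygote → two 1s, homozygote → one). Similarity
between two individuals is computed over the bands of loci typed in both
(pairwise deletion): simple matching (a+d)/(a+b+c+d) for genetic-similarity
summaries, Dice 2a/(2a+b+c) for the dendrogram. Within-group similarity is
additionally offered on a band matrix restricted to the group's own bands
(`restrict_bands=True`, used in the per-variety table): without the
restriction, within-group similarity is inflated by shared absences of
bands the group never shows, and the two conventions can differ by 20
points or more.

UPGMA is scipy's average-linkage agglomeration on D = 1 − S; node heights
are ultrametric leaf depths (half the merge distance). Trees are
deterministic given the input; ties are broken by scipy's internal
ordering. Bootstrap support resamples loci (not bands — loci are the
independent units, and a locus's bands must travel together) with
replacement, and reports the percentage of replicate trees containing each
original clade; per-locus pairwise counts are precomputed once so each
replicate is a weighted re-assembly rather than a full recount.

PCoA is classical metric MDS: Gower double-centering of −D²/2 and
eigendecomposition (via scikit-bio). The full eigenvalue spectrum is
reported, negative eigenvalues included (1 − S distances are not guaranteed
Euclidean); axes with non-positive eigenvalues are never retained silently —
the embedding is truncated with a warning.

## Admixture model

`StructureAdmixture` implements the classic admixture model with
independent cluster allele frequencies: P(k, l) ~ Dirichlet(λ = 1),
Q(i) ~ Dirichlet(α, ..., α), and a latent cluster of origin for every
allele copy. Gibbs updates cycle Z | P, Q → P | Z → Q | Z, with a
Metropolis step on the single symmetric α (normal proposal, sd 0.05,
uniform prior on (0, 10]). Missing copies are skipped — they carry no
information. The likelihood trace records ln P(X | P, Q) every `thin` = 10
sweeps, and the evidence for K is approximated by the harmonic-variance
estimator lnPD = mean(lnL) − var(lnL)/2 over post-burn-in records — an
approximation inherited from common practice, adequate for ΔK-style
comparisons but not a true marginal likelihood.

The correlated-frequencies prior, linkage model and location priors are
deliberately out of scope; the independent-frequency model is the simplest
one consistent with unlinked multiallelic SSRs.

Label switching within a chain is not corrected (chains essentially never
switch in practice at these data sizes); across replicate runs, labels are
aligned by optimal assignment (Hungarian) on the Q-column agreement with
the first run. Evanno's ΔK is the mean absolute second difference of lnPD
across K (replicates paired by index) divided by the replicate standard
deviation at K; it is undefined at the ends of the K range and when the
replicate sd is zero. Three replicates per K is the default.

Defaults mirror the published protocol scale (burn-in 2×10⁵, 10⁶ sweeps,
K = 1..15) only behind the CLI's `--published-scale` flag; the package defaults
(burn-in 2×10³, 2×10⁴ sweeps, K ≤ 8) are the desk-scale settings at which
all tests and the acceptance script run. At those settings, on data with
3 well-separated source populations (Fst 0.3, 20 multiallelic loci,
30 individuals/population), ΔK selects K = 3 and modal-cluster assignment
is ≥ 95% accurate; results at the full published scale are not asserted
anywhere.

## Private alleles

An allele is private to a group when its frequency among the group's
non-missing gene copies is ≥ `min_freq` (default 5%) and it has exactly
zero observed copies in every other group — the absence condition is a
hard zero, not a frequency threshold. A single heterozygous carrier in a
group with n typed individuals has frequency 1/(2n). The count is
monotone non-increasing in `min_freq`, which is property-tested.

## Sex prediction and linkage disequilibrium

The dominant band predicts male when present, not-male when absent;
concordance is the fraction of band-typed dioecious individuals predicted
correctly, and a monoecious individual showing the band is flagged
discordant. The LD test is genotypic, not haplotypic: gametic phase is
unknown in field samples, so the contingency table crosses observed
unordered allele-pair classes at one locus against those at the other,
over co-typed individuals. Multiallelic loci are not collapsed; rare
classes are handled by the exact/Monte-Carlo machinery rather than by
pooling. The p-value is the probability, under fixed margins, of tables
no more probable than the observed one: enumerated exactly when a cheap
bound puts the number of margin-compatible tables at ≤ 10⁶, otherwise
estimated from seeded Monte-Carlo draws of fixed-margin tables
(Patefield's algorithm, via scipy), with the add-one estimator
(1 + hits)/(reps + 1). Significance is coded at 0.01 and 0.001; no
multiple-testing correction is applied in the matrix (raw-p presentation),
which is the convention for this table shape.

## Synthetic data generator

The generic generator draws ancestral allele frequencies from a symmetric
Dirichlet, population frequencies from the Balding–Nichols
parameterization Dirichlet(p(1 − F)/F) — chosen precisely because it makes
the differentiation target F an explicit, recoverable parameter — and
genotypes with probability `inbreeding_f` of autozygosity. Null alleles
designate one allele per locus at a target frequency as non-amplifying:
heterozygous carriers appear homozygous, null homozygotes appear missing,
which reproduces the classic mechanism by which null alleles inflate
apparent homozygosity (property-tested: injection lowers apparent Ho).
Allele sizes are motif-consistent ladders (cosmetic realism only). A
dominant band is fully linked to maleness in dioecious populations —
zero recombination, matching a perfectly concordant sex marker — and
absent in monoecious populations.

`study_shaped_fixture` generates the 104-individual, 11-variety, 20-locus
layout of the hemp core collection (variety sizes, countries, 61 dioecious
individuals with their male/female split, 43 monoecious). Per locus it
matches the published panel summary: the published allele count exactly
(3–28 per locus, 301 total — unobserved rare alleles are injected after
sampling by converting single copies of the locally most common allele,
preferring heterozygous carriers so Ho is untouched); the published
top-allele frequency and gene diversity at the pooled level (the remaining
frequency mass decays geometrically with the decay rate solved to match
He); the published per-locus fixation index as the Balding–Nichols F; and
the published per-locus inbreeding coefficient as the autozygosity
probability. Missing data is off in the fixture: a panel that survived
marker validation is near-complete, and a complete table makes the allele
count reproduction exact.

What the fixture does *not* emulate: real linkage between loci beyond the
sex band, allele-size homoplasy, genotyping error, null alleles in the
calibrated panel, and any individual-level genealogy within varieties
(individuals are exchangeable draws). Published per-variety
similarity/heterozygosity values that depend on the actual multilocus
genotypes (rather than on per-locus frequency summaries) are therefore
emergent, not calibrated: the fixture reproduces the published per-locus
calibration targets within Monte-Carlo tolerance, and published columns
that are mutually inconsistent (an Ho column cannot be reconciled with the
Fis/Fst/He columns of the same table under any weighting) cannot all be
matched simultaneously — the calibration follows He/Fis/Fst and lets Ho be
implied.

## Numerical choices and degenerate inputs

* Dirichlet draws are realized as normalized Gammas; a 1e-300 floor keeps
  ancestry rows valid when a Gamma(α) draw underflows at small α.
* Fis is undefined (NaN, with a warning) when Hs = 0; all three
  F-statistics are undefined when Ht = 0; Nm is undefined for Fst ≤ 0.
* Similarity pairs with no co-typed locus are NaN with a warning; UPGMA
  and PCoA refuse incomplete matrices rather than imputing.
* Degenerate LD tables (a zero margin) return p = 1 with a warning.
* All stochastic stages (sampler, bootstrap, Monte-Carlo LD, generators)
  consume numpy `SeedSequence`-derived seeds; the CLI pipeline splits one
  root seed per stage, so reruns are byte-identical.

## Problem sizes used in validation

Tests and the acceptance script run at desk scale, chosen so each pillar
is informative while the whole suite stays fast: formula oracles on ≤4
individuals; estimator recovery on 8 populations × 50 individuals × 100
loci (F = 0.15 recovered within ±0.02, inbreeding 0.3 within ±0.05);
admixture selection on 3 × 30 individuals × 20 loci at 2×10⁴ sweeps; LD
calibration on 1000 null pairs of 120 individuals with 2000 Monte-Carlo
tables each (rejection at 0.01 inside the 95% binomial band); bootstrap
support on 2 × 8 individuals × 50 loci at 100 replicates.
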