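# Methods

## Problem setting

Qualitative metabolomic fingerprinting records, for each sample, only the
presence (1) or absence (0) of each identified metabolite. Comparing such
samples requires a binary similarity coefficient, and dozens of candidates
exist, differing chiefly in how they treat shared absences and how they map
onto the unit interval. `binfing` implements a consensus framework for
choosing among them: all coefficients are evaluated on the same data, their
induced orderings of sample pairs are compared against a consensus by sum
of ranking differences (SRD), the rankings are validated by randomization
and bootstrap, aggregated over datasets, decomposed by ANOVA, and finally
the practical payoff is quantified by how well clustering on binary
fingerprints reproduces clustering on full quantitative profiles.

## The similarity catalog

Each coefficient is a function of the contingency counts between two
fingerprints of length p: a (1–1 matches), b (1–0), c (0–1), d (0–0),
with a+b+c+d = p. The catalog holds 44 coefficients under the naming and
taxonomy of Todeschini et al. (2012, J. Chem. Inf. Model. 52:2884):
13 concordantly symmetric (S; d counts like a), 17 asymmetric (A; d
ignored), 2 intermediate (I; d down-weighted) and 12 correlation-based (Q),
and 22 metric vs 22 non-metric. Raw values are mapped onto [0, 1] by
s′ = (s + α)/β; for coefficients with a p-dependent raw range (Forbes,
Kulczynski, Fossum, Mountford, Dennis, Gower, Harris–Lahey, dispersion)
α and β are functions of p chosen so the extreme raw values map to 0 and 1
(verified exhaustively over all contingency tables with p ≤ 12).

Sokal–Sneath numbering varies between sources; here SS1 = a/(a+2b+2c),
SS2 = 2(a+d)/(p+a+d), SS3 = the quarter-sum of the four conditional
ratios, SS4 = ad/√((a+b)(a+c)(b+d)(c+d)).

**Degenerate denominators.** Fingerprint pairs with empty margins (all-zero
or all-one vectors, or coefficients such as Kulczynski's a/(b+c) on
identical vectors) make some formulas 0/0 or x/0. The catalog resolves
every such cell by one convention: if the two fingerprints are identical
(b = c = 0) the coefficient's maximal raw value is returned; otherwise the
neutral raw value 0 (which the Q-scale maps to s′ = 0.5). This keeps every
similarity matrix complete, at the cost of a documented discontinuity for
a few coefficients (e.g. Gower's, whose value jumps when the second
fingerprint stops being a strict subset of an all-present first one).

**Directional coefficients.** Di1/Di2 (Wallace's a/(a+b), a/(a+c)) and
Pe1/Pe2 (Peirce's pair) depend on the argument order and satisfy the swap
identity Di1(x,y) = Di2(y,x). The matrix builder evaluates them in a
canonical orientation — entry (i, j) with i > j uses (fingerprint_i,
fingerprint_j) — and mirrors, so all similarity matrices are symmetric and
unfolding is well defined. Their order dependence is part of why they rank
poorly in consensus analyses.

**Metricity.** A coefficient is tagged metric (M) when its similarity can
be transformed into a distance obeying non-negativity, symmetry and the
triangle inequality; identity of indiscernibles is required only for
coefficients whose self-similarity is maximal (Russell–Rao-type
coefficients have d(x,x) > 0 by construction). Twelve coefficients are
metric under the plain complement d = 1 − s′; ten more (BUB, RG, SS3, Coh,
MP, CT1, CT3, CT4, GL, SS2) are metric under the square-root complement
d = √(1 − s′), a standard metric-generating transform. Each M-tagged
coefficient records which transform applies (`metric_transform`), and the
test suite brute-forces the axioms for that transform over all bit-vector
triples up to length 5, with the degenerate conventions in force. Plain
1 − s′ violates the triangle inequality for the square-root group (e.g.
BUB on the triple 001/011/010); this is expected and is why the transform
is recorded per coefficient rather than assumed globally.

## Sum of ranking differences

The unfolded similarity vectors (strict lower triangle, pair order
(2,1), (3,1), (3,2), …) form an n_pairs × 44 matrix. The diagonal is
excluded: self-similarities are constant within most coefficients and add
no ranking information (an `include_diagonal` switch exists for exact
replication experiments; duplicated tied rows would not change the
ranking). The consensus reference is the row-wise aggregate (average by
default; min/max/median available). All columns and the reference are rank
transformed ascending with average ranks for ties — similarity columns tie
routinely, so fractional ranks are essential. A column's SRD is
Σ|rank − reference rank|, normalized by the maximal attainable SRD and
reported in percent.

The normalization constant is computed empirically as the SRD of the
reference against its own reversal, which equals n²/2 (n even) or
(n²−1)/2 (n odd) for tie-free references and handles tied references
consistently; a constant reference yields 0 and normalization is refused.
Both this empirical bound and the theoretical tie-free bound coincide in
the tie-free case, which the tests verify by exhaustive enumeration.

**Randomization (CRRN).** The chance distribution of SRD is that of a
uniformly random permutation against a fixed tie-free reference — the
distribution of Spearman's footrule. It is computed exactly by
enumerating all n! permutations for n ≤ 9 and by seeded Monte Carlo
(default 10,000 draws) above; the tie-free null is an approximation when
the observed reference carries ties. Reported are the 5%/50%/95% points in
normalized units; an observed SRD below the 5% point beats chance.

**Bootstrap.** Rows of the unfolded matrix (sample pairs) are resampled
with replacement to the original size, the consensus is recomputed inside
each resample, and normalized SRD is recorded per coefficient; resamples
with a constant reference are redrawn. Default 100 iterations; mean, SD
and the 2.5–97.5% interval are reported. Resampling pairs (rather than
samples) keeps the scheme agnostic to how the pairs arose and is the
package's choice where several schemes are defensible.

## ANOVA decomposition and grouping

Bootstrap-mean normalized SRD values from several datasets are stacked
into a long table (dataset × coefficient). One-way ANOVA is run per factor
(coefficient, symmetry class, metricity group) with datasets as
replicates — deliberately not a multi-factor model, so each decomposition
reads independently. Confidence intervals for level means use the pooled
within-group error; Tukey HSD and Bonferroni-corrected pairwise t-tests
are exported, plus a non-blocking Levene diagnostic (normality and
homoscedasticity are reported, not enforced). Coefficients are banded by
grand-mean SRD%: below 15 "best", 15–25 "medium", above 25 "worst".

## Cluster agreement (CCR%)

Binary distances are d = 1 − s′ of a chosen coefficient. The quantitative
reference standardizes each metabolite column to zero mean and unit
variance (constant columns dropped with a warning) and uses
1 − |Pearson r| between sample profiles; a sample whose standardized
profile is constant is treated as uncorrelated with everything. Both
matrices are clustered by Ward's method applied directly to the supplied
dissimilarities via the Lance–Williams update (the legacy "ward.D"
dialect; a "d2" squared-distance variant is available and cross-checked
against scipy's Ward). Agglomeration ties break towards the smallest index
pair, so output is deterministic. Cutting both trees at k clusters gives
partitions compared by CCR% — the fraction of samples whose labels match
under the best label pairing (solved as an assignment problem, any k) —
alongside the Rand pairwise agreement, since the two scores answer
slightly different questions.

A structural caveat found while validating the pipeline: with exactly two
balanced groups, every group-informative feature contributes +v to
within-group and −v to between-group correlation, so the absolute-value
reference distance 1 − |r| cannot distinguish the groups at all (measured
r_within ≈ +0.78 vs r_between ≈ −0.81 on synthetic data). Real datasets
escape this because their structure is richer than two complementary
blocks; synthetic cluster-agreement experiments therefore use three
groups, where features informative for a third group break the symmetry.

## Synthetic data generator

Each group has a prototype fingerprint of independent Bernoulli(θ) bits;
each sample copies its group prototype with independent per-bit flip
probability ε. Abundances are zero where a bit is absent and
exp(μ + δ_gm + N(0, σ_w²)) where present, with δ_gm ~ N(0, σ_b²) drawn
once per (group, metabolite) — concentrations are group-characteristic,
which is exactly what makes quantitative profiles cluster by origin.
Thresholding the quantitative layer at zero reproduces the binary table by
construction. Defaults: θ = 0.4 (moderately dense fingerprints),
ε = 0.05 (a small detection error), μ = 0, σ_w = 0.3 (~30% within-group
CV), σ_b = 0.8 (clear but not extreme group contrasts). An optional
minimum prototype Hamming distance makes separability controllable.

Nine presets mirror the sample/metabolite counts of the published case
studies the package is modeled on (8×12 up to 29×53), with 2–3 groups
each. What the generator does *not* emulate: correlated metabolite
co-occurrence, retention-time artifacts, batch effects, or missing cells.
Passing tests on synthetic data therefore demonstrate the pipeline's
correctness and its behavior under planted structure, not performance on
any particular real study.

## Problem sizes and determinism

The shipped experiments use the nine presets (largest 29 samples → 406
pairs × 44 coefficients), 100 bootstrap iterations, exact CRRN for ≤ 9
rows and 10,000 Monte Carlo draws otherwise, and 100 generator
replications for the recovery experiment; the full study runs in well
under a minute on one core. All randomness flows from one master seed
through named `SeedSequence` substreams; a rerun with the same
configuration is bit-identical, and output tables carry the configuration
hash and seed.

## Known limitations

- The catalog's metricity tags depend on the recorded transform; other
  sources tag metricity under other conventions and may differ for
  individual coefficients.
- The CRRN null assumes a tie-free reference; heavily tied references make
  the null slightly conservative.
- The two-balanced-group identifiability limit of the 1 − |r| reference is
  inherent to that distance, not to the implementation.
- ANOVA treats dataset means as independent replicates; datasets sharing
  samples (e.g. sub-tables of one study) violate this mildly.
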