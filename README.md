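# binfing — binary similarity measures for metabolomic fingerprints

Qualitative metabolomic profiling records each sample as a presence/absence
vector over identified metabolites: cheap to acquire, robust to signal
shifting and matrix effects, but dependent on one consequential choice —
the binary similarity coefficient used to compare samples. Dozens of
candidates exist (Jaccard–Tanimoto, simple matching, Baroni-Urbani–Buser,
Yule, …) and they disagree, mainly in how they weight shared absences.

`binfing` is a library for choosing among them systematically. It is aimed
at metabolomics and chemometrics practitioners who cluster or fingerprint
samples from 0/1 metabolite tables and want a defensible, reproducible
basis for the similarity coefficient they pick.

## What it computes

**Similarity catalog.** 44 coefficients as functions of the contingency
counts *a* (1–1), *b* (1–0), *c* (0–1), *d* (0–0), *p = a+b+c+d*, e.g.

    SM  = (a + d) / p                                 (simple matching)
    JT  = a / (a + b + c)                             (Jaccard–Tanimoto)
    BUB = (√(ad) + a) / (√(ad) + a + b + c)           (Baroni-Urbani–Buser)

each rescaled to [0, 1] by s′ = (s + α)/β, and tagged by concordance
symmetry (13 symmetric / 17 asymmetric / 2 intermediate / 12
correlation-based) and metricity (22 metric / 22 non-metric, brute-force
verified).

**Consensus ranking by SRD.** For one dataset, every coefficient's full
similarity matrix is unfolded into a vector over the m(m−1)/2 sample
pairs; columns are rank-transformed and compared against the row-wise
average consensus by the sum of ranking differences

    SRD_j = Σ_i | rank(x_ij) − rank(ref_i) |,

normalized to percent of the maximal attainable value. Small SRD% = the
coefficient orders sample pairs like the consensus does. A randomization
null (the exact Spearman-footrule distribution for small n, Monte Carlo
otherwise) gives the chance band, and bootstrap resampling of pairs gives
uncertainty. Across datasets, bootstrap means are decomposed by one-way
ANOVA (coefficient / class / metricity as factors, Tukey and Bonferroni
post-hoc) and banded into best (< 15), medium (15–25) and worst (> 25)
groups.

**Cluster agreement (CCR%).** Ward trees built from binary distances
(1 − s′) are compared against the quantitative reference tree
(1 − |Pearson r| on standardized concentrations): CCR% is the fraction of
samples in matching clusters under the best cluster-label pairing.

**Synthetic data.** A generator of group-structured fingerprints
(Bernoulli prototypes + bit-flip noise) with a paired concentration layer
that reproduces the binary table when thresholded at zero, including nine
presets sized like published case studies.

## Worked example

```python
from binfing import contingency, evaluate, get_measure

x = [1, 1, 1, 0, 0, 0, 0, 1, 1, 0]
y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
counts = contingency(x, y)          # a=3 b=2 c=2 d=3
for mid in ("SM", "JT", "RR", "BUB", "HD", "Yu"):
    print(mid, round(evaluate(get_measure(mid), counts), 3))
```

prints

```
SM 0.6
JT 0.429
RR 0.3
BUB 0.6
HD 0.429
Yu 0.692
```

— the same pair of samples looks moderately similar to coefficients that
credit the three shared absences (SM, BUB), less so to those that ignore
them (JT) or penalize them (RR).

Running the full consensus study on the nine case-study-sized synthetic
presets (`python examples/03_consensus_study.py`) ranks
Baroni-Urbani–Buser most consistent (grand-mean SRD% ≈ 3.3) with the
directional and asymmetric coefficients (Di2, Russell–Rao, CT3 ≈ 20) at
the bottom, and the coefficient factor is highly significant in ANOVA
(F(43, 352) ≈ 2.7, p ≈ 3·10⁻⁷). The cluster-agreement example
(`examples/04_cluster_agreement.py`) shows binary BUB clustering matching
the quantitative reference at CCR = 94.4% (one misclassified sample of
18) under 5% flip noise.

The `examples/` directory has one short script per capability; a thin CLI
(`binfing measures list`, `binfing srd`, `binfing compare`,
`binfing simulate`, `binfing run --config study.yaml`) wraps the same
functions for shell use.

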