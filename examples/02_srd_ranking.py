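"""Rank all 44 coefficients by sum of ranking differences on one dataset.

A synthetic fingerprint table sized like a real case study (17 samples, 26
metabolites) is unfolded into a 136-pair x 44-measure matrix; each column is
ranked against the row-wise average consensus.  Small normalized SRD means
the coefficient orders sample pairs the way the consensus does; the 5%
point of the randomization null is the value a coefficient must beat to be
better than chance.
"""
import numpy as np

from binfing import (SyntheticSpec, assemble_srd_input, bootstrap_srd,
                     generate, run_srd)

ds = generate(SyntheticSpec(n_groups=3, samples_per_group=(6, 6, 5),
                            n_metabolites=26, seed=3))
X = assemble_srd_input(ds.binary)
print(f"SRD input matrix: {X.n_pairs} sample pairs x {len(X.measure_ids)} measures")

rng = np.random.default_rng(0)
results = run_srd(X, mode="average", seed=rng)
boots = bootstrap_srd(X, iterations=100, seed=rng)
boot = {b.measure_id: b for b in boots}

print(f"randomization null 5% / 50% / 95%: "
      f"{' / '.join(f'{q:.1f}' for q in results[0].null_percentiles)} (SRD%)")
print("\nrank measure  SRD%   bootstrap mean +/- sd")
for i, r in enumerate(sorted(results, key=lambda r: r.srd_norm), 1):
    b = boot[r.measure_id]
    print(f"{i:4d} {r.measure_id:7s} {r.srd_norm:5.1f}   {b.mean_srd_norm:5.1f} +/- {b.sd:.1f}")
# Every coefficient scores far below the null's 5% point, so all of them
# rank pairs much more consistently than chance — but the spread between
# the best (small SRD%) and worst separates robust choices from fragile ones.
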