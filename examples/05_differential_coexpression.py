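"""Differential expression and permutation differential co-expression.

Simulates a gene x sample NB count matrix for the Alone vs Group
social-context contrast with planted 4-fold DE genes and planted
correlation-flipped (DC) gene pairs, then runs the expression filter,
the DE test (FDR < 0.05, no fold-change filter), the 1,000-permutation
1%-tail DC rule, and the DE/DC intersection.
"""

from shoalgen import coexpr as ce
from shoalgen import synthdata as sd

counts, meta, truth = sd.simulate_counts(
    300, 24, de_frac=0.08, dc_pairs=5, rho=0.9, seed=13
)
filt, _ = ce.filter_low_expression(counts, meta)
print(f"{len(filt)}/{len(counts)} genes pass the 2-RPKM filter")

de = ce.de_test(filt, meta)
planted_de = set(truth.gene_truth.loc[truth.gene_truth["de"], "gene"])
called = set(de.index[de["de"]])
print(f"DE: {len(called)} called at q<0.05; {len(called & planted_de)} of "
      f"{len(planted_de)} planted recovered")

pairs, threshold, skipped = ce.dc_pairs(filt, meta, n_perm=1000, tail=0.01, seed=13)
planted_pairs = {frozenset(t) for t in truth.pair_truth[["gene_a", "gene_b"]].to_numpy()}
found = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
n_pairs = len(filt) * (len(filt) - 1) // 2
print(f"DC: {len(pairs)} of {n_pairs} pairs above the 1%-tail permutation "
      f"threshold {threshold:.2f} (~1% expected by construction); planted "
      f"recovered {len(found & planted_pairs)}/{len(planted_pairs)}")

both = ce.de_dc_intersection(de, pairs)
print(f"genes both DE and DC: {sorted(both['gene'].unique())}")
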