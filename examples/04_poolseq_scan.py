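"""Pooled allele-frequency scan: Fisher (merged) and CMH (replicated).

Simulates 20,000 SNPs for three replicate high/low-sociability pool
pairs with 60 causal SNPs shifted by 0.25, applies the standard
coverage/count filter, then runs both scans. The merged Fisher test
uses the genome-wide threshold -log10 p > 8; the replicate-consistent
CMH test uses FDR q < 0.01 — the stringent criterion that favours
selected sites over line-specific drift.
"""

from shoalgen import poolseq as ps
from shoalgen import synthdata as sd

table, truth = sd.simulate_poolseq(
    20_000, n_causal=60, shift=0.25, coverage_mean=60, n_replicates=3, seed=5
)
filt, log = ps.filter_snps(table, min_count=6, min_coverage=25, max_coverage=200)
print(f"{filt.n_snps}/{table.n_snps} SNPs pass the coverage/count filter")

fisher = ps.fisher_scan(filt, high_pools=[0, 2, 4], low_pools=[1, 3, 5])
cmh = ps.cmh_scan(filt, strata=[(0, 1), (2, 3), (4, 5)])

tr = truth.snp_truth.set_index("pos")["causal"]
for name, scan in (("Fisher -log10 p > 8", fisher), ("CMH q < 0.01", cmh)):
    sig = scan[scan["significant"]]
    hits = tr.reindex(sig["pos"]).sum()
    print(f"{name}: {len(sig)} significant SNPs, {int(hits)} of them truly causal "
          f"(of {int(tr.sum())} planted)")

fst = ps.fst_scan(filt, 0, 1)
print(f"mean per-SNP FST (replicate 1 pools): {fst['fst'].mean():.4f}")
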