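"""Pooled-sequencing allele count generator (sync dialect).

Emulates the study design: per replicate selection line, one pool of 7
high-sociability and one pool of 7 low-sociability diploid mothers
(14 chromosomes each). Neutral SNPs share one population frequency per
replicate pair; causal SNPs are shifted consistently high-vs-low in
every replicate. Read counts are binomial draws at the pool allele
frequency with Poisson coverage. Pool DNA contributions are equimolar;
no linkage, finite-pool resampling or sequencing-error model (read
sampling is the only stochasticity the association tests are asked to
calibrate against).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from shoalgen.poolseq import SyncTable
from shoalgen.synthdata.pedigree import TruthRecord


def simulate_poolseq(
    n_snps: int,
    n_causal: int = 0,
    shift: float = 0.0,
    coverage_mean: float = 60.0,
    pool_n: int = 7,
    n_replicates: int = 3,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[SyncTable, TruthRecord]:
    """Simulate a sync table of ``n_replicates`` high/low pool pairs.

    Pools are ordered high_1, low_1, high_2, low_2, ... Causal SNPs get
    base frequency +shift/2 in high pools and -shift/2 in low pools
    (clipped away from the boundary by construction); read counts are
    binomial(coverage, pool frequency) with Poisson coverage. ``pool_n``
    documents the pooling design (7 diploid mothers per pool).
    """
    if n_causal > n_snps:
        raise ValueError("n_causal cannot exceed n_snps")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    base = rng.uniform(lo, hi, n_snps)
    causal = np.zeros(n_snps, dtype=bool)
    causal[rng.choice(n_snps, size=n_causal, replace=False)] = True
    if shift > 0 and n_causal > 0:
        margin = shift / 2
        if margin > 0.48:
            raise ValueError(f"shift {shift} impossible for frequencies in (0,1)")
        # keep causal frequencies away from the boundary so +/- shift/2 fits
        base[causal] = np.clip(base[causal], 0.02 + margin, 0.98 - margin)
    n_pools = 2 * n_replicates
    counts = np.zeros((n_snps, n_pools, 6), dtype=int)
    for rep in range(n_replicates):
        # neutral SNPs share one frequency within each replicate pair, so
        # read sampling is the only noise the association tests see; the
        # causal shift splits the pair symmetrically
        p_pair = base
        for j, sign in ((2 * rep, +1), (2 * rep + 1, -1)):
            p_pool = p_pair + np.where(causal, sign * shift / 2, 0.0)
            cov = rng.poisson(coverage_mean, n_snps)
            alt = rng.binomial(cov, np.clip(p_pool, 0.0, 1.0))
            counts[:, j, 0] = cov - alt  # reference base A
            counts[:, j, 3] = alt  # alternate base G
    table = SyncTable(
        chrom=np.array(["chr1"] * n_snps),
        pos=np.arange(1, n_snps + 1) * 100,
        ref=np.array(["A"] * n_snps),
        counts=counts,
    )
    truth = TruthRecord(
        snp_truth=pd.DataFrame(
            {
                "chrom": table.chrom,
                "pos": table.pos,
                "causal": causal,
                "base_freq": base,
                "shift": np.where(causal, shift, 0.0),
            }
        )
    )
    return table, truth
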