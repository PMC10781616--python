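"""Expression count-matrix generator with planted DE genes and
correlation-flipped gene pairs.

Counts are negative binomial with gene-specific means and dispersions.
DE genes receive a log-fold-change between the two conditions.
Differentially co-expressed (DC) pairs are driven by a shared latent
factor whose loading flips sign between conditions, giving correlation
+rho in one condition and -rho in the other.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from shoalgen.synthdata.pedigree import TruthRecord


def simulate_counts(
    n_genes: int,
    n_samples: int,
    de_frac: float = 0.0,
    dc_pairs: int = 0,
    seed: int = 0,
    log2fc: float = 2.0,
    rho: float = 0.8,
    dispersion: float = 0.1,
    mean_log_mu: float = 5.0,
    conditions: tuple[str, str] = ("Alone", "Group"),
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate a gene x sample NB count matrix.

    ``n_samples`` is the total (split evenly between the two
    conditions; at least 4 per condition). Returns (counts DataFrame
    with a gene_length column, sample metadata, truth).
    """
    if n_samples < 8:
        raise ValueError("need at least 4 samples per condition")
    rng = np.random.default_rng(seed)
    n_a = n_samples // 2
    cond = np.array([conditions[0]] * n_a + [conditions[1]] * (n_samples - n_a))
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    lengths = rng.integers(500, 5000, n_genes)

    log_mu = rng.normal(mean_log_mu, 1.0, n_genes)
    n_de = int(round(de_frac * n_genes))
    de = np.zeros(n_genes, bool)
    de[rng.choice(n_genes, n_de, replace=False)] = True
    sign = rng.choice([-1.0, 1.0], n_genes)
    lfc = np.where(de, sign * log2fc, 0.0)

    # DC pairs drawn from non-DE genes so the two plantings don't collide
    free = np.flatnonzero(~de)
    if 2 * dc_pairs > len(free):
        raise ValueError("not enough non-DE genes for the requested DC pairs")
    chosen = rng.choice(free, 2 * dc_pairs, replace=False)
    pair_a, pair_b = chosen[:dc_pairs], chosen[dc_pairs:]

    # DC pair members are highly expressed with low dispersion so the
    # planted correlation survives counting noise on the log scale
    dc_members = np.concatenate([pair_a, pair_b])
    log_mu[dc_members] = np.maximum(log_mu[dc_members], 7.0)
    disp = np.full(n_genes, dispersion)
    disp[dc_members] = min(dispersion, 0.02)

    log_mean = log_mu[:, None] + np.log(2.0) * lfc[:, None] * (cond == conditions[1])[None, :]
    # latent factor per sample drives DC pairs; loading flips sign across
    # conditions for the second member of each pair
    latent = rng.standard_normal(n_samples)
    load = np.sqrt(rho)
    noise_sd = np.sqrt(1.0 - rho)
    lognoise = rng.standard_normal((n_genes, n_samples))
    z = lognoise.copy()
    flip = np.where(cond == conditions[1], -1.0, 1.0)
    for a_, b_ in zip(pair_a, pair_b):
        z[a_] = load * latent + noise_sd * lognoise[a_]
        z[b_] = load * flip * latent + noise_sd * lognoise[b_]
    signal_sd = np.full(n_genes, 0.35)
    signal_sd[dc_members] = 0.8
    mu = np.exp(log_mean + signal_sd[:, None] * z)
    # NB via gamma-Poisson mixture; dispersion = 1/size
    size = 1.0 / disp
    lam = rng.gamma(size[:, None], mu / size[:, None])
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=[f"s{i:02d}" for i in range(n_samples)])
    counts_df.insert(0, "gene_length", lengths)
    meta = pd.DataFrame(
        {
            "sample": counts_df.columns[1:],
            "treatment": cond,
            "line": np.tile([1, 2, 3], int(np.ceil(n_samples / 3)))[:n_samples],
            "regime": "polarization",
            "tissue": "telencephalon",
            "pool_id": np.arange(n_samples),
        }
    )
    truth = TruthRecord(
        gene_truth=pd.DataFrame({"gene": genes, "de": de, "log2fc": lfc}),
        pair_truth=pd.DataFrame(
            {"gene_a": genes[pair_a], "gene_b": genes[pair_b], "dc": True}
        ),
    )
    return counts_df, meta, truth
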