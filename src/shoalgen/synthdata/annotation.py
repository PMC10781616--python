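"""Random gene -> GO-term annotation with optionally planted shared
enrichment between two gene sets.

Background annotation assigns each gene a Poisson number of random
terms. Planted terms are over-represented in both output gene sets, so
a concordance analysis downstream should find the sets agreeing on
those terms while unplanted structure stays at the bootstrap null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NAMESPACES = ["BP", "CC", "MF"]


def simulate_annotation(
    n_genes: int,
    n_terms: int,
    planted_terms: int = 0,
    seed: int = 0,
    set_size: int = 100,
    terms_per_gene: float = 4.0,
    planted_gene_frac: float = 0.6,
    module_size: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, list, list]:
    """Simulate an annotation map and two gene sets.

    Returns (gene->term map, term->namespace table, gene_set_a,
    gene_set_b). The first ``planted_terms`` terms are enriched in both
    sets: a ``planted_gene_frac`` fraction of each set's members carries
    each planted term, against a background carriage rate of
    ``terms_per_gene / n_terms``. Each term additionally annotates one
    random module of ``module_size`` genes — terms label co-functional
    gene groups, the clumpiness that lets even random gene sets reach
    occasional significant enrichment (as real ontologies do); 0
    disables it.
    """
    if planted_terms > n_terms:
        raise ValueError("planted_terms must be <= n_terms")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    terms = np.array([f"GO:{i:07d}" for i in range(n_terms)])
    ns = pd.DataFrame(
        {"term": terms, "namespace": [NAMESPACES[i % 3] for i in range(n_terms)]}
    )
    # background: each gene x term annotated independently
    p_bg = min(terms_per_gene / n_terms, 0.5)
    mat = rng.uniform(size=(n_genes, n_terms)) < p_bg
    if module_size:
        for t in range(n_terms):
            module = rng.choice(n_genes, min(module_size, n_genes), replace=False)
            mat[module, t] = True

    set_a = rng.choice(n_genes, set_size, replace=False)
    remaining = np.setdiff1d(np.arange(n_genes), set_a)
    set_b = rng.choice(remaining, min(set_size, len(remaining)), replace=False)
    for t in range(planted_terms):
        for s in (set_a, set_b):
            hit = rng.uniform(size=len(s)) < planted_gene_frac
            mat[s[hit], t] = True
    gi, ti = np.nonzero(mat)
    annot = pd.DataFrame({"gene": genes[gi], "term": terms[ti]})
    return annot, ns, list(genes[set_a]), list(genes[set_b])
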