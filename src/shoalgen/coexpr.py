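"""Brain-transcriptome stage: expression filtering, DE plumbing,
permutation-null differential co-expression and sample clustering.

The scientific contribution here is the permutation significance rule
for differential co-expression (DC): a gene pair's score in the real
data must exceed the 1% tail of the score distribution pooled over
1,000 condition-label permutations. The pair score is the absolute
difference of Fisher-z-transformed Pearson correlations between the two
conditions (a monotone surrogate for heavier co-expression statistics;
pluggable). The DE test is deliberately simple plumbing — a
moment-dispersion negative-binomial Wald test on median-of-ratios
normalized counts — so the DE/DC intersection and clustering stages are
exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import norm

from shoalgen.poolseq import bh_fdr

RPKM_THRESHOLD = 2.0
DE_Q_THRESHOLD = 0.05
DC_TAIL = 0.01


def split_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Separate the gene_length column from a counts table."""
    if "gene_length" not in counts.columns:
        raise ValueError("counts table needs a gene_length column")
    lengths = counts["gene_length"]
    mat = counts.drop(columns="gene_length")
    return mat, lengths


def rpkm(mat: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    lib = mat.sum(axis=0)
    return mat.mul(1e9).div(lib, axis=1).div(lengths, axis=0)


def filter_low_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    threshold_rpkm: float = RPKM_THRESHOLD,
    min_fraction: float = 0.5,
    strict_all_groups: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop lowly expressed genes.

    A gene is kept iff, in at least one treatment x line group (or in
    every group with ``strict_all_groups``), at least ``min_fraction``
    of the group's samples exceed ``threshold_rpkm``. Returns the
    filtered counts (gene_length retained) and a log naming the group
    that rescued each kept gene.
    """
    mat, lengths = split_counts(counts)
    expr = rpkm(mat, lengths)
    meta = meta.set_index("sample").loc[mat.columns]
    groups = meta.groupby(["treatment", "line"]).groups
    frac = pd.DataFrame(
        {
            f"{t}|{ln}": (expr[list(samples)] > threshold_rpkm).mean(axis=1)
            for (t, ln), samples in groups.items()
        }
    )
    passes = frac >= min_fraction
    keep = passes.all(axis=1) if strict_all_groups else passes.any(axis=1)
    rescued = passes.idxmax(axis=1).where(keep, other=pd.NA)
    log = pd.DataFrame({"gene": mat.index, "kept": keep, "rescuing_group": rescued})
    return counts.loc[keep], log.reset_index(drop=True)


def size_factors(mat: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per sample: the median over reference genes of count / geometric
    mean count; genes with any zero are excluded from the reference.
    """
    logs = np.log(mat.where(mat > 0))
    ref_ok = mat.gt(0).all(axis=1)
    if not ref_ok.any():
        raise ValueError("no gene is nonzero in every sample; cannot normalize")
    log_gm = logs.loc[ref_ok].mean(axis=1)
    ratios = logs.loc[ref_ok].sub(log_gm, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def de_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str = "treatment",
    q_threshold: float = DE_Q_THRESHOLD,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test per gene.

    Counts are normalized by median-of-ratios size factors; a pooled
    moment estimate of the NB dispersion feeds a Wald test on the
    log2 fold change. DE call = BH q < 0.05, with no fold-change filter
    (small expression shifts can matter for behaviour).
    """
    mat, _ = split_counts(counts)
    meta = meta.set_index("sample").loc[mat.columns]
    levels = np.sort(meta[condition].unique())
    if len(levels) != 2:
        raise ValueError(f"{condition} must have exactly 2 levels, got {list(levels)}")
    g1 = mat.columns[meta[condition] == levels[0]]
    g2 = mat.columns[meta[condition] == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 samples per group")
    sf = size_factors(mat)
    norm_counts = mat.div(sf, axis=1)

    eps = 0.5
    m1 = norm_counts[g1].mean(axis=1) + eps
    m2 = norm_counts[g2].mean(axis=1) + eps
    # moment dispersion: Var = mu + alpha mu^2, pooled within groups
    v1 = norm_counts[g1].var(axis=1, ddof=1)
    v2 = norm_counts[g2].var(axis=1, ddof=1)
    alpha = ((v1 - m1) / m1**2 + (v2 - m2) / m2**2) / 2.0
    alpha = alpha.clip(lower=1e-8)
    # delta-method variance of log2 fold change
    var_log_m1 = (1.0 / m1 + alpha) / len(g1)
    var_log_m2 = (1.0 / m2 + alpha) / len(g2)
    lfc = np.log2(m2 / m1)
    se = np.sqrt(var_log_m1 + var_log_m2) / np.log(2.0)
    wald = lfc / se
    p = 2.0 * norm.sf(np.abs(wald))
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "gene": mat.index,
            "baseMean": (m1 + m2) / 2 - eps,
            "log2fc": lfc,
            "se": se,
            "stat": wald,
            "p": p,
            "q": q,
            "de": q < q_threshold,
        }
    ).set_index("gene")


@dataclass
class DCPair:
    gene_a: str
    gene_b: str
    r_a: float
    r_b: float
    statistic: float
    threshold: float
    significant: bool


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def _pair_scores(za: np.ndarray, zb: np.ndarray, iu) -> np.ndarray:
    return np.abs(za[iu] - zb[iu])


def dc_pairs(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    condition: str = "treatment",
    n_perm: int = 1000,
    tail: float = DC_TAIL,
    seed: int = 0,
    score: Optional[Callable] = None,
) -> tuple[list[DCPair], float]:
    """Differential co-expression by the pooled permutation rule.

    Pair statistic: |z(r_A) - z(r_B)| with Fisher-z Pearson correlations
    computed on log-normalized counts per condition (replaceable via
    ``score``). The null pools the statistic over all pairs across
    ``n_perm`` random permutations of the condition labels; a pair is
    significant iff its observed statistic exceeds the (1 - tail)
    quantile of that pooled null. Constant genes are skipped (their
    correlations are undefined) and reported in the third return value.
    Returns (significant pairs, threshold, skipped genes).
    """
    mat, _ = split_counts(counts)
    meta = meta.set_index("sample").loc[mat.columns]
    levels = np.sort(meta[condition].unique())
    if len(levels) != 2:
        raise ValueError(f"{condition} must have exactly 2 levels")
    labels = (meta[condition] == levels[1]).to_numpy()
    if labels.sum() < 4 or (~labels).sum() < 4:
        raise ValueError("need at least 4 samples per condition")
    sf = size_factors(mat)
    x = np.log(mat.div(sf, axis=1) + 1.0).to_numpy()
    # a gene flat in either condition has an undefined correlation there
    raw = mat.to_numpy()
    const_a = raw[:, ~labels].std(axis=1) == 0
    const_b = raw[:, labels].std(axis=1) == 0
    keep = (x.std(axis=1) > 0) & ~const_a & ~const_b
    const_genes = list(mat.index[~keep])
    x = x[keep]
    gene_names = mat.index[keep].to_numpy()
    n_genes = x.shape[0]
    iu = np.triu_indices(n_genes, k=1)

    def corr_z(cols_a, cols_b):
        ra = _corr_safe(x[:, cols_a])
        rb = _corr_safe(x[:, cols_b])
        return _fisher_z(ra), _fisher_z(rb), ra, rb

    obs_za, obs_zb, ra, rb = corr_z(~labels, labels)
    score_fn = score or (lambda za, zb: _pair_scores(za, zb, iu))
    obs = score_fn(obs_za, obs_zb)

    rng = np.random.default_rng(seed)
    n_a = int((~labels).sum())
    null_samples = []
    idx_all = np.arange(len(labels))
    for _ in range(n_perm):
        perm = rng.permutation(idx_all)
        pa, pb = perm[:n_a], perm[n_a:]
        za, zb, _, _ = corr_z(pa, pb)
        null_samples.append(score_fn(za, zb))
    null = np.concatenate(null_samples)
    threshold = float(np.quantile(null, 1.0 - tail))
    sig = obs > threshold
    pairs = [
        DCPair(
            gene_a=gene_names[i],
            gene_b=gene_names[j],
            r_a=float(ra[i, j]),
            r_b=float(rb[i, j]),
            statistic=float(s),
            threshold=threshold,
            significant=bool(s_),
        )
        for i, j, s, s_ in zip(iu[0], iu[1], obs, sig)
        if s_
    ]
    return pairs, threshold, const_genes


def _corr_safe(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    return np.nan_to_num(r, nan=0.0)


def dc_pair_table(pairs: list[DCPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "r_a": p.r_a,
                "r_b": p.r_b,
                "statistic": p.statistic,
                "threshold": p.threshold,
                "significant": p.significant,
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "r_a", "r_b", "statistic", "threshold", "significant"],
    )


def hcluster_samples(
    counts: pd.DataFrame,
    gene_subset: Optional[list] = None,
    method: str = "average",
) -> tuple[np.ndarray, list]:
    """Hierarchical clustering of samples over a gene subset.

    Euclidean distances between samples on log-normalized counts
    (log(count / size_factor + 1)); agglomeration by the given linkage
    method with scipy's deterministic tie handling; returns (linkage
    matrix, sample order as in a dendrogram left-to-right).
    """
    mat, _ = split_counts(counts)
    if gene_subset is not None:
        mat = mat.loc[gene_subset]
    if mat.shape[1] == 1:
        return np.empty((0, 4)), list(mat.columns)
    sf = size_factors(split_counts(counts)[0])
    x = np.log(mat.div(sf, axis=1) + 1.0).to_numpy().T  # samples x genes
    z = linkage(x, method=method, metric="euclidean")
    order = to_tree(z).pre_order(lambda leaf: leaf.id)
    return z, [mat.columns[i] for i in order]


def linkage_to_newick(z: np.ndarray, labels: list) -> str:
    """Export a scipy linkage tree as a Newick string."""
    if len(z) == 0:
        return f"({labels[0]});" if len(labels) == 1 else ";"
    tree = to_tree(z)

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def de_dc_intersection(de_table: pd.DataFrame, pairs: list[DCPair]) -> pd.DataFrame:
    """Genes that are both DE and members of >= 1 significant DC pair,
    with provenance (which pair brought them in)."""
    de_genes = set(de_table.index[de_table["de"]])
    rows = []
    for p in pairs:
        if not p.significant:
            continue
        for gene in (p.gene_a, p.gene_b):
            if gene in de_genes:
                rows.append((gene, f"{p.gene_a}~{p.gene_b}", p.statistic))
    return pd.DataFrame(rows, columns=["gene", "pair", "pair_statistic"]).drop_duplicates()
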