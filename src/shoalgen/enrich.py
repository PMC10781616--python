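"""GO-term overrepresentation and cross-experiment concordance.

Overrepresentation is a one-tail (greater) Fisher exact test per term
on the 2x2 (in gene set x carries term) table over a background
universe, Bonferroni-corrected within the family of testable terms
(those annotating at least one universe gene); significant iff adjusted
p < 0.05. The concordance statistic between two experiments is the
proportion of the test experiment's significantly enriched terms
(BP, CC and MF pooled) that are also enriched in the reference
experiment, benchmarked against the mean concordance of random gene
sets of the same size (the bootstrap null).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

BONFERRONI_ALPHA = 0.05


@dataclass
class AnnotationMap:
    """Gene -> GO-term map over an explicit background universe."""

    gene_terms: pd.DataFrame  # columns gene, term
    term_namespace: pd.DataFrame  # columns term, namespace
    universe: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        genes = set(self.gene_terms["gene"])
        if self.universe is None:
            self.universe = sorted(genes)
        else:
            self.universe = sorted(set(self.universe))
            extra = genes - set(self.universe)
            if extra:
                raise ValueError(
                    f"annotated genes outside the universe: {sorted(extra)[:5]}"
                )
        dup = self.term_namespace["term"].duplicated()
        if dup.any():
            raise ValueError("terms with multiple namespaces")
        self._terms = np.sort(self.gene_terms["term"].unique())
        self._gene_index = {g: i for i, g in enumerate(self.universe)}
        self._term_index = {t: i for i, t in enumerate(self._terms)}
        self._matrix = np.zeros((len(self.universe), len(self._terms)), dtype=bool)
        gi = self.gene_terms["gene"].map(self._gene_index).to_numpy()
        ti = self.gene_terms["term"].map(self._term_index).to_numpy()
        self._matrix[gi, ti] = True

    @property
    def terms(self) -> np.ndarray:
        return self._terms

    def namespace_of(self) -> pd.Series:
        return self.term_namespace.set_index("term")["namespace"]


def enrichment_test(
    gene_set: Sequence[str],
    annotation: AnnotationMap,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """One-tail Fisher overrepresentation for every testable term.

    p = P(X >= observed) under the hypergeometric null with the
    universe's margins; Bonferroni m = number of testable terms.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in annotation._gene_index]
    if missing:
        raise ValueError(f"genes outside the universe: {missing[:5]}")
    rows = [annotation._gene_index[g] for g in gene_set]
    big_n = len(annotation.universe)
    n = len(gene_set)
    term_totals = annotation._matrix.sum(axis=0)  # K per term
    observed = annotation._matrix[rows].sum(axis=0)  # k per term
    testable = term_totals >= 1
    m = int(testable.sum())
    # one-tail (greater): survival at k-1
    p = hypergeom.sf(observed - 1, big_n, term_totals, n)
    expected = n * term_totals / big_n
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
    adj = np.minimum(p * m, 1.0)
    ns = annotation.namespace_of().reindex(annotation.terms).to_numpy()
    out = pd.DataFrame(
        {
            "term": annotation.terms,
            "namespace": ns,
            "observed": observed,
            "expected": expected,
            "fold_enrichment": fold,
            "p": p,
            "p_bonferroni": adj,
            "significant": (adj < alpha) & testable,
            "n_tested": m,
        }
    )
    return out[testable].reset_index(drop=True)


def significant_terms(result: pd.DataFrame) -> set:
    return set(result.loc[result["significant"], "term"])


def concordance(
    reference_terms: Sequence[str],
    test_terms: Sequence[str],
    direction: str = "test_in_reference",
) -> float:
    """Proportion of enriched terms shared between two experiments.

    Default direction: the fraction of the test experiment's enriched
    terms that the reference experiment also flagged. The symmetric
    Jaccard variant is available for sensitivity analyses. An empty
    denominator set (no enriched terms) gives 0 by convention, so the
    statistic stays numeric for sparse annotations.
    """
    ref, test = set(reference_terms), set(test_terms)
    if direction == "test_in_reference":
        if not test:
            return 0.0
        return len(test & ref) / len(test)
    if direction == "jaccard":
        if not (ref | test):
            return 0.0
        return len(test & ref) / len(ref | test)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class ConcordanceReport:
    observed: float
    bootstrap_mean: float
    ci_low: float
    ci_high: float
    fold_increase: Optional[float]
    n_boot: int
    seed: int
    bootstrap_values: np.ndarray

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "bootstrap_mean": self.bootstrap_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fold_increase": self.fold_increase,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def concordance_bootstrap(
    reference_terms: Sequence[str],
    observed_concordance: float,
    set_size: int,
    annotation: AnnotationMap,
    n_boot: int = 1000,
    seed: int = 0,
    direction: str = "test_in_reference",
    alpha: float = BONFERRONI_ALPHA,
) -> ConcordanceReport:
    """Bootstrap null for the concordance statistic.

    Draws ``n_boot`` random gene sets of ``set_size`` (without
    replacement) from the universe, runs the enrichment test on each,
    and computes its concordance with the reference term list. Reports
    the null mean, percentile 95% CI and the fold increase
    observed / mean (flagged None when the mean is zero).
    """
    if set_size > len(annotation.universe):
        raise ValueError("set_size exceeds the universe")
    rng = np.random.default_rng(seed)
    universe = np.array(annotation.universe)
    values = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(universe, set_size, replace=False)
        res = enrichment_test(draw, annotation, alpha=alpha)
        values[b] = concordance(reference_terms, significant_terms(res), direction)
    finite = values[np.isfinite(values)]
    mean = float(finite.mean()) if finite.size else 0.0
    if finite.size:
        lo, hi = np.percentile(finite, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    fold = observed_concordance / mean if mean > 0 else None
    return ConcordanceReport(
        observed=observed_concordance,
        bootstrap_mean=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        fold_increase=fold,
        n_boot=n_boot,
        seed=seed,
        bootstrap_values=values,
    )


def read_annotation(gene_term_path, namespace_path, universe=None) -> AnnotationMap:
    """Load an AnnotationMap from two-column TSV files.

    ``gene_term_path``: gene<TAB>term per line; ``namespace_path``:
    term<TAB>namespace (BP/CC/MF). ``universe`` optionally widens the
    background beyond the annotated genes.
    """
    gt = pd.read_csv(gene_term_path, sep="\t", header=None, names=["gene", "term"])
    ns = pd.read_csv(namespace_path, sep="\t", header=None, names=["term", "namespace"])
    return AnnotationMap(gt, ns, universe=universe)


def write_annotation(annotation: AnnotationMap, gene_term_path, namespace_path) -> None:
    annotation.gene_terms.to_csv(gene_term_path, sep="\t", header=False, index=False)
    annotation.term_namespace.to_csv(namespace_path, sep="\t", header=False, index=False)
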