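"""Pooled allele-frequency association scan.

Works on Popoolation2-style "sync" tables: one row per genomic position
with per-pool read counts as A:T:C:G:N:del. Two scan modes mirror the
two analyses run on high- vs low-sociability DNA pools:

- merged mode: all high pools merged against all low pools, two-sided
  Fisher exact test per SNP; genome-wide significant iff -log10 p > 8.
- replicate mode: a Cochran–Mantel–Haenszel test across replicate
  high/low pool pairs (1-df chi-square, no continuity correction) with
  Benjamini–Hochberg correction; significant iff q < 0.01.

Also provided: the Popoolation2-style coverage/count filter, per-SNP FST
from pool read frequencies, SNP-to-gene interval overlap with a
promoter extension, and the phenotype-based selection of the top/bottom
family pools of mothers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

BASES = ["A", "T", "C", "G", "N", "del"]
GENOME_WIDE_NEGLOG10P = 8.0
CMH_Q_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# sync I/O


@dataclass
class SyncTable:
    """Per-SNP, per-pool base counts (sync dialect)."""

    chrom: np.ndarray  # (n,) str
    pos: np.ndarray  # (n,) int, 1-based
    ref: np.ndarray  # (n,) str
    counts: np.ndarray  # (n, n_pools, 6) int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("sync counts must be non-negative")
        if (self.pos < 1).any():
            raise ValueError("positions are 1-based (>= 1)")

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SyncTable)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )


def read_sync(path) -> SyncTable:
    """Parse a sync file; malformed rows raise with their line number."""
    chroms, poss, refs, counts = [], [], [], []
    n_pools = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 tab-separated fields")
            if n_pools is None:
                n_pools = len(fields) - 3
            elif len(fields) - 3 != n_pools:
                raise ValueError(f"line {lineno}: inconsistent pool count")
            try:
                pos = int(fields[1])
            except ValueError:
                raise ValueError(f"line {lineno}: position {fields[1]!r} is not an integer")
            row = []
            for pool_field in fields[3:]:
                parts = pool_field.split(":")
                if len(parts) != 6:
                    raise ValueError(
                        f"line {lineno}: pool field {pool_field!r} must have 6 ':'-separated counts"
                    )
                try:
                    row.append([int(p) for p in parts])
                except ValueError:
                    raise ValueError(f"line {lineno}: non-integer count in {pool_field!r}")
            chroms.append(fields[0])
            poss.append(pos)
            refs.append(fields[2])
            counts.append(row)
    if not chroms:
        raise ValueError("empty sync file")
    return SyncTable(
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs),
        counts=np.array(counts, dtype=int),
    )


def write_sync(table: SyncTable, path) -> None:
    with open(path, "w") as fh:
        for i in range(table.n_snps):
            pools = "\t".join(
                ":".join(str(c) for c in table.counts[i, j]) for j in range(table.n_pools)
            )
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t{pools}\n")


# ---------------------------------------------------------------------------
# filtering and allele reduction


def major_minor_alleles(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the two highest-count true bases (A/T/C/G) summed over
    pools; N and deletions never form the test pair."""
    acgt = counts[:, :, :4].sum(axis=1)  # (n, 4)
    order = np.argsort(-acgt, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


def filter_snps(
    table: SyncTable,
    min_count: int = 6,
    min_coverage: int = 25,
    max_coverage: int = 200,
    pools: Optional[Sequence[int]] = None,
) -> tuple[SyncTable, pd.DataFrame]:
    """Coverage / minor-count filter in the Popoolation2 style.

    A SNP is kept iff every pool's coverage (sum of A/T/C/G reads) lies
    in [min_coverage, max_coverage] and the minor allele's count summed
    over the pools in the comparison is >= min_count. Returns the
    filtered table and a per-SNP log with the failure reason.
    """
    if min_count < 1 or min_coverage < 1 or max_coverage < min_coverage:
        raise ValueError("thresholds must be positive with max_coverage >= min_coverage")
    sel = np.arange(table.n_pools) if pools is None else np.asarray(pools)
    counts = table.counts[:, sel, :]
    coverage = counts[:, :, :4].sum(axis=2)  # (n, n_pools)
    maj, mnr = major_minor_alleles(counts)
    idx = np.arange(table.n_snps)
    minor_total = counts[:, :, :4].sum(axis=1)[idx, mnr]
    reason = np.array([""] * table.n_snps, dtype=object)
    low = (coverage < min_coverage).any(axis=1)
    high = (coverage > max_coverage).any(axis=1)
    small = minor_total < min_count
    reason[small] = "min-count"
    reason[high] = "max-coverage"
    reason[low] = "min-coverage"  # precedence: coverage first
    keep = ~(low | high | small)
    log = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "kept": keep,
            "reason": reason,
        }
    )
    filtered = SyncTable(
        chrom=table.chrom[keep],
        pos=table.pos[keep],
        ref=table.ref[keep],
        counts=table.counts[keep],
    )
    return filtered, log


# ---------------------------------------------------------------------------
# association tests


def _fisher_two_sided(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for 2x2 tables [[a, b], [c, d]].

    Two-sided by summation of hypergeometric point probabilities no
    larger than the observed one (the conventional definition).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    c = np.asarray(c, dtype=int)
    d = np.asarray(d, dtype=int)
    m = a + b  # row 1 margin
    n_ = c + d
    k = a + c  # column 1 margin
    kmax = int(np.max(k, initial=0))

    def loghyp(x, m, n_, k):
        return (
            gammaln(m + 1)
            - gammaln(x + 1)
            - gammaln(m - x + 1)
            + gammaln(n_ + 1)
            - gammaln(k - x + 1)
            - gammaln(n_ - (k - x) + 1)
            - (gammaln(m + n_ + 1) - gammaln(k + 1) - gammaln(m + n_ - k + 1))
        )

    p = np.empty(a.shape, dtype=float)
    xs = np.arange(kmax + 1)
    lo = np.maximum(0, k - n_)
    hi = np.minimum(k, m)
    # support mask per table over candidate x
    support = (xs[None, :] >= lo[:, None]) & (xs[None, :] <= hi[:, None])
    lp = np.where(
        support,
        loghyp(xs[None, :], m[:, None], n_[:, None], k[:, None]),
        -np.inf,
    )
    lobs = loghyp(a, m, n_, k)
    inc = lp <= lobs[:, None] + 1e-7  # tolerance for ties in log space
    p = np.exp(lp, where=np.isfinite(lp), out=np.zeros_like(lp))
    p = (p * (inc & support)).sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_scan(
    table: SyncTable,
    high_pools: Sequence[int],
    low_pools: Sequence[int],
    threshold_neglog10p: float = GENOME_WIDE_NEGLOG10P,
) -> pd.DataFrame:
    """Merged-pool Fisher exact scan.

    High pools are merged by summing read counts, likewise low pools;
    each SNP's 2x2 major/minor x high/low count table gets a two-sided
    Fisher exact test. Significant iff -log10 p > threshold (default 8,
    the traditional genome-wide threshold).
    """
    maj, mnr = major_minor_alleles(table.counts)
    idx = np.arange(table.n_snps)
    high = table.counts[:, list(high_pools), :4].sum(axis=1)
    low = table.counts[:, list(low_pools), :4].sum(axis=1)
    a, b = high[idx, maj], high[idx, mnr]
    c, d = low[idx, maj], low[idx, mnr]
    p = _fisher_two_sided(a, b, c, d)
    neglog = -np.log10(np.maximum(p, 1e-300))
    tot_high = np.maximum(a + b, 1)
    tot_low = np.maximum(c + d, 1)
    return pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "major": np.array(BASES)[maj],
            "minor": np.array(BASES)[mnr],
            "freq_high": a / tot_high,
            "freq_low": c / tot_low,
            "p": p,
            "neglog10p": neglog,
            "significant": neglog > threshold_neglog10p,
        }
    )


def cmh_scan(
    table: SyncTable,
    strata: Sequence[tuple[int, int]],
    q_threshold: float = CMH_Q_THRESHOLD,
) -> pd.DataFrame:
    """Replicate-stratified Cochran–Mantel–Haenszel scan.

    ``strata`` lists (high_pool, low_pool) index pairs, one per
    replicate line. Per SNP: CMH chi-square (1 df, no continuity
    correction) on the stacked 2x2 tables, the Mantel–Haenszel common
    odds ratio, and BH-FDR q-values; significant iff q < 0.01.
    """
    if len(strata) < 1:
        raise ValueError("need at least one high/low stratum")
    maj, mnr = major_minor_alleles(table.counts)
    idx = np.arange(table.n_snps)
    num = np.zeros(table.n_snps)
    var = np.zeros(table.n_snps)
    or_num = np.zeros(table.n_snps)
    or_den = np.zeros(table.n_snps)
    for hi, lo in strata:
        a = table.counts[idx, hi, :4][idx, maj].astype(float)
        b = table.counts[idx, hi, :4][idx, mnr].astype(float)
        c = table.counts[idx, lo, :4][idx, maj].astype(float)
        d = table.counts[idx, lo, :4][idx, mnr].astype(float)
        n = a + b + c + d
        with np.errstate(invalid="ignore", divide="ignore"):
            num += a - (a + b) * (a + c) / n
            var += (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
            or_num += a * d / n
            or_den += b * c / n
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = num**2 / var
        odds = or_num / or_den
    p = chi2.sf(stat, df=1)
    p = np.where(np.isfinite(stat), p, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "major": np.array(BASES)[maj],
            "minor": np.array(BASES)[mnr],
            "cmh_stat": stat,
            "p": p,
            "neglog10p": -np.log10(np.maximum(p, 1e-300)),
            "q": q,
            "odds_ratio": odds,
            "significant": q < q_threshold,
        }
    )


def fst_scan(table: SyncTable, pool_a: int, pool_b: int) -> pd.DataFrame:
    """Per-SNP FST from pool read frequencies.

    Classical heterozygosity partition: FST = (h_T - mean(h_S)) / h_T
    with h = 2 p (1 - p); p from major-allele read fractions. 0 when the
    pools agree, 1 at a fixed difference; NaN when h_T = 0.
    """
    maj, mnr = major_minor_alleles(table.counts)
    idx = np.arange(table.n_snps)
    out = {}
    freqs = []
    for pool in (pool_a, pool_b):
        cmaj = table.counts[idx, pool, :4][idx, maj].astype(float)
        cmnr = table.counts[idx, pool, :4][idx, mnr].astype(float)
        tot = cmaj + cmnr
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(tot > 0, cmaj / tot, np.nan))
    p1, p2 = freqs
    pbar = 0.5 * (p1 + p2)
    h_t = 2 * pbar * (1 - pbar)
    h_s = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / h_t, np.where(p1 == p2, 0.0, np.nan))
    return pd.DataFrame(
        {"chrom": table.chrom, "pos": table.pos, "freq_a": p1, "freq_b": p2, "fst": fst}
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene overlap


@dataclass
class GeneIntervalSet:
    """Gene bodies (1-based, inclusive) with strand for promoter extension."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValueError("gene start must be <= end")
        bad = ~t["strand"].isin(["+", "-", "."])
        if bad.any():
            raise ValueError("strand must be '+', '-' or '.'")


def read_gene_intervals(path, fmt: str = "gff3") -> GeneIntervalSet:
    """Read gene intervals from GFF3 (1-based inclusive) or BED (0-based
    half-open, converted)."""
    if fmt == "gff3":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=[
                "chrom",
                "source",
                "type",
                "start",
                "end",
                "score",
                "strand",
                "phase",
                "attributes",
            ],
        )
        df = df[df["type"] == "gene"].copy()
        df["gene_id"] = (
            df["attributes"]
            .str.extract(r"ID=([^;]+)")[0]
            .fillna(df["attributes"])
        )
    elif fmt == "bed":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
        )
        df["start"] = df["start"] + 1  # to 1-based inclusive
        df["strand"] = df.get("strand", pd.Series(["."] * len(df))).fillna(".")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return GeneIntervalSet(df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True))


def overlap_genes(
    snps: pd.DataFrame,
    genes: GeneIntervalSet,
    promoter_bp: int = 1000,
) -> pd.DataFrame:
    """Assign SNPs to genes whose body or promoter contains them.

    Promoters extend ``promoter_bp`` upstream of the transcription start
    (strand-aware; unstranded genes get extensions on both sides).
    ``snps`` needs columns chrom, pos. Every SNP appears at least once;
    unassigned SNPs carry gene_id = NaN.
    """
    gt = genes.table.copy()
    up = gt["strand"] != "-"
    down = gt["strand"] != "+"
    gt["ext_start"] = gt["start"] - np.where(up, promoter_bp, 0)
    gt["ext_end"] = gt["end"] + np.where(down, promoter_bp, 0)
    records = []
    for chrom, sdf in snps.groupby("chrom", sort=False):
        gdf = gt[gt["chrom"] == chrom]
        pos = sdf["pos"].to_numpy()
        for _, g in gdf.iterrows():
            inside = (pos >= g["ext_start"]) & (pos <= g["ext_end"])
            for p in pos[inside]:
                in_body = g["start"] <= p <= g["end"]
                records.append((chrom, int(p), g["gene_id"], "body" if in_body else "promoter"))
    hits = pd.DataFrame(records, columns=["chrom", "pos", "gene_id", "where"])
    out = snps[["chrom", "pos"]].merge(hits, on=["chrom", "pos"], how="left")
    return out


# ---------------------------------------------------------------------------
# phenotype-based pool selection


def select_family_pools(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    quantile: float = 0.25,
    pool_size: int = 7,
    trait: str = "phenotype",
    regime: str = "polarization",
) -> pd.DataFrame:
    """Pick mothers for the high/low DNA pools per selected line.

    The family score is the mean of the mother's and her daughters'
    alignment phenotypes, z-scored within line; per line the mothers of
    the top-quantile and bottom-quantile families are listed, truncated
    or padded by rank to exactly ``pool_size``. Ties break by family id
    (deterministic); fully tied lines are flagged.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    ped = pedigree.set_index("id")
    phe = phenotypes.set_index("id")
    fam_rows = []
    for fam, members in pedigree[pedigree["regime"] == regime].groupby("family"):
        mother = members[(members["generation"] == "parent") & (members["sex"] == "F")]
        daughters = members[(members["generation"] == "offspring") & (members["sex"] == "F")]
        ids = list(mother["id"]) + list(daughters["id"])
        vals = phe.reindex(ids)[trait].dropna()
        if vals.empty or mother.empty:
            continue
        fam_rows.append(
            (fam, int(members["line"].iloc[0]), int(mother["id"].iloc[0]), vals.mean())
        )
    fams = pd.DataFrame(fam_rows, columns=["family", "line", "mother_id", "score"])
    out = []
    for line, ldf in fams.groupby("line"):
        sd = ldf["score"].std(ddof=0)
        degenerate = not np.isfinite(sd) or sd == 0
        z = (ldf["score"] - ldf["score"].mean()) / (sd if not degenerate else 1.0)
        ldf = ldf.assign(zscore=z).sort_values(
            ["zscore", "family"], ascending=[False, True]
        )
        # the quantile defines the candidate set; rank then truncates or
        # pads it to the fixed pool size
        n_take = min(pool_size, len(ldf))
        high = ldf.head(n_take).assign(pool="high")
        low = ldf.tail(n_take).iloc[::-1].assign(pool="low")
        sel = pd.concat([high, low])
        sel["tie_degenerate"] = degenerate
        out.append(sel)
    return pd.concat(out, ignore_index=True)


def manhattan_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Manhattan-ready export: one finite -log10 p per retained SNP."""
    out = scan[["chrom", "pos", "neglog10p"]].copy()
    if not np.isfinite(out["neglog10p"]).all():
        raise ValueError("non-finite -log10 p in scan output")
    if out.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate SNP rows in scan output")
    return out
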