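"""Sync I/O, filters, Fisher/CMH/FST statistics against enumeration and
closed-form oracles, and the family-pool selection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, fisher_exact

from shoalgen import poolseq as ps
from shoalgen import synthdata as sd


def make_table(counts, chrom=None, pos=None, ref=None):
    counts = np.asarray(counts, dtype=int)
    n = counts.shape[0]
    return ps.SyncTable(
        chrom=np.array(chrom or ["chr1"] * n),
        pos=np.array(pos if pos is not None else np.arange(1, n + 1)),
        ref=np.array(ref or ["A"] * n),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# sync I/O


def test_read_sync_example(tmp_path):
    p = tmp_path / "x.sync"
    p.write_text("chr1\t5\tT\t10:0:0:20:0:0\t8:0:0:22:0:0\n")
    t = ps.read_sync(p)
    assert t.n_snps == 1 and t.n_pools == 2
    assert t.chrom[0] == "chr1" and t.pos[0] == 5 and t.ref[0] == "T"
    assert t.counts[0, 0, 0] == 10 and t.counts[0, 1, 3] == 22


def test_read_sync_malformed_field_names_line(tmp_path):
    p = tmp_path / "bad.sync"
    p.write_text("chr1\t5\tT\t10:0:0:20:0:0\nchr1\t6\tT\t1:2:3:4:5\n")
    with pytest.raises(ValueError, match="line 2"):
        ps.read_sync(p)


def test_sync_roundtrip_identical(tmp_path):
    table, _ = sd.simulate_poolseq(1000, n_causal=10, shift=0.2, seed=1)
    f = tmp_path / "t.sync"
    ps.write_sync(table, f)
    assert ps.read_sync(f) == table
    # byte-for-byte stability of write(read(write(x)))
    f2 = tmp_path / "t2.sync"
    ps.write_sync(ps.read_sync(f), f2)
    assert f.read_text() == f2.read_text()


# ---------------------------------------------------------------------------
# filters


def fixture_counts():
    """20 SNPs with known filter violations (2 pools)."""
    rows = []
    for i in range(20):
        a1, g1, a2, g2 = 40, 20, 35, 25
        if i == 3:
            a1, g1 = 20, 4  # pool 1 coverage 24 < 25
        if i == 7:
            a1, g1, a2, g2 = 57, 3, 58, 2  # minor total 5 < 6
        if i == 11:
            a1, g1 = 180, 30  # pool 1 coverage 210 > 200
        rows.append([[a1, 0, 0, g1, 0, 0], [a2, 0, 0, g2, 0, 0]])
    return rows


def test_filter_matches_hand_enumeration():
    table = make_table(fixture_counts())
    filt, log = ps.filter_snps(table, min_count=6, min_coverage=25, max_coverage=200)
    dropped = set(log.loc[~log["kept"], "pos"])
    assert dropped == {4, 8, 12}  # 1-based positions of SNPs 3, 7, 11
    assert log.set_index("pos").loc[4, "reason"] == "min-coverage"
    assert log.set_index("pos").loc[8, "reason"] == "min-count"
    assert log.set_index("pos").loc[12, "reason"] == "max-coverage"
    assert filt.n_snps == 17


def test_filter_idempotent():
    table = make_table(fixture_counts())
    once, _ = ps.filter_snps(table)
    twice, _ = ps.filter_snps(once)
    assert once == twice


def test_filter_rejects_bad_thresholds():
    table = make_table(fixture_counts())
    with pytest.raises(ValueError):
        ps.filter_snps(table, min_coverage=50, max_coverage=25)


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_balanced_table_p_one():
    t = make_table([[[10, 0, 0, 10, 0, 0], [10, 0, 0, 10, 0, 0]]])
    res = ps.fisher_scan(t, [0], [1])
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    t = make_table([[[90, 0, 0, 10, 0, 0], [60, 0, 0, 40, 0, 0]]])
    res = ps.fisher_scan(t, [0], [1])
    # independent oracle: full hypergeometric enumeration
    from math import comb

    m, n_, k = 100, 100, 150  # margins of [[90,10],[60,40]]
    total = comb(m + n_, k)
    probs = {
        x: comb(m, x) * comb(n_, k - x) / total
        for x in range(max(0, k - n_), min(k, m) + 1)
    }
    p_obs = probs[90]
    oracle = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    assert res["p"].iloc[0] == pytest.approx(oracle, abs=1e-12)


def test_fisher_agrees_with_scipy_on_random_tables(rng):
    tabs = rng.integers(0, 40, size=(200, 4))
    ours = ps._fisher_two_sided(tabs[:, 0], tabs[:, 1], tabs[:, 2], tabs[:, 3])
    for row, p in zip(tabs, ours):
        ref = fisher_exact([[row[0], row[1]], [row[2], row[3]]])[1]
        assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_significance_threshold_at_8():
    res = pd.DataFrame({"neglog10p": [8.3, 7.9]})
    assert (res["neglog10p"] > ps.GENOME_WIDE_NEGLOG10P).tolist() == [True, False]
    # end-to-end: a huge frequency difference crosses the threshold
    t = make_table([[[500, 0, 0, 0, 0, 0], [250, 0, 0, 250, 0, 0]]])
    scan = ps.fisher_scan(t, [0], [1])
    assert bool(scan["significant"].iloc[0])


def test_scans_invariant_to_allele_label_swap():
    counts = np.array([[[30, 0, 0, 12, 0, 0], [20, 0, 0, 25, 0, 0]]])
    swapped = counts[:, :, [3, 1, 2, 0, 4, 5]]
    a, b = make_table(counts), make_table(swapped)
    assert ps.fisher_scan(a, [0], [1])["p"].iloc[0] == pytest.approx(
        ps.fisher_scan(b, [0], [1])["p"].iloc[0], rel=1e-12
    )
    big = np.repeat(counts, 2, axis=1)  # 4 pools for a 2-strata CMH
    bigsw = big[:, :, [3, 1, 2, 0, 4, 5]]
    pa = ps.cmh_scan(make_table(big), [(0, 1), (2, 3)])["p"].iloc[0]
    pb = ps.cmh_scan(make_table(bigsw), [(0, 1), (2, 3)])["p"].iloc[0]
    assert pa == pytest.approx(pb, rel=1e-12)
    fa = ps.fst_scan(make_table(counts), 0, 1)["fst"].iloc[0]
    fb = ps.fst_scan(make_table(swapped), 0, 1)["fst"].iloc[0]
    assert fa == pytest.approx(fb, rel=1e-12)


# ---------------------------------------------------------------------------
# CMH


def test_cmh_identical_proportions_null():
    counts = [[[40, 0, 0, 20, 0, 0]] * 6]
    res = ps.cmh_scan(make_table(counts), [(0, 1), (2, 3), (4, 5)])
    assert res["odds_ratio"].iloc[0] == pytest.approx(1.0)
    assert res["p"].iloc[0] == pytest.approx(1.0)


def test_cmh_single_stratum_reduces_to_chisquare():
    counts = [[[50, 0, 0, 14, 0, 0], [30, 0, 0, 29, 0, 0]]]
    res = ps.cmh_scan(make_table(counts), [(0, 1)])
    table = np.array([[50, 14], [30, 29]])
    chi2_stat = chi2_contingency(table, correction=False)[0]
    # CMH uses the N-1 (hypergeometric-variance) convention
    n = table.sum()
    assert res["cmh_stat"].iloc[0] == pytest.approx(chi2_stat * (n - 1) / n, rel=1e-12)


def test_cmh_three_strata_matches_textbook_formula():
    strata_counts = [
        [[45, 0, 0, 15, 0, 0], [30, 0, 0, 30, 0, 0],
         [50, 0, 0, 10, 0, 0], [35, 0, 0, 25, 0, 0],
         [42, 0, 0, 18, 0, 0], [28, 0, 0, 30, 0, 0]]
    ]
    res = ps.cmh_scan(make_table(strata_counts), [(0, 1), (2, 3), (4, 5)])
    num = 0.0
    var = 0.0
    for a, b, c, d in [(45, 15, 30, 30), (50, 10, 35, 25), (42, 18, 28, 30)]:
        n = a + b + c + d
        num += a - (a + b) * (a + c) / n
        var += (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    from scipy.stats import chi2 as chi2_dist

    stat = num**2 / var
    assert res["cmh_stat"].iloc[0] == pytest.approx(stat, rel=1e-12)
    assert res["p"].iloc[0] == pytest.approx(chi2_dist.sf(stat, 1), rel=1e-12)


# ---------------------------------------------------------------------------
# FST


@pytest.mark.parametrize(
    "c1,c2,expected",
    [
        ((30, 30), (10, 10), 0.0),  # equal frequencies
        ((60, 0), (0, 60), 1.0),  # fixed difference
        ((48, 12), (24, 36), (0.48 - 0.4) / 0.48),  # p=0.8 vs 0.4 closed form
    ],
)
def test_fst_closed_forms(c1, c2, expected):
    counts = [[[c1[0], 0, 0, c1[1], 0, 0], [c2[0], 0, 0, c2[1], 0, 0]]]
    res = ps.fst_scan(make_table(counts), 0, 1)
    assert res["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# BH-FDR


def test_bh_fdr_step_up_arithmetic():
    assert ps.bh_fdr([0.02])[0] == pytest.approx(0.02)
    np.testing.assert_allclose(ps.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(ps.bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)


# ---------------------------------------------------------------------------
# gene overlap


def test_overlap_body_and_promoter():
    genes = ps.GeneIntervalSet(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [1000, 5000],
                "end": [2000, 6000],
                "strand": ["+", "-"],
            }
        )
    )
    snps = pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [1500, 500, 6500, 3000]})
    hits = ps.overlap_genes(snps, genes, promoter_bp=1000)
    by_pos = hits.set_index("pos")
    assert by_pos.loc[1500, "gene_id"] == "gA" and by_pos.loc[1500, "where"] == "body"
    assert by_pos.loc[500, "gene_id"] == "gA" and by_pos.loc[500, "where"] == "promoter"
    assert by_pos.loc[6500, "gene_id"] == "gB" and by_pos.loc[6500, "where"] == "promoter"
    assert by_pos.loc[3000].isna()["gene_id"]  # intergenic, outside promoters


def test_overlap_matches_bruteforce_oracle(rng):
    starts = np.sort(rng.integers(1, 100000, 10))
    genes = ps.GeneIntervalSet(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "chrom": ["chr1"] * 10,
                "start": starts,
                "end": starts + rng.integers(500, 3000, 10),
                "strand": rng.choice(["+", "-"], 10),
            }
        )
    )
    snps = pd.DataFrame({"chrom": ["chr1"] * 50, "pos": rng.integers(1, 105000, 50)})
    hits = ps.overlap_genes(snps, genes, promoter_bp=1000)
    got = set(
        (int(r.pos), r.gene_id) for r in hits.itertuples() if isinstance(r.gene_id, str)
    )
    expected = set()
    for p in snps["pos"]:
        for g in genes.table.itertuples():
            s = g.start - (1000 if g.strand == "+" else 0)
            e = g.end + (1000 if g.strand == "-" else 0)
            if s <= p <= e:
                expected.add((int(p), g.gene_id))
    assert got == expected


def test_gff3_and_bed_coordinate_conventions(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
        "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1\n"
    )
    bed = tmp_path / "g.bed"
    bed.write_text("chr1\t100\t200\tgeneA\t0\t+\n")
    a = ps.read_gene_intervals(gff, fmt="gff3").table
    b = ps.read_gene_intervals(bed, fmt="bed").table
    assert a.loc[0, "start"] == 101 and a.loc[0, "end"] == 200
    assert b.loc[0, "start"] == 101 and b.loc[0, "end"] == 200


# ---------------------------------------------------------------------------
# pool selection


def build_family_data(n_fam_per_line=28, lines=(0, 1, 2), seed=5):
    rng = np.random.default_rng(seed)
    rows, prows = [], []
    fid = 0
    nid = 0
    for line in lines:
        for _ in range(n_fam_per_line):
            mother = nid
            rows.append((mother, -1, -1, "F", line, "polarization", "parent", fid))
            nid += 1
            score = rng.normal()
            prows.append((mother, score + 0.1 * rng.normal()))
            for d in range(3):
                rows.append((nid, -1, mother, "F", line, "polarization", "offspring", fid))
                prows.append((nid, score + 0.1 * rng.normal()))
                nid += 1
            fid += 1
    ped = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "line", "regime", "generation", "family"]
    )
    phen = pd.DataFrame(prows, columns=["id", "phenotype"])
    return ped, phen


def test_pool_selection_sizes_and_planted_recovery():
    ped, phen = build_family_data()
    # plant extreme families in line 0
    fam_high = ped[(ped.line == 0)]["family"].unique()[:2]
    phen.loc[phen["id"].isin(ped[ped.family.isin(fam_high)]["id"]), "phenotype"] += 10
    sel = ps.select_family_pools(phen, ped, quantile=0.25, pool_size=7)
    for line in (0, 1, 2):
        for pool in ("high", "low"):
            assert ((sel.line == line) & (sel.pool == pool)).sum() == 7
    high0 = set(sel[(sel.line == 0) & (sel.pool == "high")]["family"])
    assert set(fam_high) <= high0
    assert not sel["tie_degenerate"].any()


def test_pool_selection_tie_degenerate_flag():
    ped, phen = build_family_data(n_fam_per_line=10, lines=(0,))
    phen["phenotype"] = 1.0
    sel = ps.select_family_pools(phen, ped, pool_size=3)
    assert sel["tie_degenerate"].all()
    # deterministic rank-by-family-id tie-break
    assert sel[sel.pool == "high"]["family"].tolist() == [0, 1, 2]


def test_manhattan_export_unique_finite():
    table, _ = sd.simulate_poolseq(500, seed=8)
    filt, _ = ps.filter_snps(table)
    scan = ps.fisher_scan(filt, [0, 2, 4], [1, 3, 5])
    man = ps.manhattan_table(scan)
    assert len(man) == filt.n_snps
    assert np.isfinite(man["neglog10p"]).all()
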