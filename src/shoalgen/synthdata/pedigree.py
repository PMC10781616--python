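"""Pedigree, breeding-value and phenotype generators.

The pedigree is a set of independent nuclear families: unrelated founder
pairs (mother, father) and ``offspring_per_sex`` offspring of each sex,
spread over replicate polarization-selected and control lines.

Breeding values are bivariate (a female-trait and a male-trait component
per individual, the one matching the individual's sex being expressed):
founders are drawn from N(0, G) with G the cross-sex additive covariance,
offspring are mid-parent plus a Mendelian sampling deviation with
covariance G/2 (non-inbred, unrelated founders).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from shoalgen.synthdata.config import SimConfig

PEDIGREE_COLUMNS = [
    "id",
    "sire",
    "dam",
    "sex",
    "line",
    "regime",
    "generation",
    "family",
]


@dataclass
class TruthRecord:
    """Ground truth for recovery tests; one entry per simulated unit."""

    breeding_values: Optional[pd.DataFrame] = None  # id, bv_f, bv_m, bv_expressed
    snp_truth: Optional[pd.DataFrame] = None  # snp index, causal flag, shift
    gene_truth: Optional[pd.DataFrame] = None  # gene, de flag, true log2 fc
    pair_truth: Optional[pd.DataFrame] = None  # gene_a, gene_b, dc flag
    extras: dict = field(default_factory=dict)


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Simulate the nuclear-family breeding design.

    Returns a table with one row per individual: founders (generation
    'parent') have unknown parents (-1); each offspring has the family's
    sire and dam. Families are assigned round-robin to lines so that
    ``n_families_total`` spreads as evenly as possible over the
    ``2 * n_lines_per_regime`` lines.
    """
    n_lines = 2 * config.n_lines_per_regime
    fam_line = np.arange(config.n_families_total) % n_lines
    regimes = np.array(["polarization", "control"])
    rows = []
    next_id = 0
    for fam in range(config.n_families_total):
        line = int(fam_line[fam])
        regime = regimes[line // config.n_lines_per_regime]
        sire_id, dam_id = next_id, next_id + 1
        rows.append((sire_id, -1, -1, "M", line, regime, "parent", fam))
        rows.append((dam_id, -1, -1, "F", line, regime, "parent", fam))
        next_id += 2
        for sex in ("F", "M"):
            for _ in range(config.offspring_per_sex):
                rows.append((next_id, sire_id, dam_id, sex, line, regime, "offspring", fam))
                next_id += 1
    ped = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    return ped


def simulate_breeding_values(
    ped: pd.DataFrame, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> TruthRecord:
    """Draw bivariate breeding values down the pedigree.

    Founders ~ N(0, G); offspring = (bv_sire + bv_dam)/2 + m with
    m ~ N(0, G/2). The expressed component matches the individual's sex.
    """
    g = config.genetic_covariance
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(ped)
    order = _topological_order(ped)
    bv = np.zeros((n, 2))
    idx_of = pd.Series(np.arange(n), index=ped["id"].to_numpy())
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    # Cholesky factors; a zero matrix has a zero factor.
    chol_g = _safe_cholesky(g)
    chol_m = _safe_cholesky(g / 2.0)
    for i in order:
        if sire[i] < 0 and dam[i] < 0:
            bv[i] = chol_g @ rng.standard_normal(2)
        else:
            mid = 0.5 * (bv[idx_of[sire[i]]] + bv[idx_of[dam[i]]])
            bv[i] = mid + chol_m @ rng.standard_normal(2)
    sex_col = (ped["sex"].to_numpy() == "M").astype(int)
    table = pd.DataFrame(
        {
            "id": ped["id"].to_numpy(),
            "bv_f": bv[:, 0],
            "bv_m": bv[:, 1],
            "bv_expressed": bv[np.arange(n), sex_col],
        }
    )
    return TruthRecord(breeding_values=table)


def simulate_phenotypes(
    ped: pd.DataFrame,
    truth: TruthRecord,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate sociability phenotypes on top of breeding values.

    phenotype = intercept + fixed effects + expressed BV + line + family
    + group-use + residual. The wild-type stimulus-group activity
    covariate is simulated standard-normal; each assay is assigned a
    group-use count 1..max_group_uses cycling through assays, mirroring
    stimulus groups being reused for up to seven trials.
    """
    if truth.breeding_values is None:
        raise ValueError("truth has no breeding values; run simulate_breeding_values")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fe = config.fixed_effects
    n = len(ped)
    sex_m = (ped["sex"] == "M").to_numpy()
    regime_sel = (ped["regime"] == "polarization").to_numpy()
    offspring = (ped["generation"] == "offspring").to_numpy()
    lines = ped["line"].to_numpy()
    fams = ped["family"].to_numpy()

    line_eff = rng.normal(0.0, np.sqrt(config.v_line), lines.max() + 1)
    fam_eff = rng.normal(0.0, np.sqrt(config.v_family), fams.max() + 1)
    gu_eff = rng.normal(0.0, np.sqrt(config.v_groupuse), config.max_group_uses)
    group_use = rng.integers(1, config.max_group_uses + 1, size=n)
    activity = rng.standard_normal(n)
    res_sd = np.where(sex_m, np.sqrt(config.v_res_m), np.sqrt(config.v_res_f))

    y = (
        fe.intercept
        + np.where(sex_m, fe.regime_m, fe.regime_f) * regime_sel
        + fe.sex * sex_m
        + fe.generation * offspring
        + fe.activity_slope * activity
        + truth.breeding_values["bv_expressed"].to_numpy()
        + line_eff[lines]
        + fam_eff[fams]
        + gu_eff[group_use - 1]
        + rng.standard_normal(n) * res_sd
    )
    out = ped[["id", "sex", "line", "regime", "generation", "family"]].copy()
    out["phenotype"] = y
    out["group_activity"] = activity
    out["group_use"] = group_use
    truth.extras["line_effects"] = line_eff
    truth.extras["family_effects"] = fam_eff
    return out


def _topological_order(ped: pd.DataFrame) -> np.ndarray:
    """Order individuals parents-before-offspring; raise on cycles."""
    idx_of = pd.Series(np.arange(len(ped)), index=ped["id"].to_numpy())
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    n = len(ped)
    state = np.zeros(n, dtype=int)  # 0 unvisited, 1 in stack, 2 done
    order: list[int] = []

    for start in range(n):
        if state[start] == 2:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise ValueError("pedigree contains a cycle")
            state[node] = 1
            stack.append((node, True))
            for parent in (sire[node], dam[node]):
                if parent >= 0:
                    p = int(idx_of[parent])
                    if state[p] == 1:
                        raise ValueError("pedigree contains a cycle")
                    if state[p] == 0:
                        stack.append((p, False))
    return np.array(order)


def _safe_cholesky(m: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerating PSD (rank-deficient) matrices."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        w = np.clip(w, 0.0, None)
        return v @ np.diag(np.sqrt(w))
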