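"""Numerator (additive) relationship matrices from pedigrees."""

from __future__ import annotations

import numpy as np
import pandas as pd

from shoalgen.synthdata.pedigree import _topological_order


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check structural invariants: parent sexes, presence, acyclicity."""
    ids = set(ped["id"].to_numpy())
    sex_of = dict(zip(ped["id"], ped["sex"]))
    for col, want in (("sire", "M"), ("dam", "F")):
        parents = ped[col].to_numpy()
        known = parents[parents >= 0]
        missing = [p for p in known if p not in ids]
        if missing:
            raise ValueError(f"{col} ids absent from pedigree: {missing[:5]}")
        bad = [p for p in known if sex_of[p] != want]
        if bad:
            raise ValueError(f"{col}s must have sex {want}: ids {sorted(set(bad))[:5]}")
    _topological_order(ped)  # raises on cycles


def build_A_matrix(ped: pd.DataFrame) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Individuals are processed parents-first; for individual i with
    parents s, d:  A[i, j] = (A[s, j] + A[d, j]) / 2 for previously
    processed j, and A[i, i] = 1 + A[s, d] / 2 (the inbreeding
    coefficient is half the parents' relationship). Unknown parents
    contribute zero.

    Returns a DataFrame indexed by individual id (symmetric).
    """
    validate_pedigree(ped)
    order = _topological_order(ped)
    n = len(ped)
    idx_of = pd.Series(np.arange(n), index=ped["id"].to_numpy())
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    # position of each individual in processing order
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    a = np.zeros((n, n))
    for k, i in enumerate(order):
        s = int(idx_of[sire[i]]) if sire[i] >= 0 else -1
        d = int(idx_of[dam[i]]) if dam[i] >= 0 else -1
        prev = order[:k]
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * a[pos[s], :k]
        if d >= 0:
            row += 0.5 * a[pos[d], :k]
        a[k, :k] = row
        a[:k, k] = row
        if s >= 0 and d >= 0:
            a[k, k] = 1.0 + 0.5 * a[pos[s], pos[d]]
        else:
            a[k, k] = 1.0
    # back to input order
    ids = ped["id"].to_numpy()[order]
    out = pd.DataFrame(a, index=ids, columns=ids)
    return out.loc[ped["id"].to_numpy(), ped["id"].to_numpy()]


def subset_same_sex(ped: pd.DataFrame, a: pd.DataFrame, sex: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict A to phenotyped individuals of one sex.

    A must be built on the full pedigree first, so relatedness that flows
    through opposite-sex relatives (e.g. paternal links between sisters)
    is preserved; subsetting only removes the other sex's phenotypes.

    Returns (A restricted to the sex, array of their ids).
    """
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    ids = ped.loc[ped["sex"] == sex, "id"].to_numpy()
    return a.loc[ids, ids], ids
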