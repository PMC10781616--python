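"""Bayesian animal models: heritability and cross-sex genetic correlation.

The model for a sociability phenotype y is

    y = X beta + a + e,

where ``a`` has covariance Va * A (A the numerator relationship matrix)
and e is residual noise, separating phenotypic variance into additive
genetic variance and the remaining variance. By default the remaining
variance also carries i.i.d. random intercepts for the replicate
selection line and the stimulus-group use count (both identified across
families). A breeding-family (common-environment) intercept is
available but off by default: with nuclear families only — no
cross-fostering — a family variance cannot be separated from Va (in the
same-sex design they are exactly confounded; in the full design it is
identified only through 195 spouse pairs and mostly injects prior
mass), so fitting it corrupts the additive estimates. Heritability per
posterior draw is Va divided by the sum of all fitted variance
components. The bivariate (full-pedigree) model treats
the female- and male-expressed phenotype as two traits whose additive
effects have a 2x2 covariance G; the cross-sex genetic correlation is
r_fm = cov / sqrt(Va_f * Va_m), with an LKJ(eta) prior on the correlation
(eta = 1 is uniform on [-1, 1]).

Priors follow the convention of weakly informative shrinkage for this
scale of data: Normal(0, 3) on fixed effects and half-Student-t(5, 0, 5)
on random-effect standard deviations.

Sampling uses a partially collapsed Gibbs scheme that exploits the
block-diagonal family structure of A: the within-block effects (breeding
values plus family intercepts) are integrated out analytically when the
genetic / family / residual variances are updated by adaptive
random-walk Metropolis, then redrawn from their exact conditional. Line
and group-use variances are updated with their own intercepts collapsed
(rank-one closed forms), after which the fixed effects and all i.i.d.
intercepts are redrawn jointly from their Gaussian conditional — the
joint draw removes the slow intercept/group-mean coupling of
one-at-a-time updates. Each update is a draw from an exact conditional
of the joint posterior, so the chain targets the correct distribution.

A note on identifiability: in a same-sex nuclear-family design (one
parent plus same-sex full sibs) every within-family pair has additive
relatedness 1/2, so Va and a separate family variance enter the
likelihood only through 0.5 * Va + V_family and cannot be separated.
Same-sex fits should therefore drop the family term
(``family_effect=False``, as :func:`fit_same_sex_model` does); its
variance is then absorbed by Va, which is why full-pedigree estimates
tend to sit below same-sex ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class Priors:
    fixed_sd: float = 3.0
    sd_df: float = 5.0
    sd_scale: float = 5.0
    lkj_eta: float = 1.0


@dataclass
class McmcConfig:
    chains: int = 4
    draws: int = 2500
    warmup: int = 1500
    seed: Optional[int] = None
    mh_substeps: int = 3
    target_accept: float = 0.30
    rhat_threshold: float = 1.01
    ess_threshold: float = 1000.0


def hdi_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the narrowest window holding ``prob`` mass."""
    x = np.sort(np.asarray(draws).ravel())
    n = len(x)
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass
class AnimalModelFit:
    """Posterior draws and diagnostics for one animal-model fit."""

    draws: dict  # name -> (chains, draws) array
    diagnostics: pd.DataFrame  # per-parameter rhat / ess
    converged: bool
    flags: list
    model: str
    fixed_effect_names: list

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.draws[name]))

    def hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        return hdi_interval(self.draws[name].ravel(), prob)

    def summary(self, prob: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            lo, hi = self.hdi(name, prob)
            rows.append((name, float(np.median(arr)), lo, hi))
        out = pd.DataFrame(rows, columns=["parameter", "median", "hdi_low", "hdi_high"])
        return out.set_index("parameter")


# ---------------------------------------------------------------------------
# priors / scalar samplers


def _half_t_logpdf(sigma: float, df: float, scale: float) -> float:
    return -0.5 * (df + 1.0) * np.log1p(sigma**2 / (df * scale**2))


def _slice_sample(x0, logp, rng, w=0.8, max_steps=30):
    """Univariate slice sampler (stepping out + shrinkage)."""
    logy = logp(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logp(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < logy:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


# ---------------------------------------------------------------------------
# block structure


class _Blocks:
    """Family blocks of the phenotyped relationship matrix, grouped by size."""

    def __init__(self, a_sub: np.ndarray, fam_codes: np.ndarray, trait: np.ndarray):
        n = a_sub.shape[0]
        n_comp, labels = connected_components(sp.csr_matrix(a_sub != 0.0), directed=False)
        # family labels must not cross blocks (independence assumption)
        for f in np.unique(fam_codes):
            if len(np.unique(labels[fam_codes == f])) > 1:
                raise ValueError("family levels cross pedigree components")
        self.groups = []
        sizes = np.bincount(labels)
        for k in np.unique(sizes):
            comp_ids = np.where(sizes == k)[0]
            idx = np.stack([np.where(labels == c)[0] for c in comp_ids])  # (m, k)
            a_stack = a_sub[idx[:, :, None], idx[:, None, :]]
            fam = fam_codes[idx]
            b_stack = (fam[:, :, None] == fam[:, None, :]).astype(float)
            self.groups.append(
                dict(idx=idx, A=a_stack, B=b_stack, trait=trait[idx], m=len(comp_ids), k=int(k))
            )
        self.n = n


def _block_cov(grp, g_mat, v_family, v_res):
    """Stacked within-block covariance Sigma + residual diag.

    g_mat: (2, 2) additive covariance over traits (univariate: both traits
    mapped to index 0). v_res: length-2 residual variances per trait.
    """
    t = grp["trait"]
    gg = g_mat[t[:, :, None], t[:, None, :]]
    sigma = gg * grp["A"] + v_family * grp["B"]
    c = sigma.copy()
    kk = np.arange(grp["k"])
    c[:, kk, kk] += v_res[t]
    return sigma, c


def _block_loglik(blocks, r, g_mat, v_family, v_res):
    total = 0.0
    for grp in blocks.groups:
        _, c = _block_cov(grp, g_mat, v_family, v_res)
        rb = r[grp["idx"]]
        try:
            ch = np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diagonal(ch, axis1=1, axis2=2)).sum()
        sol = np.linalg.solve(c, rb[..., None])[..., 0]
        quad = np.einsum("mk,mk->", rb, sol)
        total += -0.5 * (logdet + quad) - 0.5 * grp["m"] * grp["k"] * np.log(2 * np.pi)
    return total


def _draw_block_effects(blocks, r, g_mat, v_family, v_res, rng):
    """Redraw combined within-block effects u = a + family from exact
    conditional given residual variance; returns u over all observations."""
    u = np.zeros(blocks.n)
    for grp in blocks.groups:
        sigma, c = _block_cov(grp, g_mat, v_family, v_res)
        rb = r[grp["idx"]]
        k_op = np.linalg.solve(c, sigma)  # C^-1 Sigma, (m,k,k)
        mean = np.einsum("mij,mi->mj", k_op, rb)
        cov = sigma - sigma @ k_op
        kk = np.arange(grp["k"])
        cov[:, kk, kk] += 1e-10 + 1e-9 * cov[:, kk, kk].max()
        ch = np.linalg.cholesky(0.5 * (cov + cov.transpose(0, 2, 1)))
        z = rng.standard_normal(mean.shape)
        smp = mean + np.einsum("mij,mj->mi", ch, z)
        u[grp["idx"].ravel()] = smp.ravel()
    return u


# ---------------------------------------------------------------------------
# collapsed random-intercept update (line, group-use)


def _update_iid_intercept(r, codes, n_levels, w, sigma0, priors, rng):
    """Update (sigma, effects) for an i.i.d. random intercept with the
    intercept collapsed; w = per-observation precisions."""
    w_sum = np.bincount(codes, weights=w, minlength=n_levels)
    sw = np.bincount(codes, weights=w * r, minlength=n_levels)

    def logp(log_sigma):
        v = np.exp(2.0 * log_sigma)
        ll = -0.5 * np.sum(np.log1p(v * w_sum)) + 0.5 * v * np.sum(
            sw**2 / (1.0 + v * w_sum)
        )
        return ll + _half_t_logpdf(np.exp(log_sigma), priors.sd_df, priors.sd_scale) + log_sigma

    log_sigma = _slice_sample(np.log(sigma0), logp, rng)
    v = np.exp(2.0 * log_sigma)
    var = 1.0 / (w_sum + 1.0 / v) if v > 0 else np.zeros(n_levels)
    mean = var * sw
    eff = mean + np.sqrt(var) * rng.standard_normal(n_levels)
    return np.exp(log_sigma), eff


def _update_linear_block(r, x, iid_terms, iid_state, w, priors, rng):
    """Joint conjugate draw of (beta, all i.i.d. intercepts) given the
    variances; breaks the slow intercept <-> group-mean coupling of
    one-at-a-time updates. Returns (beta, {col: effects})."""
    cols = [x]
    prior_prec = [np.full(x.shape[1], 1.0 / priors.fixed_sd**2)]
    for col, codes, levels in iid_terms:
        z = np.zeros((len(r), len(levels)))
        z[np.arange(len(r)), codes] = 1.0
        cols.append(z)
        sd_k = iid_state[col][0]
        prior_prec.append(np.full(len(levels), 1.0 / max(sd_k**2, 1e-12)))
    wmat = np.concatenate(cols, axis=1)
    prec = (wmat.T * w) @ wmat + np.diag(np.concatenate(prior_prec))
    rhs = wmat.T @ (w * r)
    ch = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    draw = mean + np.linalg.solve(ch.T, rng.standard_normal(len(rhs)))
    beta = draw[: x.shape[1]]
    out = {}
    pos = x.shape[1]
    for col, codes, levels in iid_terms:
        out[col] = draw[pos : pos + len(levels)]
        pos += len(levels)
    return beta, out


# ---------------------------------------------------------------------------
# adaptive random-walk MH over the collapsed variance parameters


class _AdaptiveRW:
    def __init__(self, dim, rng, target=0.30):
        self.dim = dim
        self.rng = rng
        self.target = target
        self.log_scale = np.log(0.3 / np.sqrt(dim))
        self.cov = np.eye(dim)
        self.chol = np.eye(dim)
        self.history = []
        self.iter = 0

    def propose(self, theta):
        step = np.exp(self.log_scale) * (self.chol @ self.rng.standard_normal(self.dim))
        return theta + step

    def adapt(self, theta, accepted):
        self.iter += 1
        self.history.append(theta.copy())
        self.log_scale += (float(accepted) - self.target) / max(10.0, self.iter * 0.1)
        if self.iter >= 100 and self.iter % 50 == 0:
            hist = np.array(self.history[len(self.history) // 2 :])
            cov = np.cov(hist.T) + 1e-8 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass


# ---------------------------------------------------------------------------
# model fitting


def _design_matrix(phen: pd.DataFrame, include_sex: bool) -> tuple[np.ndarray, list]:
    cols = {
        "intercept": np.ones(len(phen)),
        "regime": (phen["regime"] == "polarization").to_numpy(float),
        "generation": (phen["generation"] == "offspring").to_numpy(float),
        "group_activity": phen["group_activity"].to_numpy(float),
    }
    if include_sex:
        cols["sex_m"] = (phen["sex"] == "M").to_numpy(float)
    return np.column_stack(list(cols.values())), list(cols)


def _prepare(phenotypes: pd.DataFrame, a: pd.DataFrame):
    phen = phenotypes.dropna(subset=["phenotype"]).copy()
    missing = set(phen["id"]) - set(a.index)
    if missing:
        raise ValueError(f"phenotyped ids absent from A: {sorted(missing)[:5]}")
    phen = phen.set_index("id").loc[[i for i in a.index if i in set(phen.index)]].reset_index()
    a_sub = a.loc[phen["id"], phen["id"]].to_numpy()
    eig_min = np.linalg.eigvalsh(a_sub).min()
    if eig_min < -1e-8:
        raise ValueError(f"A is not positive semi-definite (min eigenvalue {eig_min:.3g})")
    return phen, a_sub


def _run_chains(sampler_step, init_fn, record_names, mcmc, seed_seq):
    all_draws = {k: [] for k in record_names}
    for chain in range(mcmc.chains):
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        state = init_fn(rng)
        chain_draws = {k: np.empty(mcmc.draws) for k in record_names}
        for it in range(mcmc.warmup + mcmc.draws):
            rec = sampler_step(state, rng, adapt=it < mcmc.warmup)
            if it >= mcmc.warmup:
                for k in record_names:
                    chain_draws[k][it - mcmc.warmup] = rec[k]
        for k in record_names:
            all_draws[k].append(chain_draws[k])
    return {k: np.array(v) for k, v in all_draws.items()}


def _diagnose(draws, mcmc):
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    flags = []
    for k in draws:
        r = float(rhat[k].values)
        e = float(ess[k].values)
        rows.append((k, r, e))
        if np.isfinite(r) and r > mcmc.rhat_threshold:
            flags.append(f"rhat({k})={r:.3f} > {mcmc.rhat_threshold}")
        if e < mcmc.ess_threshold:
            flags.append(f"ess({k})={e:.0f} < {mcmc.ess_threshold:.0f}")
    diag = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"]).set_index("parameter")
    return diag, flags


def _iid_name(col: str) -> str:
    return "v_" + col.replace("_", "")


def fit_animal_model(
    phenotypes: pd.DataFrame,
    a: pd.DataFrame,
    priors: Optional[Priors] = None,
    mcmc: Optional[McmcConfig] = None,
    random_effects: Sequence[str] = ("line", "group_use"),
    family_effect: bool = False,
) -> AnimalModelFit:
    """Univariate animal model by collapsed Gibbs/MH sampling.

    phenotypes: DataFrame with columns id, phenotype, sex, regime,
    generation, group_activity, line, family (plus any columns named in
    ``random_effects``). ``a`` is the numerator relationship matrix
    (DataFrame indexed by id) built on the full pedigree; its
    phenotyped submatrix is used.

    The default model has two variance components — additive and
    residual — with fixed effects for regime, generation, the
    stimulus-group activity covariate (and sex when both sexes are
    present). Extra i.i.d. random intercepts (e.g. ``("line",
    "group_use")``) and a family intercept can be added; heritability
    per draw is Va over the sum of whatever components are in the
    model.
    """
    priors = priors or Priors()
    mcmc = mcmc or McmcConfig()
    phen, a_sub = _prepare(phenotypes, a)
    y = phen["phenotype"].to_numpy(float)
    both_sexes = phen["sex"].nunique() > 1
    x, x_names = _design_matrix(phen, include_sex=both_sexes)
    trait = np.zeros(len(phen), dtype=int)
    fam_codes = pd.factorize(phen["family"])[0]
    blocks = _Blocks(a_sub, fam_codes, trait)
    iid_terms = [
        (col, *pd.factorize(phen[col])) for col in random_effects
    ]  # (col, codes, levels)

    sd_y = np.std(y)
    n_theta = 3 if family_effect else 2  # log sd_a, [log sd_fam], log sd_e

    def init_fn(rng):
        theta = np.log(np.array(([0.5, 0.3, 0.7] if family_effect else [0.5, 0.7])) * sd_y)
        theta += 0.15 * rng.standard_normal(n_theta)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        return dict(
            theta=theta,
            beta=beta,
            u=np.zeros(len(y)),
            iid={col: (0.3 * sd_y, np.zeros(len(levels))) for col, _, levels in iid_terms},
            rw=_AdaptiveRW(n_theta, rng, mcmc.target_accept),
            loglik=None,
        )

    def unpack(theta):
        if family_effect:
            sd_a, sd_fam, sd_e = np.exp(theta)
        else:
            sd_a, sd_e = np.exp(theta)
            sd_fam = 0.0
        g_mat = np.array([[sd_a**2, 0.0], [0.0, sd_a**2]])
        v_res = np.array([sd_e**2, sd_e**2])
        return g_mat, sd_fam**2, v_res, sd_a, sd_fam, sd_e

    def log_target(theta, r1):
        g_mat, v_fam, v_res, sd_a, sd_fam, sd_e = unpack(theta)
        ll = _block_loglik(blocks, r1, g_mat, v_fam, v_res)
        lp = (
            _half_t_logpdf(sd_a, priors.sd_df, priors.sd_scale)
            + _half_t_logpdf(sd_e, priors.sd_df, priors.sd_scale)
            + theta.sum()  # log-Jacobian of the log transform
        )
        if family_effect:
            lp += _half_t_logpdf(sd_fam, priors.sd_df, priors.sd_scale)
        return ll + lp

    def iid_sum(state, skip=None):
        out = np.zeros(len(y))
        for col, codes, _ in iid_terms:
            if col != skip:
                out += state["iid"][col][1][codes]
        return out

    def step(state, rng, adapt):
        r1 = y - x @ state["beta"] - iid_sum(state)
        if state["loglik"] is None:
            state["loglik"] = log_target(state["theta"], r1)
        for _ in range(mcmc.mh_substeps):
            prop = state["rw"].propose(state["theta"])
            lp = log_target(prop, r1)
            accepted = np.log(rng.uniform()) < lp - state["loglik"]
            if accepted:
                state["theta"], state["loglik"] = prop, lp
            if adapt:
                state["rw"].adapt(state["theta"], accepted)
        g_mat, v_fam, v_res, sd_a, sd_fam, sd_e = unpack(state["theta"])
        state["u"] = _draw_block_effects(blocks, r1, g_mat, v_fam, v_res, rng)
        w = np.full(len(y), 1.0 / sd_e**2)
        for col, codes, levels in iid_terms:
            r = y - x @ state["beta"] - state["u"] - iid_sum(state, skip=col)
            sd0 = state["iid"][col][0]
            state["iid"][col] = _update_iid_intercept(
                r, codes, len(levels), w, sd0, priors, rng
            )
        r4 = y - state["u"]
        state["beta"], eff = _update_linear_block(
            r4, x, iid_terms, state["iid"], w, priors, rng
        )
        for col, _, _ in iid_terms:
            state["iid"][col] = (state["iid"][col][0], eff[col])
        state["loglik"] = None
        va = sd_a**2
        total = va + v_fam + sd_e**2
        rec = dict(va=va, v_res=sd_e**2)
        if family_effect:
            rec["v_family"] = v_fam
        for col, _, _ in iid_terms:
            v = state["iid"][col][0] ** 2
            rec[_iid_name(col)] = v
            total += v
        rec["h2"] = va / total
        for j, nm in enumerate(x_names):
            rec[f"b_{nm}"] = state["beta"][j]
        return rec

    record = ["va", "v_res"]
    if family_effect:
        record.append("v_family")
    record += [_iid_name(col) for col, _, _ in iid_terms]
    record += ["h2"] + [f"b_{nm}" for nm in x_names]

    seed_seq = np.random.SeedSequence(mcmc.seed)
    draws = _run_chains(step, init_fn, record, mcmc, seed_seq)
    diag, flags = _diagnose(draws, mcmc)
    return AnimalModelFit(
        draws=draws,
        diagnostics=diag,
        converged=not flags,
        flags=flags,
        model="univariate",
        fixed_effect_names=x_names,
    )


def fit_same_sex_model(
    phenotypes: pd.DataFrame,
    a: pd.DataFrame,
    sex: str,
    priors: Optional[Priors] = None,
    mcmc: Optional[McmcConfig] = None,
    random_effects: Sequence[str] = ("line", "group_use"),
) -> AnimalModelFit:
    """Same-sex-pedigree animal model: A built on the full pedigree, the
    phenotyped set restricted to one sex.

    A family intercept is never fitted here: with one parent plus
    same-sex full sibs every within-family pair has relatedness 1/2, so
    a family variance would be unidentifiable from Va (see the module
    docstring).
    """
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    phen = phenotypes[phenotypes["sex"] == sex]
    return fit_animal_model(
        phen, a, priors=priors, mcmc=mcmc, random_effects=random_effects, family_effect=False
    )


def fit_bivariate_animal_model(
    phenotypes: pd.DataFrame,
    a: pd.DataFrame,
    priors: Optional[Priors] = None,
    mcmc: Optional[McmcConfig] = None,
    random_effects: Sequence[str] = ("line", "group_use"),
    family_effect: bool = False,
) -> AnimalModelFit:
    """Full-pedigree bivariate (sex-limited two-trait) animal model.

    Female- and male-expressed phenotypes are two traits, each observed
    in one sex; their additive covariance G is sampled with half-t
    priors on the two genetic SDs and an LKJ(eta) prior on the
    correlation. Fixed effects (intercept, regime, generation,
    activity) are trait-specific; residual variances are per trait.
    Optional i.i.d. intercepts and a family intercept are shared across
    the sexes.
    """
    priors = priors or Priors()
    mcmc = mcmc or McmcConfig()
    phen, a_sub = _prepare(phenotypes, a)
    y = phen["phenotype"].to_numpy(float)
    single_sex = phen["sex"].nunique() < 2
    if single_sex:
        warnings.warn("single-sex data: cross-sex correlation is prior-driven")
    trait = (phen["sex"] == "M").to_numpy(int)
    x0, base_names = _design_matrix(phen, include_sex=False)
    x = np.concatenate([x0 * (trait == 0)[:, None], x0 * (trait == 1)[:, None]], axis=1)
    x = x[:, x.any(axis=0)]  # drop empty trait blocks for single-sex input
    x_names = [f"{nm}_f" for nm in base_names] + [f"{nm}_m" for nm in base_names]
    x_names = [nm for nm, keep in zip(x_names, np.ones(len(x_names), bool)) if keep][: x.shape[1]]
    fam_codes = pd.factorize(phen["family"])[0]
    blocks = _Blocks(a_sub, fam_codes, trait)
    iid_terms = [(col, *pd.factorize(phen[col])) for col in random_effects]
    sd_y = np.std(y)
    # theta = log sd_af, log sd_am, atanh(r), [log sd_fam], log sd_ef, log sd_em
    n_theta = 6 if family_effect else 5

    def unpack(theta):
        sd_af, sd_am = np.exp(theta[0]), np.exp(theta[1])
        r = np.tanh(theta[2])
        if family_effect:
            sd_fam = np.exp(theta[3])
            sd_ef, sd_em = np.exp(theta[4]), np.exp(theta[5])
        else:
            sd_fam = 0.0
            sd_ef, sd_em = np.exp(theta[3]), np.exp(theta[4])
        cov = r * sd_af * sd_am
        g_mat = np.array([[sd_af**2, cov], [cov, sd_am**2]])
        v_res = np.array([sd_ef**2, sd_em**2])
        return g_mat, sd_fam**2, v_res, (sd_af, sd_am, r, sd_fam, sd_ef, sd_em)

    def log_target(theta, r1):
        g_mat, v_fam, v_res, (sd_af, sd_am, r, sd_fam, sd_ef, sd_em) = unpack(theta)
        ll = _block_loglik(blocks, r1, g_mat, v_fam, v_res)
        lp = (
            _half_t_logpdf(sd_af, priors.sd_df, priors.sd_scale)
            + _half_t_logpdf(sd_am, priors.sd_df, priors.sd_scale)
            + _half_t_logpdf(sd_ef, priors.sd_df, priors.sd_scale)
            + _half_t_logpdf(sd_em, priors.sd_df, priors.sd_scale)
        )
        # LKJ(eta) density in r plus the atanh Jacobian, both via (1 - r^2)
        lp += (priors.lkj_eta - 1.0) * np.log1p(-(r**2)) + np.log1p(-(r**2))
        lp += theta[0] + theta[1] + theta[-2] + theta[-1]
        if family_effect:
            lp += _half_t_logpdf(sd_fam, priors.sd_df, priors.sd_scale) + theta[3]
        return ll + lp

    def init_fn(rng):
        theta = np.empty(n_theta)
        theta[0] = np.log(0.5 * sd_y)
        theta[1] = np.log(0.5 * sd_y)
        theta[2] = 0.0
        pos = 3
        if family_effect:
            theta[3] = np.log(0.3 * sd_y)
            pos = 4
        theta[pos] = np.log(0.7 * sd_y)
        theta[pos + 1] = np.log(0.7 * sd_y)
        theta += 0.15 * rng.standard_normal(n_theta)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        return dict(
            theta=theta,
            beta=beta,
            u=np.zeros(len(y)),
            iid={col: (0.3 * sd_y, np.zeros(len(levels))) for col, _, levels in iid_terms},
            rw=_AdaptiveRW(n_theta, rng, mcmc.target_accept),
            loglik=None,
        )

    def iid_sum(state, skip=None):
        out = np.zeros(len(y))
        for col, codes, _ in iid_terms:
            if col != skip:
                out += state["iid"][col][1][codes]
        return out

    def step(state, rng, adapt):
        r1 = y - x @ state["beta"] - iid_sum(state)
        if state["loglik"] is None:
            state["loglik"] = log_target(state["theta"], r1)
        for _ in range(mcmc.mh_substeps):
            prop = state["rw"].propose(state["theta"])
            lp = log_target(prop, r1)
            accepted = np.log(rng.uniform()) < lp - state["loglik"]
            if accepted:
                state["theta"], state["loglik"] = prop, lp
            if adapt:
                state["rw"].adapt(state["theta"], accepted)
        g_mat, v_fam, v_res, (sd_af, sd_am, r, sd_fam, sd_ef, sd_em) = unpack(state["theta"])
        state["u"] = _draw_block_effects(blocks, r1, g_mat, v_fam, v_res, rng)
        w = 1.0 / v_res[trait]
        for col, codes, levels in iid_terms:
            rr = y - x @ state["beta"] - state["u"] - iid_sum(state, skip=col)
            sd0 = state["iid"][col][0]
            state["iid"][col] = _update_iid_intercept(
                rr, codes, len(levels), w, sd0, priors, rng
            )
        r4 = y - state["u"]
        state["beta"], eff = _update_linear_block(
            r4, x, iid_terms, state["iid"], w, priors, rng
        )
        for col, _, _ in iid_terms:
            state["iid"][col] = (state["iid"][col][0], eff[col])
        state["loglik"] = None
        va_f, va_m = sd_af**2, sd_am**2
        common = v_fam
        rec = dict(
            va_f=va_f,
            va_m=va_m,
            cov_fm=r * sd_af * sd_am,
            r_fm=r,
            v_res_f=sd_ef**2,
            v_res_m=sd_em**2,
        )
        if family_effect:
            rec["v_family"] = v_fam
        for col, _, _ in iid_terms:
            v = state["iid"][col][0] ** 2
            rec[_iid_name(col)] = v
            common += v
        rec["h2_f"] = va_f / (va_f + common + sd_ef**2)
        rec["h2_m"] = va_m / (va_m + common + sd_em**2)
        return rec

    record = ["va_f", "va_m", "cov_fm", "r_fm", "v_res_f", "v_res_m"]
    if family_effect:
        record.append("v_family")
    record += [_iid_name(col) for col, _, _ in iid_terms]
    record += ["h2_f", "h2_m"]

    seed_seq = np.random.SeedSequence(mcmc.seed)
    draws = _run_chains(step, init_fn, record, mcmc, seed_seq)
    diag, flags = _diagnose(draws, mcmc)
    if single_sex:
        flags = list(flags) + ["single-sex data: r_fm unidentified (prior-driven)"]
    return AnimalModelFit(
        draws=draws,
        diagnostics=diag,
        converged=not flags,
        flags=flags,
        model="bivariate",
        fixed_effect_names=x_names,
    )


def heritability_summary(fit: AnimalModelFit, prob: float = 0.95) -> pd.DataFrame:
    """Median + HDI table for every heritability / correlation parameter."""
    names = [k for k in fit.draws if k.startswith("h2") or k == "r_fm"]
    rows = []
    for name in names:
        lo, hi = fit.hdi(name, prob)
        rows.append((name, fit.posterior_median(name), lo, hi, fit.model, fit.converged))
    return pd.DataFrame(
        rows, columns=["parameter", "median", "hdi_low", "hdi_high", "model", "converged"]
    )


def prior_predictive_h2(
    priors: Optional[Priors] = None, n: int = 4000, n_components: int = 2, seed: int = 0
) -> np.ndarray:
    """Draw h2 from the prior alone (sanity check: spans (0, 1))."""
    priors = priors or Priors()
    rng = np.random.default_rng(seed)
    sds = np.abs(rng.standard_t(priors.sd_df, size=(n, n_components))) * priors.sd_scale
    v = sds**2
    return v[:, 0] / v.sum(axis=1)
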