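"""Bayesian multi-trait multi-environment (MTME) model with Kronecker
genotype-by-environment covariance, fitted by Gibbs sampling.

Model, on the environment-major stacked response Y (j x t, j = n * l):

    Y = X B + Z1 b1 + Z2 b2 + E
    b1 ~ MN(0, G, Sigma_t)             genotype main effects
    b2 ~ MN(0, Sigma_E (x) G, Sigma_t) genotype x environment x trait effects
    E  ~ MN(0, I_j, R_e)               unstructured residual covariance

with X the environment indicator (j x l), Z1 = 1_l (x) I_n and Z2 = I_j.
Priors: flat on B; Sigma_t ~ IW(t + 2, I); Sigma_E ~ IW(l + 2, I);
R_e ~ IW(t + 2, I).

The Kronecker structure is never materialised: with G = Q D Q' and
Sigma_E = P L P', rotating the rows of the working residuals by Q (for b1)
or P (x) Q (for b2) renders the rows conditionally independent, so each
sweep costs batched t x t solves over n (for b1) and n*l (for b2) rows.

Because Sigma_t is shared between b1 and b2, the overall scale of Sigma_E
is likelihood-identified (its diagonal carries the G x E share of genetic
variance relative to the main effect), so no normalisation is imposed on
it.  Missing cells are data-augmented exactly as in the multi-trait model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .mt_bayes import GibbsConfig, rinvwishart, _batched_mvn_draws
from .pheno_adjust import BlueTable

__all__ = ["MtmeSpec", "MtmeFit", "build_mtme_design", "fit_mtme", "predict_mtme"]


@dataclass
class MtmeSpec:
    """Stacking declaration: rows are lines nested within environments,
    environment-major, lines in ``line_ids`` order within each block."""

    env_ids: list
    line_ids: list
    trait_names: list

    def __post_init__(self):
        self.env_ids = [str(e) for e in self.env_ids]
        self.line_ids = [str(l) for l in self.line_ids]
        self.trait_names = [str(t) for t in self.trait_names]

    @property
    def n(self):
        return len(self.line_ids)

    @property
    def l(self):
        return len(self.env_ids)

    @property
    def t(self):
        return len(self.trait_names)

    @property
    def j(self):
        return self.n * self.l

    def row_index(self, line, env) -> int:
        return self.env_ids.index(str(env)) * self.n + self.line_ids.index(str(line))

    def X(self) -> np.ndarray:
        return np.kron(np.eye(self.l), np.ones((self.n, 1)))

    def Z1(self) -> np.ndarray:
        return np.tile(np.eye(self.n), (self.l, 1))

    def Z2(self) -> np.ndarray:
        return np.eye(self.j)


@dataclass
class MtmeFit:
    spec: MtmeSpec
    Beta: np.ndarray          # l x t
    B1: np.ndarray            # n x t
    B2: np.ndarray            # (n*l) x t
    Sigma_t: np.ndarray
    Sigma_E: np.ndarray
    R_e: np.ndarray
    config: GibbsConfig = None
    n_draws: int = 0
    mc_se: dict = field(default_factory=dict)

    @property
    def trait_names(self):
        return self.spec.trait_names

    def fitted(self) -> np.ndarray:
        """X Beta + Z1 B1 + Z2 B2 on the stored posterior means."""
        s = self.spec
        return s.X() @ self.Beta + s.Z1() @ self.B1 + s.Z2() @ self.B2


def build_mtme_design(b: BlueTable, traits, envs):
    """Canonical environment-major design and response from a BlueTable.

    Returns (MtmeSpec, Y) where Y is j x t with NaN at cells to be
    augmented.  Row order is independent of the input record order.
    """
    traits = [str(t) for t in traits]
    envs = [str(e) for e in envs]
    sub = b.df[b.df["env"].isin(envs) & b.df["trait"].isin(traits)]
    lines = sorted(sub["line"].unique())
    if not lines:
        raise ValueError("no lines present in the requested environments")
    spec = MtmeSpec(envs, lines, traits)
    Y = np.full((spec.j, spec.t), np.nan)
    line_pos = {l: i for i, l in enumerate(lines)}
    env_pos = {e: i for i, e in enumerate(envs)}
    trait_pos = {t: i for i, t in enumerate(traits)}
    for row in sub.itertuples(index=False):
        Y[env_pos[row.env] * spec.n + line_pos[row.line], trait_pos[row.trait]] = row.value
    return spec, Y


def _reml_residual_share(y: np.ndarray, Gv: np.ndarray) -> float:
    """Residual fraction of variance for one fully-observed column by
    spectral REML of y = 1 mu + u + e, u ~ N(0, G sg2); used to anchor the
    residual prior (empirical Bayes)."""
    from scipy.optimize import minimize_scalar

    from .gblup import _reml_profile

    obs = np.isfinite(y)
    if obs.sum() < 10 or np.var(y[obs], ddof=1) <= 0:
        return 0.5
    d, U = np.linalg.eigh(Gv[np.ix_(obs, obs)])
    d = np.clip(d, 0.0, None)
    yt = U.T @ y[obs]
    xt = U.T @ np.ones(int(obs.sum()))
    parts, negloglik = _reml_profile(d, yt, xt)
    res = minimize_scalar(negloglik, bounds=(np.log(1e-5), np.log(1e5)),
                          method="bounded", options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    _, _, _, ypy = parts(delta)
    sg2 = max(ypy / (obs.sum() - 1), 1e-12)
    se2 = delta * sg2
    gbar = float(np.mean(np.diag(Gv)[obs]))
    return float(np.clip(se2 / (sg2 * gbar + se2), 0.01, 0.99))


def _group_missing_patterns(miss: np.ndarray):
    """Group row indices by their boolean missing pattern (excluding the
    all-observed pattern)."""
    groups = {}
    for i in range(miss.shape[0]):
        key = tuple(miss[i])
        if any(key):
            groups.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def fit_mtme(spec: MtmeSpec, Y: np.ndarray, G: RelationshipMatrix,
             cfg: GibbsConfig, min_obs: int = 5, _init: dict | None = None) -> MtmeFit:
    """Gibbs sampler for the MTME model; ``Y`` is j x t with NaN = missing."""
    n, l, t, j = spec.n, spec.l, spec.t, spec.j
    if Y.shape != (j, t):
        raise ValueError(f"response shape {Y.shape} != ({j}, {t})")
    Gs = G.subset(spec.line_ids)

    obs_mask = ~np.isnan(Y)
    per_col = obs_mask.reshape(l, n, t).sum(axis=1)  # l x t observed counts
    if (per_col < min_obs).any():
        bad = [
            (spec.env_ids[e], spec.trait_names[k])
            for e, k in zip(*np.where(per_col < min_obs))
        ]
        raise ValueError(f"(env, trait) columns with <{min_obs} observations: {bad[:5]}")

    d, Q = np.linalg.eigh(Gs.values)
    if d.min() < -1e-8:
        raise ValueError("G is not PSD; apply make_psd first")
    d = np.clip(d, 1e-8, None)
    Ginv = (Q / d) @ Q.T
    Gih = (Q / np.sqrt(d)) @ Q.T  # G^(-1/2)

    rng = np.random.default_rng(cfg.seed)
    nu_E, S_E0 = l + 2, np.eye(l)
    # empirical-Bayes anchors: per-trait residual share from spectral REML
    # on each environment column (averaged), splitting the genetic remainder
    # equally between the main effect and the GxE term.  A fixed identity
    # scale would anchor the residual at full phenotypic variance and the
    # genetic terms at twice it, which visibly biases the weakly-identified
    # genetic/residual split in both directions.
    resid_share = np.empty(t)
    for k in range(t):
        shares = [
            _reml_residual_share(Y[e * n:(e + 1) * n, k], Gs.values)
            for e in range(l)
        ]
        resid_share[k] = float(np.mean(shares))
    nu_t, S_t0 = t + 2, np.diag((1.0 - resid_share) / 2.0)
    nu_R, S_R0 = t + 2, np.diag(resid_share)

    # standardise traits so the identity-scale covariance priors are weakly
    # informative in any units; results are transformed back on exit
    center = np.nanmean(Y, axis=0)
    obs_var = np.nanvar(Y, axis=0, ddof=1)
    scale = np.sqrt(np.where(np.isfinite(obs_var) & (obs_var > 0), obs_var, 1.0))
    Y = (Y - center) / scale
    col_mean = np.array([
        np.nanmean(Y[:, k]) if obs_mask[:, k].any() else 0.0 for k in range(t)
    ])
    Ya = Y.copy()
    Ya[~obs_mask] = np.broadcast_to(col_mean, Y.shape)[~obs_mask]
    obs_var = np.ones(t)

    Beta = Ya.reshape(l, n, t).mean(axis=1)
    B1 = np.zeros((n, t))
    B2 = np.zeros((j, t))
    Sigma_t = np.diag(obs_var / 3.0)
    Sigma_E = np.eye(l)
    R_e = np.diag(obs_var / 3.0)
    if _init:  # diagnostic entry point for chain-sensitivity checks
        Sigma_t = _init.get("Sigma_t", Sigma_t)
        Sigma_E = _init.get("Sigma_E", Sigma_E)
        R_e = _init.get("R_e", R_e)

    miss_groups = _group_missing_patterns(~obs_mask)

    total = cfg.n_burn + cfg.n_iter
    keep = 0
    sums = {
        "Beta": np.zeros((l, t)),
        "B1": np.zeros((n, t)),
        "B2": np.zeros((j, t)),
        "Sigma_t": np.zeros((t, t)),
        "Sigma_E": np.zeros((l, l)),
        "R_e": np.zeros((t, t)),
    }
    sq_SE = np.zeros((l, l))
    sq_St = np.zeros((t, t))

    for it in range(total):
        Rinv = np.linalg.inv(R_e)
        St_inv = np.linalg.inv(Sigma_t)

        # (1) environment-by-trait coefficients, flat prior
        resid = (Ya - B2).reshape(l, n, t) - B1[None, :, :]
        means = resid.mean(axis=1)  # l x t
        Lr = np.linalg.cholesky(R_e / n)
        Beta = means + rng.standard_normal((l, t)) @ Lr.T

        # (2) genotype main effects b1, with b2 integrated out (partially
        # collapsed draw: b1 and the common component of b2 are nearly
        # confounded, and the collapsed update mixes across that ridge)
        lam, Pe = np.linalg.eigh(Sigma_E)
        lam = np.clip(lam, 1e-10, None)
        M = Ya.reshape(l, n, t) - Beta[:, None, :]
        Mrot = np.einsum("ea,eik->aik", Pe, M)
        Mrot = np.einsum("qi,aik->aqk", Q.T, Mrot)  # (l, n, t) in (a, q) rows
        # marginal row covariance V_aq = lam_a d_q Sigma_t + R_e
        V = (lam[:, None, None, None] * d[None, :, None, None]
             * Sigma_t[None, None, :, :] + R_e[None, None, :, :])
        Vinv = np.linalg.inv(V)
        s_env = Pe.sum(axis=0)  # rotated coefficients of the b1 column space
        P1 = (St_inv[None, :, :] / d[:, None, None]
              + np.einsum("a,aqkm->qkm", s_env**2, Vinv))
        rhs1 = np.einsum("a,aqkm,aqm->qk", s_env, Vinv, Mrot)
        B1t = _batched_mvn_draws(P1, rhs1, rng)
        B1 = Q @ B1t

        # (3) GxE effects b2 ~ MN(0, Sigma_E (x) G, Sigma_t) given b1
        Mrot1 = Mrot - s_env[:, None, None] * B1t[None, :, :]
        row_scale = (lam[:, None] * d[None, :]).reshape(-1)
        Pp = St_inv[None, :, :] / row_scale[:, None, None] + Rinv[None, :, :]
        rhs2 = Mrot1.reshape(j, t) @ Rinv.T
        B2rot = _batched_mvn_draws(Pp, rhs2, rng).reshape(l, n, t)
        B2 = np.einsum("ae,aik->eik", Pe.T, B2rot)
        B2 = np.einsum("iq,eqk->eik", Q, B2).reshape(j, t)

        # (4) Sigma_t pooling b1 and b2 quadratic forms
        B2e = B2.reshape(l, n, t)
        GinvB2 = np.einsum("pq,eqk->epk", Ginv, B2e)
        SE_inv = np.linalg.inv(Sigma_E)
        S1 = B1.T @ (Ginv @ B1)
        S2 = np.einsum("eik,ef,fim->km", B2e, SE_inv, GinvB2)
        Sigma_t = rinvwishart(rng, nu_t + n + j, S_t0 + S1 + 0.5 * (S2 + S2.T))

        # (5) Sigma_E given b2, G, Sigma_t
        wt, Vt = np.linalg.eigh(0.5 * (Sigma_t + Sigma_t.T))
        wt = np.clip(wt, 1e-10, None)
        St_ih = (Vt / np.sqrt(wt)) @ Vt.T
        A = np.einsum("pq,eqk->epk", Gih, B2e)
        A = np.einsum("eik,km->eim", A, St_ih)
        S_E = np.einsum("eik,fik->ef", A, A)
        Sigma_E = rinvwishart(rng, nu_E + n * t, S_E0 + 0.5 * (S_E + S_E.T))

        # (6) residual covariance
        E = Ya - np.repeat(Beta, n, axis=0) - np.tile(B1, (l, 1)) - B2
        R_e = rinvwishart(rng, nu_R + j, S_R0 + E.T @ E)

        # (7) data augmentation of missing cells
        if miss_groups:
            fitted = np.repeat(Beta, n, axis=0) + np.tile(B1, (l, 1)) + B2
            for pattern, rows in miss_groups.items():
                m = np.array(pattern)
                if m.all():
                    Lr = np.linalg.cholesky(R_e)
                    z = rng.standard_normal((rows.size, t))
                    Ya[rows] = fitted[rows] + z @ Lr.T
                else:
                    o = ~m
                    Roo = R_e[np.ix_(o, o)]
                    Rmo = R_e[np.ix_(m, o)]
                    K = Rmo @ np.linalg.inv(Roo)
                    cond_cov = R_e[np.ix_(m, m)] - K @ Rmo.T
                    Lc = np.linalg.cholesky(0.5 * (cond_cov + cond_cov.T))
                    resid_o = Ya[np.ix_(rows, np.where(o)[0])] - fitted[np.ix_(rows, np.where(o)[0])]
                    cond_mean = fitted[np.ix_(rows, np.where(m)[0])] + resid_o @ K.T
                    z = rng.standard_normal((rows.size, int(m.sum())))
                    Ya[np.ix_(rows, np.where(m)[0])] = cond_mean + z @ Lc.T

        if not (np.all(np.isfinite(Sigma_t)) and np.all(np.isfinite(Sigma_E))
                and np.all(np.isfinite(R_e))):
            raise RuntimeError(f"non-finite draw at iteration {it}")

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            keep += 1
            sums["Beta"] += Beta
            sums["B1"] += B1
            sums["B2"] += B2
            sums["Sigma_t"] += Sigma_t
            sums["Sigma_E"] += Sigma_E
            sums["R_e"] += R_e
            sq_SE += Sigma_E**2
            sq_St += Sigma_t**2

    means = {k: v / keep for k, v in sums.items()}
    ss = np.outer(scale, scale)
    mc_se = {
        "Sigma_E": np.sqrt(np.maximum(sq_SE / keep - means["Sigma_E"] ** 2, 0) / keep),
        "Sigma_t": np.sqrt(
            np.maximum(sq_St / keep - means["Sigma_t"] ** 2, 0) / keep) * ss,
    }
    return MtmeFit(spec, center + means["Beta"] * scale, means["B1"] * scale,
                   means["B2"] * scale, means["Sigma_t"] * ss, means["Sigma_E"],
                   means["R_e"] * ss, cfg, keep, mc_se)


def predict_mtme(f: MtmeFit, cells) -> pd.Series:
    """Predictions Beta[env, trait] + B1[line, trait] + B2[(line, env), trait]
    for a list of (line, env, trait) cells (defined also for cells that were
    missing during fitting)."""
    s = f.spec
    env_pos = {e: i for i, e in enumerate(s.env_ids)}
    line_pos = {l: i for i, l in enumerate(s.line_ids)}
    trait_pos = {t: i for i, t in enumerate(s.trait_names)}
    out = []
    for line, env, trait in cells:
        line, env, trait = str(line), str(env), str(trait)
        if line not in line_pos or env not in env_pos or trait not in trait_pos:
            raise KeyError(f"unknown cell ({line}, {env}, {trait})")
        e, i, k = env_pos[env], line_pos[line], trait_pos[trait]
        out.append(f.Beta[e, k] + f.B1[i, k] + f.B2[e * s.n + i, k])
    idx = pd.MultiIndex.from_tuples(
        [(str(a), str(b), str(c)) for a, b, c in cells],
        names=["line", "env", "trait"],
    )
    return pd.Series(out, index=idx)
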