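"""Single-trait GBLUP fitted by spectral REML (the ST-CV1 baseline).

The model is y = 1 mu + u + e with u ~ N(0, G sigma_g2) and
e ~ N(0, I sigma_e2); it is equivalent to ridge regression on centered
markers at penalty lambda = delta * 2 sum p(1-p), where delta =
sigma_e2/sigma_g2.  The restricted likelihood is profiled down to a 1-D
search over log(delta) after a single eigendecomposition of G (EMMA-style),
with delta bounded in [1e-5, 1e5].

Genetic values for unphenotyped lines are the conditional expectations under
the joint normal, i.e. u_new = G[new, obs] (G[obs, obs] + delta I)^-1
(y - mu), so every line carried in G receives a GEBV.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinship import RelationshipMatrix

__all__ = ["StFit", "fit_gblup", "predict_st"]

DELTA_BOUNDS = (1e-5, 1e5)


@dataclass
class StFit:
    line_ids: list
    mu: float
    gebv: np.ndarray          # one entry per line in the relationship matrix
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    phenotyped: list

    def gebv_series(self) -> pd.Series:
        return pd.Series(self.gebv, index=self.line_ids)


def _reml_profile(d, yt, xt):
    """Profiled restricted log-likelihood pieces for H = diag(d) + delta I."""
    n = d.size

    def parts(delta):
        h = d + delta
        xhx = float(np.sum(xt * xt / h))
        xhy = float(np.sum(xt * yt / h))
        yhy = float(np.sum(yt * yt / h))
        mu = xhy / xhx
        ypy = yhy - xhy * xhy / xhx
        return h, xhx, mu, ypy

    def negloglik(log_delta):
        h, xhx, _, ypy = parts(np.exp(log_delta))
        if ypy <= 0:
            return np.inf
        sg2 = ypy / (n - 1)
        ll = -0.5 * (
            (n - 1) * (np.log(2.0 * np.pi * sg2) + 1.0)
            + np.sum(np.log(h))
            + np.log(xhx)
        )
        return -ll

    return parts, negloglik


def fit_gblup(y: pd.Series, G: RelationshipMatrix) -> StFit:
    """REML fit of the GBLUP model; ``y`` is indexed by line id.

    Lines present in ``G`` but absent from ``y`` are predicted through their
    genomic relationship to the phenotyped lines.
    """
    y = y.dropna()
    obs = [l for l in G.ids if l in set(y.index)]
    if len(obs) < 2:
        raise ValueError("need >= 2 phenotyped lines present in G")
    yv = y.loc[obs].to_numpy(dtype=float)
    obs_idx = np.array([G.ids.index(l) for l in obs])
    Gobs = G.values[np.ix_(obs_idx, obs_idx)]

    d, U = np.linalg.eigh(Gobs)
    if d.min() < -1e-8:
        raise ValueError(
            f"G is not PSD over the phenotyped lines (min eigenvalue {d.min():.3g}); "
            "apply make_psd first"
        )
    d = np.clip(d, 0.0, None)

    if np.var(yv, ddof=1) <= 1e-12:
        warnings.warn("zero phenotypic variance; sigma_g2 set to 0")
        mu = float(np.mean(yv))
        return StFit(list(G.ids), mu, np.zeros(G.n), 0.0, 0.0, DELTA_BOUNDS[1],
                     float("nan"), obs)

    yt = U.T @ yv
    xt = U.T @ np.ones_like(yv)
    parts, negloglik = _reml_profile(d, yt, xt)
    res = minimize_scalar(
        negloglik,
        bounds=(np.log(DELTA_BOUNDS[0]), np.log(DELTA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    _, _, mu, ypy = parts(delta)
    n = yv.size
    sigma_g2 = max(ypy / (n - 1), 0.0)
    sigma_e2 = delta * sigma_g2

    # BLUP of u for every line in G via joint-normal conditioning
    rhs = U @ ((yt - mu * xt) / (d + delta))
    gebv = G.values[:, obs_idx] @ rhs
    return StFit(list(G.ids), float(mu), gebv, sigma_g2, sigma_e2, delta,
                 float(-res.fun), obs)


def predict_st(f: StFit, line_ids) -> pd.Series:
    """Predicted phenotype mu + GEBV for the requested lines."""
    known = set(f.line_ids)
    unknown = [l for l in line_ids if l not in known]
    if unknown:
        raise KeyError(f"lines not in the fitted relationship matrix: {unknown[:5]}")
    s = f.gebv_series()
    return f.mu + s.loc[list(line_ids)]
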