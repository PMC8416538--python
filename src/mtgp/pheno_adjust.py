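"""Adjusted genotype means (BLUEs/BLUPs), REML variance components,
broad-sense heritability and trait/environment correlations.

The per-environment model is

    y_ij = mu + R_i + G_j + e_ij

with genotype fixed and the complete-block replicate random; its
genotype-random companion fit supplies the variance components for the
entry-mean heritability H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_rep).
The across-environment model adds environment, replicate-within-environment
and genotype-by-environment random effects.

All variance components are REML estimates obtained by an EM algorithm on
the mixed-model equations (components floored at zero, relative tolerance
1e-8), which on balanced data coincides with the classical ANOVA estimators.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "BlueTable",
    "VarComp",
    "CorrelationMatrix",
    "emreml",
    "fit_env_blues",
    "fit_across_env",
    "reml_two_component",
    "heritability",
    "trait_correlations",
    "env_correlations",
    "genetic_correlations_from_fit",
]


@dataclass
class BlueTable:
    """Line x environment x trait adjusted means (long format)."""

    df: pd.DataFrame
    intercepts: dict = field(default_factory=dict)  # (env, trait) -> mu

    REQUIRED = ("line", "env", "trait", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"BlueTable lacks columns {missing}")
        self.df = self.df[list(self.REQUIRED)].copy()
        for c in ("line", "env", "trait"):
            self.df[c] = self.df[c].astype(str)
        dup = self.df.duplicated(subset=["line", "env", "trait"])
        if dup.any():
            raise ValueError("duplicate (line, env, trait) entries in BlueTable")
        self.df = self.df.reset_index(drop=True)

    @property
    def lines(self):
        return sorted(self.df["line"].unique())

    @property
    def envs(self):
        return sorted(self.df["env"].unique())

    @property
    def traits(self):
        return sorted(self.df["trait"].unique())

    def series(self, env, trait) -> pd.Series:
        """Per-line adjusted means for one (env, trait), indexed by line."""
        sub = self.df[(self.df["env"] == str(env)) & (self.df["trait"] == str(trait))]
        return pd.Series(sub["value"].to_numpy(), index=sub["line"].to_numpy())

    def matrix(self, env, traits) -> pd.DataFrame:
        """Lines x traits matrix for one environment (NaN where absent)."""
        sub = self.df[self.df["env"] == str(env)]
        pv = sub.pivot(index="line", columns="trait", values="value")
        return pv.reindex(columns=[str(t) for t in traits])

    def env_matrix(self, trait) -> pd.DataFrame:
        sub = self.df[self.df["trait"] == str(trait)]
        return sub.pivot(index="line", columns="env", values="value")

    @staticmethod
    def concat(tables):
        df = pd.concat([t.df for t in tables], ignore_index=True)
        intercepts = {}
        for t in tables:
            intercepts.update(t.intercepts)
        return BlueTable(df, intercepts)


@dataclass
class VarComp:
    sigma_g2: float
    sigma_e2: float
    sigma_r2: float = 0.0
    n_rep: float = 1.0
    available: bool = True

    def __post_init__(self):
        if self.available:
            for v in (self.sigma_g2, self.sigma_e2, self.sigma_r2):
                if v < 0:
                    raise ValueError("variance components must be >= 0")


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# EM-REML on the mixed-model equations
# ---------------------------------------------------------------------------

def emreml(y, X, Z_blocks, tol: float = 1e-8, max_iter: int = 10000):
    """EM-REML for y = X b + sum_k Z_k u_k + e with u_k ~ N(0, sigma_k^2 I).

    ``X`` must have full column rank.  Returns a dict with the GLS fixed
    effects, BLUPs per block, the variance components and iteration info.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if n <= p:
        raise ValueError("no residual degrees of freedom; model unidentifiable")
    q = [Z.shape[1] for Z in Z_blocks]
    k = len(Z_blocks)

    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if vy <= 1e-12 * max(1.0, float(np.mean(y)) ** 2):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return {
            "beta": beta,
            "u": [np.zeros(qk) for qk in q],
            "sigma2": [0.0] * k,
            "sigma_e2": 0.0,
            "n_iter": 0,
            "converged": True,
        }

    W = np.hstack([X] + list(Z_blocks)) if k else X
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    # index ranges of each random block inside the MME
    starts = np.cumsum([p] + q)[:-1] if k else []
    slices = [slice(s, s + qk) for s, qk in zip(starts, q)]

    sig = [vy / (k + 1)] * k
    sige = vy / (k + 1)
    floor = 1e-12 * vy

    def _solve(sig_cur, sige_cur):
        C = WtW.copy()
        for sl, s2 in zip(slices, sig_cur):
            lam = max(sige_cur, 1e-10 * vy) / max(s2, floor)
            C[sl, sl] += lam * np.eye(sl.stop - sl.start)
        try:
            cf = cho_factor(C)
        except np.linalg.LinAlgError:
            C += 1e-10 * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
            cf = cho_factor(C)
        return cho_solve(cf, Wty), cho_solve(cf, np.eye(C.shape[0]))

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        sol, Cinv = _solve(sig, sige)

        new_sige = (yty - float(sol @ Wty)) / (n - p)
        new_sige = max(new_sige, 0.0)
        new_sig = []
        for sl, qk in zip(slices, q):
            uk = sol[sl]
            tr = float(np.trace(Cinv[sl, sl]))
            new_sig.append(max((float(uk @ uk) + new_sige * tr) / qk, 0.0))

        delta = abs(new_sige - sige) / max(vy, 1e-300)
        for a, b in zip(new_sig, sig):
            delta = max(delta, abs(a - b) / max(vy, 1e-300))
        sig, sige = new_sig, new_sige
        if delta < tol:
            converged = True
            break

    sig = [0.0 if s < 1e-6 * vy else s for s in sig]
    # re-solve with zero-variance blocks dropped (their BLUP is exactly 0),
    # which keeps fixed effects clean when components hit the boundary
    if any(s == 0.0 for s in sig):
        keep_cols = list(range(p))
        for sl, s in zip(slices, sig):
            if s > 0.0:
                keep_cols.extend(range(sl.start, sl.stop))
        keep_cols = np.array(keep_cols)
        sub = np.ix_(keep_cols, keep_cols)
        C = WtW[sub].copy()
        off = p
        for sl, s in zip(slices, sig):
            if s > 0.0:
                qk = sl.stop - sl.start
                lam = max(sige, 1e-10 * vy) / s
                C[off:off + qk, off:off + qk] += lam * np.eye(qk)
                off += qk
        full = np.zeros_like(sol)
        try:
            full[keep_cols] = np.linalg.solve(C, Wty[keep_cols])
        except np.linalg.LinAlgError:
            full[keep_cols] = np.linalg.lstsq(C, Wty[keep_cols], rcond=None)[0]
        sol = full
    beta = sol[:p]
    u = [sol[sl] for sl in slices]
    return {
        "beta": beta,
        "u": u,
        "sigma2": sig,
        "sigma_e2": sige,
        "n_iter": n_iter,
        "converged": converged,
    }


def _dummies(labels):
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    Z = (labels.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


# ---------------------------------------------------------------------------
# per-environment and across-environment fits
# ---------------------------------------------------------------------------

def fit_env_blues(p, env, trait):
    """Per-environment genotype BLUEs and H^2 variance components.

    Fits genotype fixed / replicate random for the BLUEs, plus a
    genotype-random companion fit for (sigma_g2, sigma_r2, sigma_e2).
    Returns (BlueTable, VarComp).
    """
    sub = p.subset(env=env, trait=trait).dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no observations for env={env!r}, trait={trait!r}")
    all_lines = sorted(p.subset(env=None, trait=trait)["line"].unique())
    present = sorted(sub["line"].unique())
    dropped = set(all_lines) - set(present)
    if dropped:
        warnings.warn(
            f"{len(dropped)} line(s) without observations in env {env!r} omitted"
        )
    if len(present) < 2:
        raise ValueError("need >= 2 lines with data to estimate BLUEs")

    y = sub["value"].to_numpy(dtype=float)
    Zg, g_levels = _dummies(sub["line"])
    Zr, r_levels = _dummies(sub["rep"])
    counts = sub.groupby("line").size()
    n_rep = float(counts.mean())

    if counts.max() < 2 or len(r_levels) < 2:
        # unreplicated: BLUE = observed value; H^2 components unavailable
        blues = sub.groupby("line")["value"].mean()
        vc = VarComp(np.nan, np.nan, np.nan, n_rep, available=False)
    else:
        X = np.hstack([np.ones((len(y), 1)), Zg[:, 1:]])
        res = emreml(y, X, [Zr])
        mu = res["beta"][0]
        eff = np.concatenate([[0.0], res["beta"][1:]])
        blues = pd.Series(mu + eff, index=g_levels)
        comp = emreml(y, np.ones((len(y), 1)), [Zr, Zg])
        vc = VarComp(comp["sigma2"][1], comp["sigma_e2"], comp["sigma2"][0], n_rep)

    df = pd.DataFrame(
        {
            "line": blues.index,
            "env": str(env),
            "trait": str(trait),
            "value": blues.to_numpy(),
        }
    )
    table = BlueTable(df, {(str(env), str(trait)): float(blues.mean())})
    return table, vc


def fit_across_env(p, trait, mode: str = "blue"):
    """Across-environment adjusted means for one trait.

    Model: y = mu + env + rep(env) + genotype + GxE + error with env,
    rep(env) and GxE random; genotype fixed (``blue``) or random (``blup``).
    Returns (BlueTable, VarComp); the variance components come from the
    genotype-random fit in either mode.
    """
    if mode not in ("blue", "blup"):
        raise ValueError("mode must be 'blue' or 'blup'")
    sub = p.subset(trait=trait).dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"trait {trait!r} absent from all environments")
    envs = sorted(sub["env"].unique())
    if len(envs) < 2:
        raise ValueError("across-environment fit needs >= 2 environments")

    y = sub["value"].to_numpy(dtype=float)
    Zg, g_levels = _dummies(sub["line"])
    Ze, _ = _dummies(sub["env"])
    Zre, _ = _dummies(sub["env"].str.cat(sub["rep"], sep=":"))
    Zge, _ = _dummies(sub["line"].str.cat(sub["env"], sep=":"))
    n_rep = float(sub.groupby(["line", "env"]).size().mean())

    comp = emreml(y, np.ones((len(y), 1)), [Ze, Zre, Zg, Zge])
    vc = VarComp(comp["sigma2"][2], comp["sigma_e2"], comp["sigma2"][1],
                 n_rep * len(envs))

    if mode == "blue":
        X = np.hstack([np.ones((len(y), 1)), Zg[:, 1:]])
        res = emreml(y, X, [Ze, Zre, Zge])
        mu = res["beta"][0]
        eff = np.concatenate([[0.0], res["beta"][1:]])
        values = mu + eff
        grand_mu = float(values.mean())
    else:
        mu = comp["beta"][0]
        values = mu + comp["u"][2]
        grand_mu = float(mu)

    df = pd.DataFrame(
        {"line": g_levels, "env": "ALL", "trait": str(trait), "value": values}
    )
    return BlueTable(df, {("ALL", str(trait)): grand_mu}), vc


def reml_two_component(values, groups, n_rep: float | None = None) -> VarComp:
    """REML for the one-way random-effects model (groups = lines).

    On balanced data this equals the ANOVA estimators
    sigma_e2 = MSE, sigma_g2 = (MSB - MSE)/r.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(groups).astype(str)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if counts.max() < 2:
        raise ValueError("no within-group replication; sigma_e2 unidentifiable")
    Z, _ = _dummies(groups)
    res = emreml(values, np.ones((values.size, 1)), [Z])
    if n_rep is None:
        n_rep = float(counts.mean())
    return VarComp(res["sigma2"][0], res["sigma_e2"], 0.0, n_rep)


def heritability(v: VarComp) -> float:
    """Entry-mean broad-sense heritability sigma_g2/(sigma_g2 + sigma_e2/n_rep)."""
    if not v.available or not np.isfinite(v.sigma_g2):
        return float("nan")
    if v.n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    denom = v.sigma_g2 + v.sigma_e2 / v.n_rep
    if denom <= 0:
        warnings.warn("both variance components zero; heritability undefined")
        return float("nan")
    return float(v.sigma_g2 / denom)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _pairwise_corr(frame: pd.DataFrame, labels, kind: str) -> CorrelationMatrix:
    var = frame.var(ddof=1)
    degenerate = var[var <= 0].index.tolist()
    if degenerate:
        warnings.warn(f"zero-variance columns, correlations set missing: {degenerate}")
    corr = frame.corr(min_periods=3)
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    corr = corr.reindex(index=labels, columns=labels)
    return CorrelationMatrix(list(labels), corr.to_numpy(), kind)


def trait_correlations(b: BlueTable, traits=None, kind="pearson_phenotypic"):
    """Pairwise-complete Pearson correlations among traits on line-level values.

    With several environments the line-level value is the mean of the
    per-environment adjusted means.
    """
    if kind != "pearson_phenotypic":
        raise ValueError("only pearson_phenotypic is supported here")
    traits = [str(t) for t in (traits if traits is not None else b.traits)]
    wide = (
        b.df[b.df["trait"].isin(traits)]
        .groupby(["line", "trait"])["value"]
        .mean()
        .unstack("trait")
    )
    return _pairwise_corr(wide, traits, kind)


def env_correlations(b: BlueTable, trait) -> CorrelationMatrix:
    """Pearson correlations among environments for one trait."""
    wide = b.env_matrix(trait)
    return _pairwise_corr(wide, list(wide.columns), "pearson_phenotypic")


def genetic_correlations_from_fit(fit) -> CorrelationMatrix:
    """Genetic correlations from the posterior-mean trait covariance Sigma_t."""
    from .kinship import RelationshipMatrix, make_psd

    S = np.asarray(fit.Sigma_t, dtype=float)
    labels = list(fit.trait_names)
    w = np.linalg.eigvalsh(0.5 * (S + S.T))
    if w.min() < 0:
        warnings.warn("posterior-mean Sigma_t not PSD; repairing by eigenvalue clip")
        S = make_psd(RelationshipMatrix(labels, 0.5 * (S + S.T), "sigma")).values
    sd = np.sqrt(np.diag(S))
    corr = S / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(labels, corr, "genetic")
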