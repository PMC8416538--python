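"""Cross-validation schemes, predictive ability and the sparse-testing
allocation experiment.

Schemes (all on repeated random 80/20 line splits unless k-fold is asked
for):

* ST-CV1 — single-trait GBLUP; test lines carry no phenotype at all.
* MT-CV1 — multi-trait model; all traits of test lines are masked.
* MT-CV2 — multi-trait model; only the primary trait of test lines is
  masked, their secondary-trait phenotypes stay in the fit.
* MTME-CV — multi-trait multi-environment model; every cell of a test line
  is masked in every environment.

Predictive ability (PA) is the Pearson correlation between predictions and
the held-out per-environment adjusted means.  The sparse-testing design
phenotypes elite lines in all environments and advanced lines in a subset;
the MTME model predicts the advanced lines in the held-out environments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .bmtme import build_mtme_design, fit_mtme, predict_mtme
from .gblup import fit_gblup, predict_st
from .kinship import RelationshipMatrix
from .mt_bayes import GibbsConfig, fit_mt, predict_mt
from .pheno_adjust import BlueTable

__all__ = [
    "CvPartition",
    "CvResult",
    "SparseDesign",
    "make_cv1_partitions",
    "make_kfold_partitions",
    "predictive_ability",
    "run_st_cv1",
    "run_mt_cv",
    "run_mtme_cv",
    "percent_improvement",
    "build_sparse_design",
    "run_sparse_experiment",
]


@dataclass
class CvPartition:
    rep_index: int
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class CvResult:
    """Per-repetition predictive abilities with (env, trait, model) tags."""

    records: pd.DataFrame  # columns: rep, env, trait, model, pa

    def summary(self, fisher_z: bool = False) -> pd.DataFrame:
        def agg(x):
            x = x.dropna()
            if fisher_z:
                return float(np.tanh(np.arctanh(np.clip(x, -0.999999, 0.999999)).mean()))
            return float(x.mean())

        g = self.records.groupby(["env", "trait", "model"])["pa"]
        out = g.apply(agg).rename("mean_pa").reset_index()
        out["sd"] = g.std().to_numpy()
        out["n_rep"] = g.count().to_numpy()
        return out

    def mean_pa(self, model=None, trait=None) -> float:
        r = self.records
        if model is not None:
            r = r[r["model"] == model]
        if trait is not None:
            r = r[r["trait"] == str(trait)]
        return float(r["pa"].mean())


def make_cv1_partitions(line_ids, train_frac: float = 0.8, reps: int = 10,
                        seed: int = 0):
    """Independent random train/test splits, |train| = round(train_frac * n)."""
    line_ids = list(line_ids)
    n = len(line_ids)
    if n < 10:
        raise ValueError("need >= 10 lines for cross-validation")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(train_frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("train or test set would be empty")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(reps):
        perm = rng.permutation(n)
        train = [line_ids[i] for i in perm[:n_train]]
        test = [line_ids[i] for i in perm[n_train:]]
        out.append(CvPartition(r, train, test, seed))
    return out


def make_kfold_partitions(line_ids, k: int = 5, seed: int = 0):
    """One shuffled k-fold split (the five-subpopulation variant)."""
    line_ids = list(line_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(line_ids))
    folds = np.array_split(perm, k)
    out = []
    for r, fold in enumerate(folds):
        test = [line_ids[i] for i in fold]
        train = [l for l in line_ids if l not in set(test)]
        out.append(CvPartition(r, train, test, seed))
    return out


def predictive_ability(pred, obs) -> float:
    """Pearson correlation between predictions and observed values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3:
        return float("nan")
    if np.var(pred) <= 0 or np.var(obs) <= 0:
        warnings.warn("zero variance in predictions or observations; PA undefined")
        return float("nan")
    return float(pearsonr(pred, obs)[0])


def percent_improvement(pa_model: float, pa_baseline: float) -> float:
    """100 * (pa_model - pa_baseline) / pa_baseline."""
    if not np.isfinite(pa_baseline) or pa_baseline <= 0:
        warnings.warn("baseline predictive ability <= 0; improvement undefined")
        return float("nan")
    return float(100.0 * (pa_model - pa_baseline) / pa_baseline)


# ---------------------------------------------------------------------------
# scheme runners
# ---------------------------------------------------------------------------

def run_st_cv1(b: BlueTable, G: RelationshipMatrix, traits, envs,
               reps: int = 1000, seed: int = 0, train_frac: float = 0.8,
               audit=None) -> CvResult:
    """Single-trait GBLUP under CV1, refitting variances in every replicate."""
    traits = [str(t) for t in traits]
    envs = [str(e) for e in envs]
    lines = sorted(set(b.df["line"]) & set(G.ids))
    parts = make_cv1_partitions(lines, train_frac, reps, seed)
    rows = []
    for part in parts:
        test = set(part.test_ids)
        for env in envs:
            for trait in traits:
                y = b.series(env, trait)
                y_train = y[~y.index.isin(test)]
                if audit is not None:
                    audit("st_cv1", part.rep_index, env, trait, y_train)
                try:
                    fit = fit_gblup(y_train, G)
                    test_obs = y[y.index.isin(test)].dropna()
                    pred = predict_st(fit, list(test_obs.index))
                    pa = predictive_ability(pred.to_numpy(), test_obs.to_numpy())
                except Exception as exc:  # noqa: BLE001 - rep flagged and skipped
                    warnings.warn(f"rep {part.rep_index} ({env}, {trait}) skipped: {exc}")
                    pa = float("nan")
                rows.append((part.rep_index, env, trait, "st_cv1", pa))
    return CvResult(pd.DataFrame(rows, columns=["rep", "env", "trait", "model", "pa"]))


def run_mt_cv(b: BlueTable, G: RelationshipMatrix, traits, envs, scheme: str,
              primary_trait, reps: int = 50, seed: int = 0,
              cfg: GibbsConfig | None = None, train_frac: float = 0.8,
              audit=None) -> CvResult:
    """Multi-trait CV1/CV2; one model per environment, PA on the primary trait."""
    if scheme not in ("cv1", "cv2"):
        raise ValueError("scheme must be 'cv1' or 'cv2'")
    traits = [str(t) for t in traits]
    primary_trait = str(primary_trait)
    if primary_trait not in traits:
        raise ValueError(f"primary trait {primary_trait!r} not in traits {traits}")
    envs = [str(e) for e in envs]
    cfg = cfg or GibbsConfig()
    lines = sorted(set(b.df["line"]) & set(G.ids))
    parts = make_cv1_partitions(lines, train_frac, reps, seed)
    rows = []
    for part in parts:
        test = set(part.test_ids)
        for env in envs:
            Y = b.matrix(env, traits)
            Y = Y.loc[[l for l in lines if l in Y.index]]
            held_out = Y.loc[Y.index.isin(test), primary_trait].dropna()
            Ymask = Y.copy()
            in_test = Ymask.index.isin(test)
            if scheme == "cv1":
                Ymask.loc[in_test, :] = np.nan
            else:
                Ymask.loc[in_test, primary_trait] = np.nan
            if audit is not None:
                audit(f"mt_{scheme}", part.rep_index, env, primary_trait, Ymask)
            try:
                rep_cfg = GibbsConfig(cfg.n_burn, cfg.n_iter, cfg.thin,
                                      cfg.seed + 1000 * part.rep_index)
                fit = fit_mt(Ymask, G, rep_cfg)
                pred = predict_mt(fit, list(held_out.index), primary_trait)
                pa = predictive_ability(pred.to_numpy(), held_out.to_numpy())
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"rep {part.rep_index} ({env}) skipped: {exc}")
                pa = float("nan")
            rows.append((part.rep_index, env, primary_trait, f"mt_{scheme}", pa))
    return CvResult(pd.DataFrame(rows, columns=["rep", "env", "trait", "model", "pa"]))


def run_mtme_cv(b: BlueTable, G: RelationshipMatrix, traits, envs,
                reps: int = 25, seed: int = 0, cfg: GibbsConfig | None = None,
                train_frac: float = 0.8, audit=None) -> CvResult:
    """MTME CV: all cells of test lines masked in every environment."""
    traits = [str(t) for t in traits]
    envs = [str(e) for e in envs]
    cfg = cfg or GibbsConfig()
    lines = sorted(set(b.df["line"]) & set(G.ids))
    parts = make_cv1_partitions(lines, train_frac, reps, seed)
    spec, Y_full = build_mtme_design(
        BlueTable(b.df[b.df["line"].isin(lines)].copy()), traits, envs
    )
    rows = []
    for part in parts:
        test_pos = np.array([spec.line_ids.index(l) for l in part.test_ids
                             if l in spec.line_ids])
        mask_rows = (np.arange(spec.l)[:, None] * spec.n + test_pos[None, :]).ravel()
        Ymask = Y_full.copy()
        Ymask[mask_rows, :] = np.nan
        if audit is not None:
            audit("mtme", part.rep_index, None, None, Ymask)
        try:
            rep_cfg = GibbsConfig(cfg.n_burn, cfg.n_iter, cfg.thin,
                                  cfg.seed + 1000 * part.rep_index)
            fit = fit_mtme(spec, Ymask, G, rep_cfg)
            for e, env in enumerate(spec.env_ids):
                for k, trait in enumerate(spec.trait_names):
                    obs = Y_full[e * spec.n + test_pos, k]
                    ok = np.isfinite(obs)
                    pred = np.array([
                        fit.Beta[e, k] + fit.B1[i, k] + fit.B2[e * spec.n + i, k]
                        for i in test_pos[ok]
                    ])
                    pa = predictive_ability(pred, obs[ok])
                    rows.append((part.rep_index, env, trait, "mtme", pa))
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"rep {part.rep_index} skipped: {exc}")
            for env in spec.env_ids:
                for trait in spec.trait_names:
                    rows.append((part.rep_index, env, trait, "mtme", float("nan")))
    return CvResult(pd.DataFrame(rows, columns=["rep", "env", "trait", "model", "pa"]))


# ---------------------------------------------------------------------------
# sparse testing
# ---------------------------------------------------------------------------

@dataclass
class SparseDesign:
    elite_ids: list
    advanced_ids: list
    train_envs: list
    test_envs: list
    mask: set = field(default_factory=set)  # (line, env) cells hidden from fitting

    def __post_init__(self):
        if set(self.elite_ids) & set(self.advanced_ids):
            raise ValueError("elite and advanced sets overlap")
        if set(self.train_envs) & set(self.test_envs):
            raise ValueError("train and test environments overlap")


def build_sparse_design(elite_ids, advanced_ids, envs, train_envs) -> SparseDesign:
    """Mask = advanced lines x held-out environments."""
    envs = [str(e) for e in envs]
    train_envs = [str(e) for e in train_envs]
    if not set(train_envs) <= set(envs):
        raise ValueError("train_envs must be a subset of envs")
    test_envs = [e for e in envs if e not in set(train_envs)]
    if not test_envs:
        raise ValueError("no held-out environments in the sparse design")
    advanced_ids = [str(a) for a in advanced_ids]
    if not advanced_ids:
        warnings.warn("empty advanced set; sparse mask is empty")
    mask = {(a, e) for a in advanced_ids for e in test_envs}
    return SparseDesign([str(e) for e in elite_ids], advanced_ids,
                        train_envs, test_envs, mask)


def run_sparse_experiment(b: BlueTable, G: RelationshipMatrix,
                          design: SparseDesign, traits,
                          cfg: GibbsConfig | None = None,
                          audit=None) -> pd.DataFrame:
    """Fit the MTME model with the sparse mask and score the held-out cells.

    Returns a table (env, trait, pa, n_lines) over the test environments.
    """
    traits = [str(t) for t in traits]
    cfg = cfg or GibbsConfig(n_iter=15000)
    envs = design.train_envs + design.test_envs
    spec, Y_full = build_mtme_design(b, traits, envs)
    Ymask = Y_full.copy()
    for line, env in design.mask:
        if line in spec.line_ids and env in spec.env_ids:
            r = spec.row_index(line, env)
            Ymask[r, :] = np.nan
    if audit is not None:
        audit("sparse", 0, None, None, Ymask)
    fit = fit_mtme(spec, Ymask, G, cfg)
    rows = []
    adv = [a for a in design.advanced_ids if a in spec.line_ids]
    for env in design.test_envs:
        e = spec.env_ids.index(env)
        for k, trait in enumerate(spec.trait_names):
            obs, pred = [], []
            for line in adv:
                i = spec.line_ids.index(line)
                v = Y_full[e * spec.n + i, k]
                if np.isfinite(v):
                    obs.append(v)
                    pred.append(fit.Beta[e, k] + fit.B1[i, k]
                                + fit.B2[e * spec.n + i, k])
            rows.append((env, trait, predictive_ability(pred, obs), len(obs)))
    return pd.DataFrame(rows, columns=["env", "trait", "pa", "n_lines"])
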