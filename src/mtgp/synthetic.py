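"""Synthetic breeding-trial generator with known truth.

Emulates a winter-wheat multi-environment trial: ~150 related inbred lines
from a modest number of families, genotyped at genome-wide SNPs, phenotyped
for up to five agronomic traits (grain yield, grain protein, test weight,
plant height, days to heading) in five environments with two complete
blocks.

Genotypes: marker allele frequencies are drawn from U(0.05, 0.5); each
family gets a small pool of founder haplotypes and every line mixes two
founder haplotypes per recombination-free block, which produces elevated
within-family relatedness without a full meiosis model.

Phenotypes follow the generative direction of the MTME model: a genotype
main effect B1 ~ MN(0, G, v1 * Sigma_t) plus a genotype-by-environment
effect B2 ~ MN(0, Sigma_E (x) G, v2 * Sigma_t), plus a complete-block
effect and plot noise.  The plot-noise variance is calibrated per
(environment, trait) from the *realized* genetic variance so that the
entry-mean heritability hits its target exactly in expectation:
sigma_plot^2 = n_rep * var(g) * (1 - h2) / h2.

Two presets mirror the season-to-season contrast such trials show:
``season_low`` (weak trait correlations, environment correlations ~0.3)
and ``season_high`` (strong trait correlations, environment correlations
~0.7, yield-protein genetic correlation -0.54).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import MarkerSet, PlotTable
from .kinship import grm_vanraden, make_psd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_season_scenarios",
    "subset_envs",
    "subset_traits",
]

TRAIT_NAMES = ("YLD", "PROT", "TW", "HT", "HD")
TRAIT_BASE = {"YLD": 80.0, "PROT": 13.0, "TW": 77.0, "HT": 92.0, "HD": 160.0}
TRAIT_GENETIC_SD = {"YLD": 4.0, "PROT": 0.5, "TW": 0.9, "HT": 3.0, "HD": 1.2}
TRAIT_H2 = {"YLD": 0.75, "PROT": 0.80, "TW": 0.90, "HT": 0.87, "HD": 0.89}
ENV_OFFSET_FRAC = (-0.05, 0.0, 0.03, -0.02, 0.04, -0.03, 0.02, 0.01)


def _corr(off):
    t = off.shape[0]
    m = off.copy()
    np.fill_diagonal(m, 1.0)
    return m


def _uniform_corr(k, rho):
    return _corr(np.full((k, k), rho))


# strong-season trait correlation structure (yield-protein correlation
# -0.54, typical of a hard-winter-wheat panel); the weak season halves it
_SIGMA_T_HIGH = np.array(
    [
        [1.00, -0.54, -0.15, -0.25, -0.30],
        [-0.54, 1.00, 0.50, 0.30, 0.15],
        [-0.15, 0.50, 1.00, 0.40, 0.15],
        [-0.25, 0.30, 0.40, 1.00, 0.25],
        [-0.30, 0.15, 0.15, 0.25, 1.00],
    ]
)
_SIGMA_T_LOW = _corr(0.52 * _SIGMA_T_HIGH)


@dataclass
class SimConfig:
    n_lines: int = 150
    n_markers: int = 2000
    n_families: int = 15
    n_envs: int = 5
    n_reps: int = 2
    trait_names: tuple = TRAIT_NAMES
    h2: dict = None                     # trait -> target entry-mean H^2
    genetic_sd: dict = None             # trait -> genetic standard deviation
    Sigma_t_corr: np.ndarray = None     # t x t genetic correlations
    Sigma_E_corr: np.ndarray = None     # l x l environment correlations
    env_means: np.ndarray = None        # l x t
    main_effect_prop: float = 0.5       # share of genetic variance in B1
    block_var_frac: float = 0.05        # block variance as fraction of var(g)
    n_blocks: int = 20                  # recombination-free marker blocks
    n_founders: int = 4                 # founder haplotypes per family
    seed: int = 0
    rng_algorithm: str = "numpy PCG64"  # recorded for provenance

    def __post_init__(self):
        self.trait_names = tuple(str(t) for t in self.trait_names)
        t, l = len(self.trait_names), self.n_envs
        if self.h2 is None:
            self.h2 = {k: TRAIT_H2.get(k, 0.75) for k in self.trait_names}
        if self.genetic_sd is None:
            self.genetic_sd = {k: TRAIT_GENETIC_SD.get(k, 1.0) for k in self.trait_names}
        if self.Sigma_t_corr is None:
            self.Sigma_t_corr = _uniform_corr(t, 0.3)
        self.Sigma_t_corr = np.asarray(self.Sigma_t_corr, dtype=float)
        if self.Sigma_E_corr is None:
            self.Sigma_E_corr = _uniform_corr(l, 0.5)
        self.Sigma_E_corr = np.asarray(self.Sigma_E_corr, dtype=float)
        if self.env_means is None:
            base = np.array([TRAIT_BASE.get(k, 0.0) for k in self.trait_names])
            off = np.array(ENV_OFFSET_FRAC[:l])[:, None]
            self.env_means = base[None, :] * (1.0 + off)
        self.env_means = np.asarray(self.env_means, dtype=float)
        for m, name, k in ((self.Sigma_t_corr, "Sigma_t_corr", t),
                           (self.Sigma_E_corr, "Sigma_E_corr", l)):
            if m.shape != (k, k) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric {k}x{k}")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
        for k, v in self.h2.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"heritability for {k} must be in (0,1), got {v}")
        if not 0.0 <= self.main_effect_prop <= 1.0:
            raise ValueError("main_effect_prop must be in [0, 1]")
        if self.n_families > self.n_lines:
            raise ValueError("n_families cannot exceed n_lines")

    @property
    def env_ids(self):
        return [f"E{i + 1}" for i in range(self.n_envs)]

    @property
    def line_ids(self):
        width = len(str(self.n_lines))
        return [f"L{i + 1:0{width}d}" for i in range(self.n_lines)]

    @property
    def families(self):
        # interleaved so that any contiguous line split spans families
        return np.arange(self.n_lines) % self.n_families


@dataclass
class SimTruth:
    """Serialisable ground truth accompanying a simulated data set."""

    line_ids: list
    env_ids: list
    trait_names: list
    B1: np.ndarray
    B2: np.ndarray                       # (l*n) x t, environment-major
    Sigma_t: np.ndarray                  # full-scale genetic covariance
    Sigma_E_corr: np.ndarray
    main_effect_prop: float
    h2_target: dict
    realized_h2: dict = field(default_factory=dict)   # (env, trait) -> H^2
    plot_noise_var: dict = field(default_factory=dict)
    seed: int = 0

    def genetic_values(self, env) -> np.ndarray:
        """True total genetic value B1 + B2 in one environment (n x t)."""
        e = self.env_ids.index(str(env))
        n = len(self.line_ids)
        return self.B1 + self.B2[e * n:(e + 1) * n]

    def to_json(self, path) -> None:
        payload = {
            "line_ids": self.line_ids,
            "env_ids": self.env_ids,
            "trait_names": self.trait_names,
            "B1": self.B1.tolist(),
            "B2": self.B2.tolist(),
            "Sigma_t": self.Sigma_t.tolist(),
            "Sigma_E_corr": self.Sigma_E_corr.tolist(),
            "main_effect_prop": self.main_effect_prop,
            "h2_target": self.h2_target,
            "realized_h2": {f"{e}|{t}": v for (e, t), v in self.realized_h2.items()},
            "plot_noise_var": {f"{e}|{t}": v for (e, t), v in self.plot_noise_var.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return SimTruth(
            d["line_ids"], d["env_ids"], d["trait_names"],
            np.array(d["B1"]), np.array(d["B2"]), np.array(d["Sigma_t"]),
            np.array(d["Sigma_E_corr"]), d["main_effect_prop"], d["h2_target"],
            {tuple(k.split("|")): v for k, v in d["realized_h2"].items()},
            {tuple(k.split("|")): v for k, v in d["plot_noise_var"].items()},
            d["seed"],
        )


def simulate_genotypes(cfg: SimConfig) -> MarkerSet:
    """Family-structured inbred-line dosages; deterministic given the seed."""
    if cfg.n_markers < 10:
        raise ValueError("need >= 10 markers")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    p = rng.uniform(0.05, 0.5, size=cfg.n_markers)
    fam = cfg.families
    # block boundaries and per-line founder choices (marker independent)
    blocks = np.array_split(np.arange(cfg.n_markers), cfg.n_blocks)
    choice = rng.integers(0, cfg.n_founders, size=(cfg.n_lines, cfg.n_blocks, 2))

    def compose(founders):
        # founders: (n_families, n_founders, n_markers) 0/1 haplotypes
        d = np.empty((cfg.n_lines, cfg.n_markers))
        for b, cols in enumerate(blocks):
            h1 = founders[fam, choice[:, b, 0]][:, cols]
            h2 = founders[fam, choice[:, b, 1]][:, cols]
            d[:, cols] = h1 + h2
        return d

    founders = (rng.uniform(size=(cfg.n_families, cfg.n_founders, cfg.n_markers))
                < p).astype(float)
    dos = compose(founders)
    # redraw founder alleles at markers that came out (nearly) monomorphic
    for _ in range(30):
        maf = np.minimum(dos.mean(axis=0) / 2, 1 - dos.mean(axis=0) / 2)
        bad = maf < 0.01
        if not bad.any():
            break
        founders[:, :, bad] = (
            rng.uniform(size=(cfg.n_families, cfg.n_founders, int(bad.sum())))
            < p[bad]
        ).astype(float)
        dos = compose(founders)
    width = len(str(cfg.n_markers))
    marker_ids = [f"M{i + 1:0{width}d}" for i in range(cfg.n_markers)]
    chrom = np.array([f"chr{(i % 21) + 1}" for i in range(cfg.n_markers)], dtype=object)
    pos = np.arange(1, cfg.n_markers + 1) * 1000
    return MarkerSet(cfg.line_ids, marker_ids, dos, chrom, pos)


def simulate_phenotypes(g: MarkerSet, cfg: SimConfig):
    """Draw plot-level phenotypes from the generative model.

    Returns (PlotTable, SimTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    n, l, t = g.n_lines, cfg.n_envs, len(cfg.trait_names)
    G = make_psd(grm_vanraden(g)).values
    L_G = np.linalg.cholesky(G + 1e-10 * np.eye(n))
    sd = np.array([cfg.genetic_sd[k] for k in cfg.trait_names])
    Sigma_t = np.outer(sd, sd) * cfg.Sigma_t_corr
    wt, Vt = np.linalg.eigh(Sigma_t)
    L_t = Vt * np.sqrt(np.clip(wt, 0, None))
    v1, v2 = cfg.main_effect_prop, 1.0 - cfg.main_effect_prop

    B1 = np.sqrt(v1) * (L_G @ rng.standard_normal((n, t))) @ L_t.T
    wE, VE = np.linalg.eigh(cfg.Sigma_E_corr)
    L_E = VE * np.sqrt(np.clip(wE, 0, None))
    Z = rng.standard_normal((l, n, t))
    Z = np.einsum("pq,eqk->epk", L_G, Z)
    Z = np.einsum("ef,fik->eik", L_E, Z)
    B2 = np.sqrt(v2) * np.einsum("eik,mk->eim", Z, L_t)

    records = []
    realized_h2, noise_var = {}, {}
    env_ids, line_ids = cfg.env_ids, g.line_ids
    rep_ids = [f"R{r + 1}" for r in range(cfg.n_reps)]
    for e, env in enumerate(env_ids):
        gval = B1 + B2[e]
        for k, trait in enumerate(cfg.trait_names):
            var_g = float(np.var(gval[:, k], ddof=1))
            h2 = cfg.h2[trait]
            s_plot2 = cfg.n_reps * var_g * (1.0 - h2) / h2
            noise_var[(env, trait)] = s_plot2
            realized_h2[(env, trait)] = var_g / (var_g + s_plot2 / cfg.n_reps)
            block = rng.normal(0.0, np.sqrt(cfg.block_var_frac * var_g),
                               size=cfg.n_reps)
            for r, rep in enumerate(rep_ids):
                vals = (cfg.env_means[e, k] + gval[:, k] + block[r]
                        + rng.normal(0.0, np.sqrt(s_plot2), size=n))
                records.append(pd.DataFrame({
                    "line": line_ids, "env": env, "rep": rep,
                    "trait": trait, "value": vals,
                }))
    plot = PlotTable(pd.concat(records, ignore_index=True))
    truth = SimTruth(
        list(line_ids), list(env_ids), list(cfg.trait_names),
        B1, B2.reshape(l * n, t), Sigma_t, cfg.Sigma_E_corr,
        v1, dict(cfg.h2), realized_h2, noise_var, cfg.seed,
    )
    return plot, truth


def make_season_scenarios():
    """Named presets for the weak- and strong-correlation seasons."""
    low = SimConfig(
        Sigma_t_corr=_SIGMA_T_LOW,
        Sigma_E_corr=_uniform_corr(5, 0.3),
    )
    high = SimConfig(
        Sigma_t_corr=_SIGMA_T_HIGH,
        Sigma_E_corr=_uniform_corr(5, 0.7),
    )
    return {"season_low": low, "season_high": high}


def subset_envs(cfg: SimConfig, n_envs: int) -> SimConfig:
    """A config restricted to the first ``n_envs`` environments."""
    if not 1 <= n_envs <= cfg.n_envs:
        raise ValueError("n_envs out of range")
    return replace(
        cfg,
        n_envs=n_envs,
        Sigma_E_corr=cfg.Sigma_E_corr[:n_envs, :n_envs],
        env_means=cfg.env_means[:n_envs, :],
    )


def subset_traits(cfg: SimConfig, traits) -> SimConfig:
    """A config restricted to a subset of traits (correlations sliced)."""
    traits = [str(t) for t in traits]
    idx = [cfg.trait_names.index(t) for t in traits]
    return replace(
        cfg,
        trait_names=tuple(traits),
        h2={t: cfg.h2[t] for t in traits},
        genetic_sd={t: cfg.genetic_sd[t] for t in traits},
        Sigma_t_corr=cfg.Sigma_t_corr[np.ix_(idx, idx)],
        env_means=cfg.env_means[:, idx],
    )
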