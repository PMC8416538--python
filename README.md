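# mtgp — multi-trait multi-environment genomic prediction

`mtgp` is a Python package for genomic selection in replicated plant
breeding trials. It takes SNP genotypes (VCF or dosage TSV) and plot-level
phenotypes from multi-environment yield trials and produces
genome-estimated breeding values (GEBVs) under four prediction models, the
cross-validation schemes used to compare them, and a sparse-testing
allocation analysis that tells a breeder how well lines phenotyped in a
subset of locations can be predicted in the rest.

It is aimed at breeders and quantitative geneticists who want the complete
workflow — marker QC, genomic relationships, adjusted means, Bayesian
multi-trait G×E models, honest cross-validation — in one tested package,
with a synthetic-trial generator for validating every step against known
truth.

## Models

With per-environment adjusted means (BLUEs) `y` and the additive genomic
relationship matrix `G = WW'/2Σp(1−p)` built from centered dosages:

* **Single-trait GBLUP / rrBLUP** — `y = 1μ + u + ε`, `u ~ N(0, G σ²_g)`,
  fitted by spectral REML; exactly equivalent to ridge regression on
  markers at the matched penalty.
* **Bayesian multi-trait (MT)** — `Y = 1μ' + U + E`,
  `vec(U) ~ N(0, Σ ⊗ G)` with unstructured trait covariance Σ and diagonal
  residuals, Gibbs-sampled with missing-cell augmentation. Supports CV1
  (test lines fully unphenotyped) and CV2 (secondary traits observed on
  test lines).
* **Bayesian multi-trait multi-environment (MTME)** —
  `Y = XB + Z₁b₁ + Z₂b₂ + E` with `b₁ ~ MN(0, G, Σt)` and
  `b₂ ~ MN(0, Σ_E ⊗ G, Σt)`: genotype main effects plus
  genotype × environment × trait effects with a Kronecker covariance,
  unstructured Σt, Σ_E and residual Re.

Predictive ability (PA) is the Pearson correlation between predictions and
held-out adjusted means. Entry-mean heritability is
`H² = σ²_g/(σ²_g + σ²_e/n_rep)`.

## Worked example

Simulate a strong-correlation season (150 lines, 3 environments, a
low-heritability primary trait with an h²=0.7 secondary trait at genetic
correlation 0.9), then compare the schemes:

```python
import numpy as np
from mtgp import *

cfg = SimConfig(
    n_lines=150, n_markers=1000, n_families=15, n_envs=3,
    trait_names=("PRIMARY", "SECONDARY"),
    h2={"PRIMARY": 0.3, "SECONDARY": 0.7},
    genetic_sd={"PRIMARY": 1.0, "SECONDARY": 1.0},
    Sigma_t_corr=np.array([[1.0, 0.9], [0.9, 1.0]]),
    Sigma_E_corr=np.full((3, 3), 0.7) + 0.3 * np.eye(3),
    seed=11,
)
geno = simulate_genotypes(cfg)
plots, truth = simulate_phenotypes(geno, cfg)
G = make_psd(grm_vanraden(geno))
blues = BlueTable.concat([
    fit_env_blues(plots, e, t)[0]
    for e in cfg.env_ids for t in cfg.trait_names
])

chain = GibbsConfig(300, 1200, 3, seed=1)
st   = run_st_cv1(blues, G, ["PRIMARY"], cfg.env_ids, reps=20, seed=42)
cv2  = run_mt_cv(blues, G, cfg.trait_names, cfg.env_ids, "cv2",
                 "PRIMARY", reps=20, seed=42, cfg=chain)
mtme = run_mtme_cv(blues, G, cfg.trait_names, cfg.env_ids,
                   reps=10, seed=42, cfg=chain)

print(f"ST-CV1  mean PA: {st.mean_pa():.3f}")
print(f"MT-CV2  mean PA: {cv2.mean_pa():.3f}")
print(f"MTME    mean PA: {mtme.mean_pa(trait='PRIMARY'):.3f}")
print(f"MT-CV2 improvement over ST-CV1: "
      f"{percent_improvement(cv2.mean_pa(), st.mean_pa()):.0f}%")
```

Output:

```
ST-CV1  mean PA: 0.291
MT-CV2  mean PA: 0.410
MTME    mean PA: 0.328
MT-CV2 improvement over ST-CV1: 41%
```

Read: predicting the low-heritability primary trait from markers alone
(ST-CV1) reaches PA ≈ 0.29; letting the model borrow the correlated
secondary trait observed on the test lines (MT-CV2) lifts it to ≈ 0.41, a
41% gain, and borrowing across correlated environments (MTME) gives an
intermediate gain — the ordering these models are designed to produce when
trait and environment correlations are strong.

A `mtgp` command-line interface drives the same pipeline from a YAML
config (`mtgp simulate`, `qc`, `grm`, `blues`, `cv`, `sparse`, `report`);
every output directory carries a manifest with the config hash and seed.

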