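"""Additive genomic relationship matrices from marker dosages.

Two normalisations of the same centered cross-product are provided:

* ``grm_vanraden`` — G = WW' / (2 * sum_k p_k (1 - p_k)), the additive
  relationship matrix used by all prediction models here;
* ``kinship_centered_ibs`` — K = WW' / (trace(WW')/n), the centered
  identity-by-state kinship whose mean diagonal is 1.

W is the dosage matrix with each column centered at twice the allele
frequency estimated from the analysed lines.  Off-diagonal entries of the
two matrices are proportional; only the scale differs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "grm_vanraden",
    "kinship_centered_ibs",
    "make_psd",
    "write_relationship_tsv",
    "read_relationship_tsv",
]


@dataclass
class RelationshipMatrix:
    ids: list
    values: np.ndarray
    method: str

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(
            [self.ids[i] for i in idx], self.values[np.ix_(idx, idx)], self.method
        )


def _centered(g):
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("missing dosages present; run impute_mean first")
    p = d.mean(axis=0) / 2.0
    return d - 2.0 * p, p


def grm_vanraden(g) -> RelationshipMatrix:
    """Additive GRM with denominator 2*sum p(1-p)."""
    W, p = _centered(g)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(g.line_ids, G, "vanraden")


def kinship_centered_ibs(g) -> RelationshipMatrix:
    """Centered-IBS kinship normalised to mean diagonal 1."""
    W, _ = _centered(g)
    C = W @ W.T
    c = np.trace(C) / g.n_lines
    if c <= 0:
        raise ValueError("all markers monomorphic; kinship normaliser is zero")
    K = C / c
    K = 0.5 * (K + K.T)
    return RelationshipMatrix(g.line_ids, K, "centered_ibs")


def make_psd(m: RelationshipMatrix, eps: float = 1e-8) -> RelationshipMatrix:
    """Clip eigenvalues below ``eps`` up to ``eps`` and reconstruct.

    Leaves an already-PSD matrix numerically unchanged; eigenvectors are
    preserved, which keeps spectral REML stable.
    """
    A = m.values
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("make_psd requires a symmetric matrix")
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    if w.min() >= eps:
        return RelationshipMatrix(m.ids, A, m.method)
    w = np.clip(w, eps, None)
    B = (V * w) @ V.T
    return RelationshipMatrix(m.ids, 0.5 * (B + B.T), m.method)


def write_relationship_tsv(m: RelationshipMatrix, path, sidecar_path=None) -> None:
    m.to_frame().rename_axis("line").to_csv(path, sep="\t")
    if sidecar_path is not None:
        Path(sidecar_path).write_text(
            json.dumps({"method": m.method, "n": m.n}, indent=2)
        )


def read_relationship_tsv(path, method: str = "vanraden") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(list(df.index.astype(str)), df.to_numpy(), method)
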