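"""Genotype / phenotype input-output, marker quality control and imputation.

Genotypes are held as a line x marker dosage matrix (counts of the VCF ALT
allele, 0/1/2, missing as NaN) with a simple marker map (chromosome label and
1-based position; ``unknown`` marks unplaced markers).  Phenotypes are plot
level records in long format: one row per (line, environment, replicate,
trait).

QC follows the standard GBS pipeline conventions: markers with more than 20%
missing calls are removed first, then markers with minor allele frequency
below 0.05 (computed on non-missing calls), then unplaced markers.  Missing
dosages are imputed by the per-marker mean of the non-missing calls, which
yields real-valued dosages downstream.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING_STRINGS = {"NA", ".", "", "NaN", "nan"}
UNMAPPED_CHROMS = {"unknown", "UN", "Un", "un"}

__all__ = [
    "MarkerSet",
    "PlotTable",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "filter_markers",
    "impute_mean",
    "read_phenotypes",
    "write_phenotypes",
]


@dataclass
class MarkerSet:
    """A line x marker dosage matrix with map metadata.

    ``dosages`` is float64 with entries in {0, 1, 2} (or real values after
    imputation) and NaN for missing calls.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray
    chrom: np.ndarray = None
    pos: np.ndarray = None

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids are not unique")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line ids are not unique")
        if self.chrom is None:
            self.chrom = np.array(["unknown"] * self.n_markers, dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is None:
            self.pos = np.zeros(self.n_markers, dtype=int)
        else:
            self.pos = np.asarray(self.pos, dtype=int)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def copy(self) -> "MarkerSet":
        return MarkerSet(
            list(self.line_ids),
            list(self.marker_ids),
            self.dosages.copy(),
            self.chrom.copy(),
            self.pos.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)


@dataclass
class PlotTable:
    """Plot-level phenotype records in long format.

    Columns: line, env, rep, trait, value.  The (line, env, rep, trait) key is
    unique; value may be NaN (recorded but missing).
    """

    df: pd.DataFrame
    trait_units: dict = field(default_factory=dict)

    REQUIRED = ("line", "env", "rep", "trait", "value")

    def __post_init__(self):
        missing_cols = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks columns: {missing_cols}")
        self.df = self.df[list(self.REQUIRED)].copy()
        for c in ("line", "env", "rep", "trait"):
            self.df[c] = self.df[c].astype(str)
        self.df["value"] = pd.to_numeric(self.df["value"], errors="coerce")
        dup = self.df.duplicated(subset=["line", "env", "rep", "trait"])
        if dup.any():
            keys = self.df.loc[dup, ["line", "env", "rep", "trait"]].head(5)
            raise ValueError(
                "duplicate (line, env, rep, trait) keys, e.g.:\n"
                + keys.to_string(index=False)
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def lines(self) -> list:
        return sorted(self.df["line"].unique())

    @property
    def envs(self) -> list:
        return sorted(self.df["env"].unique())

    @property
    def reps(self) -> list:
        return sorted(self.df["rep"].unique())

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique())

    def subset(self, env=None, trait=None) -> pd.DataFrame:
        out = self.df
        if env is not None:
            out = out[out["env"] == str(env)]
        if trait is not None:
            out = out[out["trait"] == str(trait)]
        return out


# ---------------------------------------------------------------------------
# reading / writing genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None, map_path=None) -> MarkerSet:
    """Read a genotype matrix from VCF (biallelic SNPs) or a dosage TSV.

    TSV layout: header row of marker ids, first column of line ids, entries in
    {0, 1, 2} with NA/. for missing.  ``map_path`` may point to a sidecar TSV
    with columns (marker, chrom, pos); without it TSV markers are "unknown".
    """
    path = Path(path)
    if format is None:
        suffixes = "".join(path.suffixes)
        format = "vcf" if ".vcf" in suffixes else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path, map_path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> MarkerSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    line_ids = list(vcf.samples)
    marker_ids, chroms, poss, cols = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT)}); only biallelic SNPs are supported"
            )
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_ids.append(mid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = var.gt_types.astype(float)  # gts012: 0,1,2; 3 = missing
        gt[gt == 3] = np.nan
        cols.append(gt)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    dosages = np.column_stack(cols)
    return MarkerSet(line_ids, marker_ids, dosages, np.array(chroms, dtype=object),
                     np.array(poss, dtype=int))


def _read_tsv(path: Path, map_path=None) -> MarkerSet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    marker_ids = list(df.columns)
    line_ids = list(df.index.astype(str))
    dosages = np.empty((len(line_ids), len(marker_ids)))
    for j, m in enumerate(marker_ids):
        col = df[m]
        for i, raw in enumerate(col):
            s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if s in MISSING_STRINGS:
                dosages[i, j] = np.nan
                continue
            try:
                v = float(s)
            except ValueError:
                v = None
            if v not in (0.0, 1.0, 2.0):
                raise ValueError(
                    f"non-{{0,1,2}} dosage {raw!r} at line {line_ids[i]!r}, "
                    f"marker {m!r}"
                )
            dosages[i, j] = v
    chrom = pos = None
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={"marker": str, "chrom": str})
        mp = mp.set_index("marker").reindex(marker_ids)
        chrom = mp["chrom"].fillna("unknown").to_numpy(dtype=object)
        pos = mp["pos"].fillna(0).astype(int).to_numpy()
    return MarkerSet(line_ids, marker_ids, dosages, chrom, pos)


def write_genotypes_tsv(g: MarkerSet, path, map_path=None) -> None:
    """Write the dosage matrix as TSV (and optionally the marker map)."""
    frame = g.to_frame()
    out = frame.copy()
    # keep integer dosages as integers so the file round-trips exactly
    if np.all((np.isnan(g.dosages)) | (np.mod(g.dosages, 1) == 0)):
        out = frame.astype("Int64")
    out.index.name = "line"
    out.to_csv(path, sep="\t", na_rep="NA")
    if map_path is not None:
        pd.DataFrame(
            {"marker": g.marker_ids, "chrom": g.chrom, "pos": g.pos}
        ).to_csv(map_path, sep="\t", index=False)


def write_vcf(g: MarkerSet, path) -> None:
    """Write integer dosages as a minimal VCF 4.2 (GT field only)."""
    d = g.dosages
    if not np.all(np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))):
        raise ValueError("VCF output requires integer dosages in {0,1,2}")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.line_ids)) + "\n")
        for j, mid in enumerate(g.marker_ids):
            calls = [
                "./." if np.isnan(d[i, j]) else gt_map[d[i, j]]
                for i in range(g.n_lines)
            ]
            fh.write(
                f"{g.chrom[j]}\t{max(int(g.pos[j]), 1)}\t{mid}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# QC and imputation
# ---------------------------------------------------------------------------

def filter_markers(
    g: MarkerSet,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    drop_unmapped: bool = True,
):
    """Apply the marker QC rules; returns (filtered MarkerSet, report dict).

    Order: missing-fraction filter, then MAF on non-missing calls, then
    unplaced markers.  MAF = min(p, 1-p) with p = mean(dosage)/2.
    """
    for name, thr in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    d = g.dosages
    n = d.shape[0]
    miss_frac = np.isnan(d).sum(axis=0) / n
    keep = miss_frac <= max_missing
    n_missing_removed = int((~keep).sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_fail = keep & ~(maf >= min_maf)
    n_maf_removed = int(maf_fail.sum())
    keep &= ~maf_fail

    n_unmapped_removed = 0
    if drop_unmapped:
        unmapped = np.array([c in UNMAPPED_CHROMS for c in g.chrom])
        n_unmapped_removed = int((keep & unmapped).sum())
        keep &= ~unmapped

    if not keep.any():
        raise ValueError(
            "all markers removed by QC; review max_missing/min_maf thresholds"
        )
    idx = np.where(keep)[0]
    out = MarkerSet(
        g.line_ids,
        [g.marker_ids[i] for i in idx],
        d[:, idx],
        g.chrom[idx],
        g.pos[idx],
    )
    report = {
        "n_input": g.n_markers,
        "n_removed_missing": n_missing_removed,
        "n_removed_maf": n_maf_removed,
        "n_removed_unmapped": n_unmapped_removed,
        "n_retained": out.n_markers,
        "max_missing": max_missing,
        "min_maf": min_maf,
    }
    return out, report


def write_filter_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def impute_mean(g: MarkerSet) -> MarkerSet:
    """Replace each missing dosage by the marker's mean non-missing dosage."""
    d = g.dosages.copy()
    nan_mask = np.isnan(d)
    if not nan_mask.any():
        return g.copy()
    n_obs = (~nan_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.marker_ids[i] for i in np.where(n_obs == 0)[0][:5]]
        raise ValueError(f"markers with no observed calls cannot be imputed: {bad}")
    col_mean = np.nansum(d, axis=0) / n_obs
    d[nan_mask] = np.broadcast_to(col_mean, d.shape)[nan_mask]
    return replace(g.copy(), dosages=d)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> PlotTable:
    """Read a long-format phenotype TSV (line, env, rep, trait, value)."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for c in PlotTable.REQUIRED:
        if c not in df.columns:
            raise ValueError(f"phenotype file lacks required column {c!r}")
    values = df["value"].str.strip()
    df["value"] = pd.to_numeric(values.replace(sorted(MISSING_STRINGS), np.nan),
                                errors="raise")
    return PlotTable(df)


def write_phenotypes(p: PlotTable, path) -> None:
    p.df.to_csv(path, sep="\t", index=False, na_rep="NA")
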