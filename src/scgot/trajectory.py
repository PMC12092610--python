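"""Genotype-fraction summaries per cell type and along pseudotime.

Normalized mutant frequency per cell type (per-patient fractions averaged
across patients, restricted to types with more than a floor number of
genotyped cells) and binned genotype-ratio / module-score curves along a
supplied pseudotime with 1.96 x SE bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinnedCurve",
    "normalized_mutant_frequency",
    "genotype_ratio_along_pseudotime",
    "score_along_pseudotime",
]

Z_BAND = 1.96


@dataclass
class BinnedCurve:
    """Per-bin mean with a 1.96 x SE band; underpopulated bins are masked."""

    bin_centers: np.ndarray
    value: np.ndarray
    se: np.ndarray
    n: np.ndarray
    masked: np.ndarray  # True where n < the floor

    @property
    def band_halfwidth(self) -> np.ndarray:
        return Z_BAND * self.se

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.value,
                "se": self.se,
                "n": self.n,
                "masked": self.masked,
            }
        )


def normalized_mutant_frequency(
    cells: pd.DataFrame,
    min_cells: int = 100,
    mode: str = "per_patient_mean",
) -> pd.DataFrame:
    """Mutant-cell frequency per cell type, normalized across patients.

    Only cell types with strictly more than ``min_cells`` genotyped
    (MUT or WT) cells are analyzed. The default mode computes
    n_MUT / (n_MUT + n_WT) within each patient and averages across patients
    so no single patient dominates; ``mode="pooled"`` pools cells across
    patients instead. The mode used is recorded in the output.
    """
    if mode not in ("per_patient_mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    geno = cells[cells["genotype"].isin(["MUT", "WT"])]
    rows = []
    for cell_type, grp in geno.groupby("cell_type", sort=True):
        if len(grp) <= min_cells:
            continue
        if mode == "pooled":
            freq = float((grp["genotype"] == "MUT").mean())
        else:
            per_patient = grp.groupby("patient")["genotype"].apply(
                lambda g: (g == "MUT").mean()
            )
            freq = float(per_patient.mean())
        rows.append(
            {
                "cell_type": cell_type,
                "mutant_frequency": freq,
                "n_genotyped": len(grp),
                "mode": mode,
            }
        )
    if not rows:
        warnings.warn(f"no cell type has more than {min_cells} genotyped cells")
        return pd.DataFrame(
            columns=["cell_type", "mutant_frequency", "n_genotyped", "mode"]
        )
    return pd.DataFrame(rows)


def _bin_assign(t: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bins over [0, 1]; returns (bin index, bin centers)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(t, edges[1:-1]), 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return idx, centers


def genotype_ratio_along_pseudotime(
    cells: pd.DataFrame,
    lineage_mask: np.ndarray | pd.Series | None = None,
    n_bins: int = 20,
    min_per_bin: int = 10,
    denominator: str = "all",
) -> dict[str, BinnedCurve]:
    """MUT and WT cell ratios in equal-width pseudotime bins.

    Per bin, the MUT ratio is n_MUT / n_cells-in-bin (denominator "all",
    i.e. including unassigned genotypes, matching ratios "to all cells" of
    the lineage; ``denominator="assigned"`` restricts to genotyped cells).
    SE is the binomial sqrt(p(1-p)/n); bins with fewer than ``min_per_bin``
    cells are masked. Values are stored on the linear scale; log display is
    a rendering choice.
    """
    if denominator not in ("all", "assigned"):
        raise ValueError(f"unknown denominator {denominator!r}")
    df = cells if lineage_mask is None else cells[np.asarray(lineage_mask)]
    if df.empty:
        raise ValueError("empty lineage")
    if df["pseudotime"].isna().any():
        raise ValueError("pseudotime missing for some lineage cells")
    if denominator == "assigned":
        df = df[df["genotype"].isin(["MUT", "WT"])]
    t = df["pseudotime"].to_numpy(dtype=float)
    idx, centers = _bin_assign(t, n_bins)
    geno = df["genotype"].to_numpy()
    out: dict[str, BinnedCurve] = {}
    n = np.bincount(idx, minlength=n_bins).astype(float)
    for allele in ("MUT", "WT"):
        k = np.bincount(idx[geno == allele], minlength=n_bins).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, k / np.maximum(n, 1), np.nan)
            se = np.where(n > 0, np.sqrt(p * (1 - p) / np.maximum(n, 1)), np.nan)
        out[allele] = BinnedCurve(
            bin_centers=centers,
            value=p,
            se=se,
            n=n.astype(int),
            masked=n < min_per_bin,
        )
    return out


def score_along_pseudotime(
    cells: pd.DataFrame,
    score_column: str,
    group_column: str | None = None,
    n_bins: int = 20,
    min_per_bin: int = 10,
) -> dict[str, BinnedCurve]:
    """Mean module score per pseudotime bin, per group, with 1.96 x SE bands
    (SE = sd / sqrt(n), sample sd)."""
    if score_column not in cells.columns:
        raise ValueError(f"missing score column {score_column!r}")
    groups = (
        {"all": cells}
        if group_column is None
        else {str(g): grp for g, grp in cells.groupby(group_column, sort=True)}
    )
    out: dict[str, BinnedCurve] = {}
    for name, grp in groups.items():
        t = grp["pseudotime"].to_numpy(dtype=float)
        s = grp[score_column].to_numpy(dtype=float)
        idx, centers = _bin_assign(t, n_bins)
        mean = np.full(n_bins, np.nan)
        se = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            vals = s[idx == b]
            n[b] = vals.size
            if vals.size:
                mean[b] = vals.mean()
                se[b] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        out[name] = BinnedCurve(
            bin_centers=centers, value=mean, se=se, n=n, masked=n < min_per_bin
        )
    return out
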