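"""Immune-repertoire clonality, diversity, expansion, SHM and usage tables.

Cells sharing an identical CDR3 nucleotide sequence on their primary chain
(TRB for T cells, IGH for B cells) form a clone. Diversity is summarized by
the Shannon entropy H(P) = -sum p_i log2 p_i over clone frequencies and the
Gini index over clone sizes; clones of more than 20 cells are "expanded";
B-cell somatic hypermutation is categorized as germline (0), low ((0, 3%])
or high (> 3%) mutation frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_clones",
    "shannon_entropy",
    "gini_index",
    "classify_expansion",
    "classify_shm",
    "isotype_table",
    "vdj_usage",
]

PRIMARY_LOCUS = {"T": "TRB", "B": "IGH"}

_ISOTYPE_MAP = {
    "IGHM": "IgM", "IGHD": "IgD", "IGHG1": "IgG1", "IGHG2": "IgG2",
    "IGHG3": "IgG3", "IGHG4": "IgG4", "IGHA1": "IgA1", "IGHA2": "IgA2",
    "IGHE": "IgE",
}

EXPANSION_CLASSES = (
    ("singleton", 1, 1),
    ("small", 2, 5),
    ("medium", 6, 20),
    ("expanded", 21, None),
)


def _primary_chain_per_cell(chains: pd.DataFrame, locus: str) -> pd.DataFrame:
    """One defining chain per cell: the primary-locus chain with the most
    supporting UMIs (ties broken by lexicographic CDR3)."""
    prim = chains[(chains["locus"] == locus) & (chains["productive"].isin(["T", True]))]
    if prim.empty:
        return prim
    umis = prim["umis"] if "umis" in prim.columns else pd.Series(1, index=prim.index)
    ranked = prim.assign(_umis=umis).sort_values(
        ["cell_id", "_umis", "cdr3"], ascending=[True, False, True], kind="stable"
    )
    return ranked.drop_duplicates("cell_id", keep="first").drop(columns="_umis")


def group_clones(
    chains: pd.DataFrame,
    locus: str = "TRB",
    mode: str = "cdr3nt",
) -> pd.DataFrame:
    """Group cells into clones by identical CDR3 nucleotide sequence
    (optionally also identical V and J calls) on the primary chain.

    Only productive chains are considered. Returns one row per clone:
    clone id, defining key, size (cells), frequency, and member barcodes.
    """
    if mode not in ("cdr3nt", "cdr3nt+VJ"):
        raise ValueError(f"unknown clone-grouping mode {mode!r}")
    prim = _primary_chain_per_cell(chains, locus)
    if prim.empty:
        return pd.DataFrame(
            columns=["clone_id", "clone_key", "size", "frequency", "members"]
        )
    if mode == "cdr3nt":
        key = prim["cdr3"].astype(str)
    else:
        key = (
            prim["cdr3"].astype(str)
            + "|" + prim["v_call"].astype(str)
            + "|" + prim["j_call"].astype(str)
        )
    grouped = (
        prim.assign(clone_key=key)
        .groupby("clone_key", sort=True)["cell_id"]
        .apply(lambda s: sorted(s))
    )
    sizes = grouped.str.len()
    total = int(sizes.sum())
    out = pd.DataFrame(
        {
            "clone_key": grouped.index,
            "size": sizes.to_numpy(),
            "frequency": sizes.to_numpy() / total,
            "members": [",".join(m) for m in grouped],
        }
    ).sort_values(["size", "clone_key"], ascending=[False, True], kind="stable")
    out.insert(0, "clone_id", [f"{locus}_clone{i + 1:05d}" for i in range(len(out))])
    return out.reset_index(drop=True)


def shannon_entropy(frequencies) -> float:
    """Shannon entropy H(P) = -sum p_i log2 p_i in bits.

    Requires strictly positive frequencies summing to 1 (no silent
    renormalization). H lies in [0, log2 n].
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p <= 0):
        raise ValueError("clone frequencies must be strictly positive")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    return float(-(p * np.log2(p)).sum())


def gini_index(sizes) -> float:
    """Gini index of inequality over clone sizes: 0 for perfect evenness,
    approaching 1 under extreme clonal dominance.

    G = sum_ij |x_i - x_j| / (2 n^2 xbar), computed via the sorted
    rank formula.
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("empty clone-size vector")
    if np.any(x < 1):
        raise ValueError("clone sizes must be >= 1")
    n = x.size
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * xs).sum()) / (n * xs.sum()) - (n + 1.0) / n)


def classify_expansion(sizes) -> list[str]:
    """Expansion class per clone: singleton (1), small (2-5), medium (6-20),
    expanded (strictly more than 20 cells)."""
    out = []
    for s in np.asarray(sizes):
        s = int(s)
        if s < 1:
            raise ValueError(f"clone size must be >= 1, got {s}")
        for name, lo, hi in EXPANSION_CLASSES:
            if s >= lo and (hi is None or s <= hi):
                out.append(name)
                break
    return out


def classify_shm(mutation_frequencies) -> list[str]:
    """SHM category per sequence: germline (frequency exactly 0), low
    (0 < f <= 0.03), high (f > 0.03)."""
    out = []
    for f in np.asarray(mutation_frequencies, dtype=float):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"mutation frequency {f} outside [0, 1]")
        if f == 0.0:
            out.append("germline")
        elif f <= 0.03:
            out.append("low")
        else:
            out.append("high")
    return out


def isotype_table(
    chains: pd.DataFrame,
    subtypes: pd.Series | dict,
) -> pd.DataFrame:
    """Per-subtype antibody isotype frequencies from heavy-chain constant
    genes (rows sum to 1; unknown constant genes are reported as 'unknown')."""
    heavy = _primary_chain_per_cell(chains, "IGH")
    if heavy.empty:
        raise ValueError("no productive heavy chains")
    sub = pd.Series(subtypes)
    heavy = heavy[heavy["cell_id"].isin(sub.index)]
    isotype = heavy["c_call"].map(_ISOTYPE_MAP).fillna("unknown")
    df = pd.DataFrame(
        {"subtype": sub.loc[heavy["cell_id"]].to_numpy(), "isotype": isotype.to_numpy()}
    )
    counts = df.groupby(["subtype", "isotype"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def vdj_usage(
    chains: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    gene_column: str = "v_call",
) -> tuple[pd.DataFrame, float, float]:
    """V (or J) gene usage frequencies per group plus a between-group
    chi-square test on the usage counts.

    Returns (per-group frequency table with rows summing to 1, chi-square
    statistic, p). With a single group or a single gene the statistic is 0
    and p is 1.
    """
    g = pd.Series(np.asarray(groups), index=chains.index, name="group")
    counts = (
        chains.assign(group=g).groupby(["group", gene_column]).size().unstack(fill_value=0)
    )
    freqs = counts.div(counts.sum(axis=1), axis=0)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return freqs, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy())
    return freqs, float(chi2), float(p)
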