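"""Cell QC, normalization, marker-overlap cluster annotation, control-binned
module scoring, and Wilcoxon differential expression.

The defaults are the published workflow's: cells with < 500 or > 6000
detected genes or > 5% mitochondrial reads are excluded; counts are scaled
to a library size of 10,000 and natural-log transformed; the top 250 most
population-specific reference genes form each subtype's signature; clusters
are assigned by one-sided Fisher's exact overlap between their marker genes
and the signatures; module scores subtract an expression-matched,
bin-sampled control gene set; differential expression uses the two-sided
Wilcoxon rank-sum test with Bonferroni correction, flagging genes with
unadjusted P < 0.05 and log average fold change > 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

__all__ = [
    "SignatureSet",
    "ModuleDefinition",
    "qc_filter",
    "normalize_log",
    "derive_subtype_signatures",
    "fisher_overlap",
    "assign_cluster_identity",
    "module_score",
    "differential_expression",
    "cluster_markers",
]


@dataclass
class SignatureSet:
    """Ordered signature gene lists per subtype, with the universe they came from."""

    signatures: dict[str, list[str]]
    universe_size: int

    def __getitem__(self, subtype: str) -> list[str]:
        return self.signatures[subtype]

    def subtypes(self) -> list[str]:
        return sorted(self.signatures)


@dataclass(frozen=True)
class ModuleDefinition:
    name: str
    genes: tuple[str, ...]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    adata: AnnData,
    min_genes: int = 500,
    max_genes: int = 6000,
    max_mito: float = 0.05,
    mito_prefix: str = "MT-",
) -> tuple[AnnData, dict[str, int]]:
    """Remove low-quality cells.

    Retains cells with ``min_genes <= detected genes <= max_genes`` (below:
    potential fragments; above: potential doublets) and a mitochondrial read
    fraction of at most ``max_mito``. Returns the filtered matrix and per
    criterion removal counts. Idempotent.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty count matrix")
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    low = n_genes < min_genes
    high = n_genes > max_genes
    mito_bad = mito_frac > max_mito
    keep = ~(low | high | mito_bad)
    report = {
        "input_cells": int(adata.n_obs),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_high_mito": int(mito_bad.sum()),
        "retained_cells": int(keep.sum()),
    }
    return adata[keep].copy(), report


def normalize_log(adata: AnnData, scale: int = 10_000) -> AnnData:
    """Library-size normalization to ``scale`` followed by ln(1 + x).

    Raises on zero-library cells (those should have been removed by QC).
    """
    libs = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(libs <= 0):
        raise ValueError(
            f"{int((libs <= 0).sum())} cells have zero library size; run qc_filter first"
        )
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    return out


# ---------------------------------------------------------------------------
# signatures and cluster assignment
# ---------------------------------------------------------------------------

def derive_subtype_signatures(
    reference: pd.DataFrame, top_k: int = 250
) -> SignatureSet:
    """Signature = the genes most specific to each subtype of a reference
    gene-by-subtype mean-expression table.

    Genes are ranked per subtype by (mean in subtype - mean of the rest),
    descending, ties broken by gene name; the top ``top_k`` are kept.
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least two subtypes to derive signatures")
    if top_k > len(reference):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(reference)}-gene universe; truncating"
        )
        top_k = len(reference)
    sigs: dict[str, list[str]] = {}
    for subtype in reference.columns:
        others = reference.drop(columns=subtype).mean(axis=1)
        contrast = reference[subtype] - others
        order = contrast.sort_index().sort_values(ascending=False, kind="stable")
        sigs[str(subtype)] = order.index[:top_k].tolist()
    return SignatureSet(signatures=sigs, universe_size=len(reference))


def fisher_overlap(
    cluster_markers: set[str],
    signature: set[str],
    universe: int,
    alternative: str = "greater",
) -> float:
    """One-sided (enrichment) Fisher's exact p for the overlap of two gene
    sets within a universe of ``universe`` genes."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    m, s = len(cluster_markers), len(signature)
    k = len(cluster_markers & signature)
    neither = universe - m - s + k
    if neither < 0:
        raise ValueError("sets exceed the stated universe")
    table = [[k, m - k], [s - k, neither]]
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def assign_cluster_identity(
    markers_per_cluster: dict[str, set[str]],
    signatures: SignatureSet,
    universe: int,
) -> pd.DataFrame:
    """Label each cluster with the subtype whose signature overlaps its
    markers most significantly.

    Ties on p are broken by larger overlap, then subtype name; forced ties
    (identical p and overlap) are flagged ambiguous. Returns one row per
    cluster with the winning subtype, its p, the overlap, and every
    candidate p.
    """
    rows = []
    for cluster in sorted(markers_per_cluster):
        markers = set(markers_per_cluster[cluster])
        if not markers:
            raise ValueError(f"cluster {cluster!r} has no marker genes")
        cands = []
        for subtype in signatures.subtypes():
            sig = set(signatures[subtype])
            p = fisher_overlap(markers, sig, universe)
            cands.append((p, -len(markers & sig), subtype))
        cands.sort()
        p, neg_ov, subtype = cands[0]
        ambiguous = len(cands) > 1 and cands[1][:2] == cands[0][:2]
        rows.append(
            {
                "cluster": cluster,
                "subtype": subtype,
                "p_value": p,
                "overlap": -neg_ov,
                "ambiguous": ambiguous,
                **{f"p_{s}": pv for pv, _, s in cands},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module scoring
# ---------------------------------------------------------------------------

def module_score(
    expr: AnnData,
    module: ModuleDefinition | list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Control-binned per-cell module score on normalized expression.

    Genes are binned into ``n_bins`` expression bins by their average across
    cells; for each module gene, ``n_ctrl`` control genes are drawn without
    replacement from the non-module genes of its bin (the whole remaining bin
    when it has at most ``n_ctrl`` genes; genes may recur across module
    genes' draws); the score is the mean expression of module genes minus the
    mean of the pooled control draws. When a module covers its entire bin the
    bin itself serves as control, so a module of all genes scores exactly 0.
    Deterministic under a fixed seed, invariant to gene order and to adding a
    constant to the matrix.
    """
    genes = list(module.genes) if isinstance(module, ModuleDefinition) else list(module)
    name = module.name if isinstance(module, ModuleDefinition) else "module"
    present = [g for g in genes if g in expr.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"module {name!r}: {len(missing)} genes absent, dropped")
    if not present:
        raise ValueError(f"module {name!r} has no genes in the matrix")

    X = _dense(expr.X).astype(float)
    var_names = list(expr.var_names)
    gene_pos = {g: i for i, g in enumerate(var_names)}
    avg = X.mean(axis=0)

    # equal-frequency bins of average expression; deterministic tie handling
    order = np.lexsort((np.array(var_names), avg))
    n_genes = len(var_names)
    bins_eff = min(n_bins, n_genes)
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * bins_eff) // n_genes
    members = {b: np.nonzero(bin_of == b)[0] for b in range(bins_eff)}

    rng = np.random.default_rng(seed)
    module_pos = {gene_pos[g] for g in present}
    nonmod = {
        b: np.array([i for i in idx if i not in module_pos], dtype=int)
        for b, idx in members.items()
    }
    ctrl_idx: list[np.ndarray] = []
    for g in sorted(present):  # sorted: gene-order invariance
        b = bin_of[gene_pos[g]]
        pool = nonmod[b]
        # module saturates its bin: widen to expression-adjacent bins
        d = 1
        while pool.size == 0 and (b - d >= 0 or b + d < bins_eff):
            parts = [nonmod[bb] for bb in (b - d, b + d) if 0 <= bb < bins_eff]
            pool = np.concatenate([pool, *parts])
            d += 1
        if pool.size == 0:
            pool = members[b]  # module covers every gene: score is exactly 0
        k = min(n_ctrl, pool.size)
        ctrl_idx.append(rng.choice(pool, size=k, replace=False))
    ctrl = np.concatenate(ctrl_idx)
    mod_idx = np.array([gene_pos[g] for g in present])
    return X[:, mod_idx].mean(axis=1) - X[:, ctrl].mean(axis=1)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    expr: AnnData,
    group_a: np.ndarray | list,
    group_b: np.ndarray | list,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.1,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression, A vs B.

    Log fold change = ln(mean(expm1(A)) + 1) - ln(mean(expm1(B)) + 1) on the
    log-normalized matrix. Bonferroni-adjusted p is reported alongside; the
    DE flag uses the unadjusted P < ``p_threshold`` with log fold change >
    ``lfc_threshold``. Genes constant across both groups get p = 1.
    """
    A = _dense(expr[np.asarray(group_a)].X).astype(float)
    B = _dense(expr[np.asarray(group_b)].X).astype(float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    n_genes = A.shape[1]
    pooled = np.vstack([A, B])
    constant = np.ptp(pooled, axis=0) == 0

    p = np.ones(n_genes)
    varying = ~constant
    if varying.any():
        res = stats.mannwhitneyu(
            A[:, varying], B[:, varying], alternative="two-sided", axis=0
        )
        p[varying] = res.pvalue
    p_adj = np.minimum(p * n_genes, 1.0)
    lfc = np.log(np.expm1(A).mean(axis=0) + 1.0) - np.log(
        np.expm1(B).mean(axis=0) + 1.0
    )
    out = pd.DataFrame(
        {
            "gene": list(expr.var_names),
            "log_fc": lfc,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )
    out["is_de"] = (out["p_value"] < p_threshold) & (out["log_fc"] > lfc_threshold)
    return out


def cluster_markers(
    expr: AnnData,
    cluster_labels: pd.Series | np.ndarray,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.1,
) -> dict[str, set[str]]:
    """Marker genes per cluster: one-vs-rest differential expression with the
    standard thresholds (unadjusted P < 0.05, log average fold change > 0.1)."""
    labels = np.asarray(cluster_labels)
    out: dict[str, set[str]] = {}
    for cl in sorted(pd.unique(labels)):
        mask = labels == cl
        de = differential_expression(
            expr, np.nonzero(mask)[0], np.nonzero(~mask)[0],
            p_threshold=p_threshold, lfc_threshold=lfc_threshold,
        )
        out[str(cl)] = set(de.loc[de["is_de"], "gene"])
    return out
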