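"""Synthetic single-cell cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
hemizygous mutant/wild-type cell mixture whose mutant fraction depends on
lineage (high in myeloid cells, absent in T and B cells, intermediate and
declining along pseudotime in NK cells), sparse per-cell capture of the
variant locus by a targeted amplicon (~17%) and by ordinary transcriptome
reads (~5%), PCR duplication with occasional single-edit UMI corruption,
marker-structured expression counts, power-law clone sizes, and
subtype-dependent somatic hypermutation in B cells.

Every generator is a pure function of (ground truth, config, seed): the same
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "SimulatedCohort",
    "simulate_cells",
    "simulate_amplicon_reads",
    "simulate_tagged_reads",
    "simulate_counts",
    "simulate_repertoire",
    "simulate_cohort",
]

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

# Fixture module gene lists used by the scoring stage; included in the
# synthetic gene universe so module scores can be computed end to end.
HLA_CLASS_II_GENES = [
    "HLA-DRA", "HLA-DRB1", "HLA-DRB5", "HLA-DQA1", "HLA-DQA2", "HLA-DQB1",
    "HLA-DMA", "HLA-DMB", "HLA-DPA1", "HLA-DPB1",
]
S100A_ALARMIN_GENES = ["S100A8", "S100A9", "S100A12"]
EXHAUSTION_GENES = [
    "CXCL13", "HAVCR2", "PDCD1", "TIGIT", "LAG3", "CTLA4", "LAYN", "RBPJ",
    "VCAM1", "GZMB", "TOX", "MYO7A",
]

_TRBV = ["TRBV2", "TRBV5-1", "TRBV6-5", "TRBV7-9", "TRBV9", "TRBV19", "TRBV20-1", "TRBV28"]
_TRBJ = ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7"]
_TRAV = ["TRAV1-2", "TRAV8-2", "TRAV12-1", "TRAV17", "TRAV29"]
_TRAJ = ["TRAJ12", "TRAJ23", "TRAJ33", "TRAJ49"]
_IGHV = ["IGHV1-18", "IGHV1-69", "IGHV3-23", "IGHV3-30", "IGHV4-34", "IGHV4-59", "IGHV5-51"]
_IGHJ = ["IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"]
_IGKV = ["IGKV1-39", "IGKV3-20", "IGKV4-1"]
_IGKJ = ["IGKJ1", "IGKJ2", "IGKJ4"]

# heavy-chain constant-region usage per B subtype; plasmablasts skew to IgG
_ISOTYPE_WEIGHTS = {
    "Naive_B": {"IGHM": 0.7, "IGHD": 0.3},
    "Memory_B": {
        "IGHM": 0.20, "IGHG1": 0.30, "IGHG2": 0.15, "IGHG3": 0.10,
        "IGHA1": 0.20, "IGHA2": 0.05,
    },
    "Plasmablast": {
        "IGHG1": 0.45, "IGHG3": 0.20, "IGHG4": 0.05, "IGHG2": 0.05,
        "IGHA1": 0.15, "IGHM": 0.10,
    },
}


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _BASES[idx]])


def _unique_barcodes(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        for bc in _random_seqs(rng, n - len(out), length):
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.array(out)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def simulate_cells(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-cell ground truth: barcode, patient, type, pseudotime, genotype.

    NK mutant probability at pseudotime ``t`` is
    ``logistic(logit(p0) - decay * t)`` with ``p0`` the configured NK mutant
    fraction; all other lineages use their configured fraction directly.
    """
    config.validate()
    n = config.n_patients * config.n_cells_per_patient
    types = sorted(config.cell_type_proportions)
    probs = np.array([config.cell_type_proportions[t] for t in types])
    cell_type = rng.choice(types, size=n, p=probs / probs.sum())
    patient = np.repeat(
        [f"P{i + 1:02d}" for i in range(config.n_patients)],
        config.n_cells_per_patient,
    )
    pseudotime = rng.uniform(0.0, 1.0, size=n)
    p_mut = np.zeros(n)
    for t in types:
        mask = cell_type == t
        p0 = config.mutant_fraction_by_type.get(t, 0.0)
        if t == "NK" and 0.0 < p0 < 1.0 and config.nk_pseudotime_decay > 0:
            logit0 = np.log(p0 / (1.0 - p0))
            p_mut[mask] = _logistic(logit0 - config.nk_pseudotime_decay * pseudotime[mask])
        else:
            p_mut[mask] = p0
    genotype = np.where(rng.uniform(size=n) < p_mut, "MUT", "WT")
    barcode = _unique_barcodes(rng, n, config.barcode_length)

    b_subtype = np.full(n, ".", dtype=object)
    b_mask = cell_type == "B"
    b_subtype[b_mask] = rng.choice(
        ["Naive_B", "Memory_B"], size=int(b_mask.sum()), p=[0.6, 0.4]
    )
    b_subtype[cell_type == "Plasmablast"] = "Plasmablast"

    return pd.DataFrame(
        {
            "cell_barcode": barcode,
            "patient": patient,
            "cell_type": cell_type,
            "b_subtype": b_subtype,
            "pseudotime": pseudotime,
            "genotype": genotype,
        }
    )


# ---------------------------------------------------------------------------
# amplicon and transcriptome reads at the variant locus
# ---------------------------------------------------------------------------

def _locus_reads(
    cells: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    capture_rate: float,
    umis_per_cell_mean: float,
    corrupt_umis: bool,
) -> pd.DataFrame:
    """Shared read machinery: capture, UMI emission, PCR duplication, errors.

    Returns one row per read: cell_barcode, umi, locus_base (WT/MUT).
    """
    rows: list[tuple[str, str, str]] = []
    captured = rng.uniform(size=len(cells)) < capture_rate
    for bc, geno in zip(
        cells.loc[captured, "cell_barcode"], cells.loc[captured, "genotype"]
    ):
        n_umis = 1 + rng.poisson(max(umis_per_cell_mean - 1.0, 0.0))
        umis = _random_seqs(rng, n_umis, config.umi_length)
        for umi in umis:
            n_reads = 1 + rng.poisson(config.reads_per_umi_mean)
            for k in range(n_reads):
                read_umi = umi
                if (
                    corrupt_umis
                    and k > 0
                    and rng.uniform() < config.umi_error_rate
                ):
                    pos = rng.integers(0, config.umi_length)
                    alt = rng.choice([b for b in "ACGT" if b != umi[pos]])
                    read_umi = umi[:pos] + alt + umi[pos + 1 :]
                base = geno
                if rng.uniform() < config.per_base_error_rate:
                    base = "WT" if base == "MUT" else "MUT"
                rows.append((bc, read_umi, base))
    return pd.DataFrame(rows, columns=["cell_barcode", "umi", "locus_base"])


def simulate_amplicon_reads(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Targeted amplicon reads: each captured cell emits >=1 UMI, each UMI
    1 + Poisson(reads_per_umi_mean) PCR duplicates; duplicate reads carry a
    single-substitution UMI corruption with probability ``umi_error_rate``;
    the locus base flips allele with probability ``per_base_error_rate``."""
    return _locus_reads(
        cells,
        config,
        rng,
        capture_rate=config.amplicon_capture_rate,
        umis_per_cell_mean=config.umis_per_cell_mean,
        corrupt_umis=True,
    )


def simulate_tagged_reads(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Transcriptome reads at the variant position, as a tagged-read table
    (cell_barcode, umi, base_at_variant); a small fraction of reads lose
    their CB or UB tag (recorded as '.')."""
    df = _locus_reads(
        cells,
        config,
        rng,
        capture_rate=config.transcriptome_capture_rate,
        umis_per_cell_mean=config.transcriptome_umis_per_cell_mean,
        corrupt_umis=False,
    ).rename(columns={"locus_base": "base_at_variant"})
    if len(df) and config.missing_tag_rate > 0:
        missing = rng.uniform(size=len(df)) < config.missing_tag_rate
        which_cb = rng.uniform(size=len(df)) < 0.5
        df.loc[missing & which_cb, "cell_barcode"] = "."
        df.loc[missing & ~which_cb, "umi"] = "."
    return df


# ---------------------------------------------------------------------------
# expression counts and reference profiles
# ---------------------------------------------------------------------------

def simulate_counts(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[AnnData, pd.DataFrame, dict[str, list[str]]]:
    """Marker-structured UMI counts, the matching reference expression table,
    and the true marker map.

    Each cell type has ``n_markers_per_type`` exclusive marker genes whose
    Poisson rate is multiplied by ``marker_fold_change`` in cells of that
    type. Thirteen mitochondrial genes provide a realistic baseline
    mitochondrial fraction; small planted subpopulations of low-complexity
    and high-mitochondrial cells exercise the QC filter.
    """
    types = sorted(config.cell_type_proportions)
    named = HLA_CLASS_II_GENES + S100A_ALARMIN_GENES + EXHAUSTION_GENES
    marker_genes = {
        t: [f"MK-{t.upper()}-{i + 1}" for i in range(config.n_markers_per_type)]
        for t in types
    }
    all_markers = [g for t in types for g in marker_genes[t]]
    n_named = len(named) + len(all_markers)
    n_filler = max(config.n_background_genes - n_named, 0)
    filler = [f"GENE{i + 1:05d}" for i in range(n_filler)]
    genes = named + all_markers + filler + MITO_GENES
    n_genes = len(genes)

    base_lam = rng.gamma(0.6, 1.2, size=n_genes) + 0.05
    mito_idx = np.arange(n_genes - len(MITO_GENES), n_genes)
    base_lam[mito_idx] = 2.0

    gene_pos = {g: i for i, g in enumerate(genes)}
    marker_idx = {t: np.array([gene_pos[g] for g in marker_genes[t]]) for t in types}

    n_cells = len(cells)
    size_factor = rng.lognormal(0.0, 0.3, size=n_cells)
    low_q = rng.uniform(size=n_cells) < config.low_quality_cell_fraction
    size_factor[low_q] *= 0.08
    high_mito = rng.uniform(size=n_cells) < config.high_mito_cell_fraction

    blocks: list[sp.csr_matrix] = []
    block = 1000
    ct = cells["cell_type"].to_numpy()
    for start in range(0, n_cells, block):
        stop = min(start + block, n_cells)
        lam = np.tile(base_lam, (stop - start, 1))
        for t in types:
            rows = np.nonzero(ct[start:stop] == t)[0]
            if rows.size:
                lam[np.ix_(rows, marker_idx[t])] *= config.marker_fold_change
        lam *= size_factor[start:stop, None]
        hm = np.nonzero(high_mito[start:stop])[0]
        if hm.size:
            lam[np.ix_(hm, mito_idx)] *= 4.0
        blocks.append(sp.csr_matrix(rng.poisson(lam).astype(np.int32)))
    X = sp.vstack(blocks, format="csr")

    obs = cells.set_index("cell_barcode")[["patient", "cell_type", "pseudotime"]].copy()
    obs.index.name = "cell_barcode"
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_mito"] = var.index.str.startswith("MT-")
    marker_of = pd.Series(".", index=var.index, dtype=object)
    for t in types:
        marker_of.loc[marker_genes[t]] = t
    var["marker_of"] = marker_of
    adata = AnnData(X=X, obs=obs, var=var)

    # reference table: true per-type mean expression (markers elevated)
    ref = pd.DataFrame(
        {t: base_lam.copy() for t in types}, index=pd.Index(genes, name="gene")
    )
    for t in types:
        ref.iloc[marker_idx[t], ref.columns.get_loc(t)] *= config.marker_fold_change
    return adata, ref, marker_genes


# ---------------------------------------------------------------------------
# immune repertoire
# ---------------------------------------------------------------------------

def _zipf_clone_sizes(
    rng: np.random.Generator, n_cells: int, alpha: float
) -> list[int]:
    """Discrete power-law (zeta) clone sizes truncated at the group size,
    drawn until all cells are assigned."""
    sizes: list[int] = []
    remaining = n_cells
    while remaining > 0:
        s = int(rng.zipf(alpha))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float], n: int) -> np.ndarray:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return rng.choice(keys, size=n, p=p / p.sum())


def _shm_draw(
    rng: np.random.Generator, mean: float, conc: float, n: int
) -> np.ndarray:
    if mean <= 0.0:
        return np.zeros(n)
    if mean >= 1.0:
        return np.ones(n)
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=n)


def simulate_repertoire(
    cells: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AIRR-style receptor chains for T and B lineage cells.

    Clone sizes follow a zeta distribution with exponent ``clone_size_alpha``
    truncated at the per-patient lineage size; clone members share CDR3 and
    V/J calls. B-cell mutation frequencies are beta-distributed around the
    subtype mean from ``shm_by_subtype``; plasmablast heavy chains skew to
    IgG. Returns (chain table, ground-truth clone table).
    """
    chain_rows: list[dict] = []
    clone_rows: list[dict] = []
    for patient, pat_cells in cells.groupby("patient", sort=True):
        for lineage, loci in (("T", ("TRB", "TRA")), ("B", ("IGH", "IGK"))):
            if lineage == "T":
                members = pat_cells[pat_cells["cell_type"] == "T"]
            else:
                members = pat_cells[pat_cells["cell_type"].isin(["B", "Plasmablast"])]
            if members.empty:
                continue
            barcodes = members["cell_barcode"].to_numpy()
            order = rng.permutation(len(barcodes))
            sizes = _zipf_clone_sizes(rng, len(barcodes), config.clone_size_alpha)
            primary, secondary = loci
            if primary == "TRB":
                v_cat, j_cat, c_cat = _TRBV, _TRBJ, ["TRBC1", "TRBC2"]
                v2, j2, c2 = _TRAV, _TRAJ, ["TRAC"]
            else:
                v_cat, j_cat, c_cat = _IGHV, _IGHJ, None
                v2, j2, c2 = _IGKV, _IGKJ, ["IGKC"]
            pos = 0
            for k, size in enumerate(sizes):
                clone_bc = barcodes[order[pos : pos + size]]
                pos += size
                clone_id = f"{patient}_{primary}_{k + 1:04d}"
                cdr3 = "".join(rng.choice(list("ACGT"), size=36))
                cdr3_aa = "C" + "".join(rng.choice(_AA, size=10)) + "F"
                v_call = str(rng.choice(v_cat))
                j_call = str(rng.choice(j_cat))
                clone_rows.append(
                    {"clone_id": clone_id, "patient": patient, "locus": primary,
                     "size": size}
                )
                sub = members.set_index("cell_barcode").loc[clone_bc, "b_subtype"]
                for bc in clone_bc:
                    subtype = sub.loc[bc] if lineage == "B" else "."
                    if lineage == "B":
                        weights = _ISOTYPE_WEIGHTS.get(
                            subtype, _ISOTYPE_WEIGHTS["Memory_B"]
                        )
                        c_call = str(_weighted_choice(rng, weights, 1)[0])
                        mean, conc = config.shm_by_subtype.get(subtype, (0.02, 40.0))
                        mu = float(_shm_draw(rng, mean, conc, 1)[0])
                    else:
                        c_call = str(rng.choice(c_cat))
                        mu = 0.0
                    productive = "T" if rng.uniform() < 0.97 else "F"
                    chain_rows.append(
                        {
                            "cell_id": bc, "patient": patient, "locus": primary,
                            "productive": productive, "cdr3": cdr3,
                            "cdr3_aa": cdr3_aa, "v_call": v_call, "j_call": j_call,
                            "c_call": c_call, "mu_freq": round(mu, 6),
                            "umis": int(1 + rng.poisson(2.0)),
                            "clone_id": clone_id,
                        }
                    )
                    # one secondary (light / alpha) chain per cell
                    chain_rows.append(
                        {
                            "cell_id": bc, "patient": patient, "locus": secondary,
                            "productive": "T",
                            "cdr3": "".join(rng.choice(list("ACGT"), size=33)),
                            "cdr3_aa": "C" + "".join(rng.choice(_AA, size=9)) + "F",
                            "v_call": str(rng.choice(v2)),
                            "j_call": str(rng.choice(j2)),
                            "c_call": str(rng.choice(c2)),
                            "mu_freq": round(mu, 6) if lineage == "B" else 0.0,
                            "umis": int(1 + rng.poisson(2.0)),
                            "clone_id": ".",
                        }
                    )
    chains = pd.DataFrame(
        chain_rows,
        columns=[
            "cell_id", "patient", "locus", "productive", "cdr3", "cdr3_aa",
            "v_call", "j_call", "c_call", "mu_freq", "umis", "clone_id",
        ],
    )
    clones = pd.DataFrame(clone_rows, columns=["clone_id", "patient", "locus", "size"])
    return chains, clones


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the generating ground truth."""

    config: SimulationConfig
    cells: pd.DataFrame                    # ground truth per cell
    amplicon_reads: pd.DataFrame           # cell_barcode, umi, locus_base
    tagged_reads: pd.DataFrame             # cell_barcode, umi, base_at_variant
    counts: AnnData                        # genes x cells (cells as obs)
    reference_profiles: pd.DataFrame       # gene x subtype mean expression
    chains: pd.DataFrame                   # AIRR-style receptor chains
    true_clones: pd.DataFrame              # clone_id, patient, locus, size
    markers: dict[str, list[str]]          # true marker genes per cell type

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text interchange files; returns paths."""
        from . import io as scio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": out / "amplicon_R1.fastq",
            "r2": out / "amplicon_R2.fastq",
            "tagged_reads": out / "tagged_reads.tsv",
            "matrix": out / "matrix.mtx",
            "genes": out / "genes.tsv",
            "barcodes": out / "barcodes.tsv",
            "cell_metadata": out / "cell_metadata.tsv",
            "reference_profiles": out / "reference_profiles.tsv",
            "receptor_chains": out / "receptor_chains.tsv",
            "ground_truth": out / "ground_truth_cells.tsv",
            "true_clones": out / "ground_truth_clones.tsv",
            "markers": out / "ground_truth_markers.tsv",
            "config": out / "config.yaml",
        }
        scio.write_fastq_pair(
            self.amplicon_reads, self.config.locus, paths["r1"], paths["r2"]
        )
        scio.write_tsv(self.tagged_reads, paths["tagged_reads"])
        scio.write_count_matrix(
            self.counts, paths["matrix"], paths["genes"], paths["barcodes"]
        )
        meta = self.cells[["cell_barcode", "patient", "cell_type", "pseudotime"]].copy()
        meta["cluster"] = self.cells["cell_type"]  # cluster labels are inputs
        scio.write_tsv(meta, paths["cell_metadata"])
        scio.write_tsv(
            self.reference_profiles.reset_index(), paths["reference_profiles"]
        )
        scio.write_tsv(self.chains, paths["receptor_chains"])
        scio.write_tsv(self.cells, paths["ground_truth"])
        scio.write_tsv(self.true_clones, paths["true_clones"])
        mk = pd.DataFrame(
            [(t, g) for t in sorted(self.markers) for g in self.markers[t]],
            columns=["cell_type", "gene"],
        )
        scio.write_tsv(mk, paths["markers"])
        self.config.save(paths["config"])
        return paths


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate the full synthetic cohort bundle from one root seed.

    Randomness is split per stage from ``config.seed`` so each component is
    individually reproducible.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise ConfigurationError("pass either a config object or keyword overrides")
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    cells = simulate_cells(config, streams[0])
    amplicon = simulate_amplicon_reads(cells, config, streams[1])
    tagged = simulate_tagged_reads(cells, config, streams[2])
    counts, ref, markers = simulate_counts(cells, config, streams[3])
    chains, clones = simulate_repertoire(cells, config, streams[4])
    return SimulatedCohort(
        config=config,
        cells=cells,
        amplicon_reads=amplicon,
        tagged_reads=tagged,
        counts=counts,
        reference_profiles=ref,
        chains=chains,
        true_clones=clones,
        markers=markers,
    )
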