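"""End-to-end pipeline: simulate -> genotype (GoT) -> sniff -> annotate ->
trajectory -> repertoire, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as scio
from .annotation import (
    ModuleDefinition,
    assign_cluster_identity,
    cluster_markers,
    derive_subtype_signatures,
    module_score,
    normalize_log,
    qc_filter,
)
from .config import PipelineConfig, SimulationConfig
from .genotyping import default_umi_threshold, genotype_cells
from .repertoire import (
    classify_expansion,
    classify_shm,
    gini_index,
    group_clones,
    isotype_table,
    shannon_entropy,
    vdj_usage,
)
from .simulate import (
    EXHAUSTION_GENES,
    HLA_CLASS_II_GENES,
    S100A_ALARMIN_GENES,
    simulate_cohort,
)
from .sniffer import TaggedRead, sniff_cells
from .trajectory import genotype_ratio_along_pseudotime, normalized_mutant_frequency

FIXTURE_MODULES = [
    ModuleDefinition("HLA_class_II", tuple(HLA_CLASS_II_GENES)),
    ModuleDefinition("S100A_alarmins", tuple(S100A_ALARMIN_GENES)),
    ModuleDefinition("Exhaustion", tuple(EXHAUSTION_GENES)),
]


def _tagged_reads_from_frame(df: pd.DataFrame) -> list[TaggedRead]:
    return [
        TaggedRead(str(r.cell_barcode), str(r.umi), str(r.base_at_variant))
        for r in df.itertuples(index=False)
    ]


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    pipe_config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on a freshly simulated cohort and write all outputs.

    Returns a manifest dict (also written as ``manifest.json``) recording the
    package version, seeds, parameters, and output checksums; reruns with the
    same seeds and parameters are byte-identical.
    """
    pipe = pipe_config or PipelineConfig()
    sim = sim_config or SimulationConfig(seed=pipe.seed)
    out = Path(out_dir or pipe.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    cohort = simulate_cohort(sim)
    paths = cohort.write(out / "simulated")

    # --- GoT genotyping ---------------------------------------------------
    reads = list(
        scio.read_fastq_pair(
            paths["r1"], paths["r2"], sim.locus, sim.barcode_length, sim.umi_length
        )
    )
    threshold = (
        default_umi_threshold(sim.umi_length)
        if pipe.umi_threshold == "auto"
        else int(pipe.umi_threshold)
    )
    got = genotype_cells(reads, threshold=threshold, chunk_size=pipe.chunk_size)
    scio.write_tsv(got.umi_frame(), out / "got_umis.tsv", {"threshold": threshold})
    scio.write_tsv(
        got.cell_frame(),
        out / "got_cells.tsv",
        {"threshold": threshold, "conflicted_cells": got.n_conflicted_cells},
    )

    # --- transcriptome sniffer -------------------------------------------
    sniffed = sniff_cells(
        _tagged_reads_from_frame(cohort.tagged_reads),
        threshold=pipe.sniffer_threshold,
        strict_greater=pipe.sniffer_strict_greater,
    )
    scio.write_tsv(
        sniffed.cell_frame(), out / "sniffer_cells.tsv", sniffed.report
    )

    # --- annotation -------------------------------------------------------
    adata = cohort.counts
    filtered, qc_report = qc_filter(
        adata, pipe.qc_min_genes, pipe.qc_max_genes, pipe.qc_max_mito, pipe.mito_prefix
    )
    expr = normalize_log(filtered)
    ref = cohort.reference_profiles.loc[
        cohort.reference_profiles.index.intersection(expr.var_names)
    ]
    signatures = derive_subtype_signatures(ref, top_k=pipe.top_k_signature_genes)
    markers = cluster_markers(expr, filtered.obs["cell_type"])
    universe = len(ref)
    assignments = assign_cluster_identity(markers, signatures, universe)
    scio.write_tsv(assignments, out / "cluster_assignments.tsv", {"universe": universe})
    scores = pd.DataFrame({"cell_barcode": list(expr.obs_names)})
    for mod in FIXTURE_MODULES:
        scores[mod.name] = module_score(
            expr, mod, pipe.module_n_bins, pipe.module_n_ctrl, seed=pipe.seed
        )
    scio.write_tsv(scores, out / "module_scores.tsv")

    # --- trajectory -------------------------------------------------------
    cell_table = cohort.cells[
        ["cell_barcode", "patient", "cell_type", "pseudotime"]
    ].merge(
        got.cell_frame()[["cell_barcode", "genotype"]], on="cell_barcode", how="left"
    )
    cell_table["genotype"] = cell_table["genotype"].fillna("UNASSIGNED")
    scio.write_tsv(cell_table, out / "cell_table.tsv")
    freq = normalized_mutant_frequency(cell_table, min_cells=pipe.min_cells_per_type)
    scio.write_tsv(freq, out / "normalized_mutant_frequency.tsv")
    nk = cell_table["cell_type"] == "NK"
    curves = genotype_ratio_along_pseudotime(
        cell_table, nk, n_bins=pipe.trajectory_n_bins,
        min_per_bin=pipe.trajectory_min_per_bin,
    )
    for allele, curve in curves.items():
        scio.write_tsv(curve.frame(), out / f"nk_{allele.lower()}_ratio_curve.tsv")

    # --- repertoire -------------------------------------------------------
    chains = cohort.chains
    rep_rows = []
    expansion_rows = []
    for patient, pchains in chains.groupby("patient", sort=True):
        clones = group_clones(pchains, locus="TRB", mode=pipe.clone_mode)
        if clones.empty:
            continue
        rep_rows.append(
            {
                "patient": patient,
                "n_clones": len(clones),
                "n_cells": int(clones["size"].sum()),
                "shannon_entropy_bits": shannon_entropy(clones["frequency"]),
                "gini_index": gini_index(clones["size"]),
                "n_expanded": int((clones["size"] > 20).sum()),
            }
        )
        cls = classify_expansion(clones["size"])
        expansion_rows.extend(
            {"patient": patient, "clone_id": cid, "size": s, "class": c}
            for cid, s, c in zip(clones["clone_id"], clones["size"], cls)
        )
    scio.write_tsv(pd.DataFrame(rep_rows), out / "tcr_diversity.tsv")
    scio.write_tsv(pd.DataFrame(expansion_rows), out / "tcr_expansion.tsv")

    heavy = chains[(chains["locus"] == "IGH") & (chains["productive"] == "T")].copy()
    heavy["shm_class"] = classify_shm(heavy["mu_freq"])
    scio.write_tsv(
        heavy[["cell_id", "patient", "c_call", "mu_freq", "shm_class"]],
        out / "bcr_shm.tsv",
    )
    subtype_by_cell = cohort.cells.set_index("cell_barcode")["b_subtype"]
    iso = isotype_table(chains, subtype_by_cell[subtype_by_cell != "."])
    scio.write_tsv(iso.reset_index(), out / "isotype_table.tsv")
    usage, chi2, chi_p = vdj_usage(heavy, heavy["patient"])
    scio.write_tsv(
        usage.reset_index(), out / "ighv_usage.tsv", {"chi2": chi2, "p": chi_p}
    )

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "scgot_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": sim.seed,
        "simulation_config": sim.to_dict(),
        "pipeline_config": pipe.to_dict(),
        "qc_report": qc_report,
        "genotyping": {
            "reads_in": got.n_reads_in,
            "ambiguous_umis": got.n_ambiguous_umis,
            "conflicted_cells": got.n_conflicted_cells,
        },
        "checksums": {
            str(p.relative_to(out)): scio.file_checksum(p) for p in outputs
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
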