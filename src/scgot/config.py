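"""Configuration objects for the simulator and the pipeline.

All tunable constants of the analysis live here, with defaults matching the
published workflow: UMI-collapse threshold ceiling(0.1 x UMI length), cell QC
bounds 500/6000 genes and 5% mitochondrial reads, top-250 signature genes,
sniffer consensus threshold 0.75, clonal-expansion boundary >20 cells, and
somatic-hypermutation boundary 3%.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its legal range."""


# ---------------------------------------------------------------------------
# Locus specification
# ---------------------------------------------------------------------------

_DEFAULT_WT_CONTEXT = (
    "CTGGAAGATGGCACCCTGGAAGAATTTAAGAGTGTCATGTAGGGTAACAGCCTTGACAT"
)
# X-linked UBA1-style missense: a single T>C substitution at the variant
# offset distinguishes the mutant amplicon from wild type.
_DEFAULT_VARIANT_OFFSET = 30


def _mutate(seq: str, offset: int, base: str) -> str:
    return seq[:offset] + base + seq[offset + 1 :]


@dataclass(frozen=True)
class LocusSpec:
    """Expected wild-type and mutant amplicon contexts around one variant.

    Read 2 of an amplicon pair is classified by the base it carries at
    ``variant_offset``: the wild-type base, the mutant base, or anything else
    (``OTHER``).
    """

    wt_context: str = _DEFAULT_WT_CONTEXT
    mut_context: str = _mutate(_DEFAULT_WT_CONTEXT, _DEFAULT_VARIANT_OFFSET, "C")
    variant_offset: int = _DEFAULT_VARIANT_OFFSET

    def __post_init__(self) -> None:
        if len(self.wt_context) != len(self.mut_context):
            raise ConfigurationError("wt_context and mut_context lengths differ")
        if not (0 <= self.variant_offset < len(self.wt_context)):
            raise ConfigurationError("variant_offset outside amplicon context")
        if self.wt_base == self.mut_base:
            raise ConfigurationError(
                "wt and mut contexts agree at variant_offset; no variant to genotype"
            )

    @property
    def wt_base(self) -> str:
        return self.wt_context[self.variant_offset]

    @property
    def mut_base(self) -> str:
        return self.mut_context[self.variant_offset]

    def classify_base(self, base: str) -> str:
        if base == self.wt_base:
            return "WT"
        if base == self.mut_base:
            return "MUT"
        return "OTHER"

    def classify_read(self, read2: str) -> str:
        """Classify an amplicon read 2 by its base at the variant offset."""
        if len(read2) <= self.variant_offset:
            return "OTHER"
        return self.classify_base(read2[self.variant_offset])


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def _default_cell_type_proportions() -> dict[str, float]:
    return {
        "Mono": 0.20,
        "DC": 0.05,
        "NK": 0.10,
        "T": 0.45,
        "B": 0.15,
        "Plasmablast": 0.05,
    }


def _default_mutant_fraction_by_type() -> dict[str, float]:
    # Myeloid-restricted somatic mutation: high in monocytes/DC, intermediate
    # in NK, absent from the B and T lineages.
    return {
        "Mono": 0.4,
        "DC": 0.4,
        "NK": 0.2,
        "T": 0.0,
        "B": 0.0,
        "Plasmablast": 0.0,
    }


def _default_shm_by_subtype() -> dict[str, tuple[float, float]]:
    # (mean mutation frequency, beta concentration) per B subtype: naive B
    # cells carry germline receptors, memory B cells low-to-moderate SHM,
    # plasmablasts the highest load.
    return {
        "Naive_B": (0.0, 40.0),
        "Memory_B": (0.025, 40.0),
        "Plasmablast": (0.06, 40.0),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe a nine-patient cohort of 1,000 cells each with a
    hemizygous myeloid-restricted mutation, ~17% amplicon and ~5%
    transcriptome per-cell capture of the locus, PCR duplication with UMI
    corruption, marker-structured counts, power-law clone sizes, and
    subtype-dependent somatic hypermutation.
    """

    n_patients: int = 9
    n_cells_per_patient: int = 1000
    cell_type_proportions: dict[str, float] = field(
        default_factory=_default_cell_type_proportions
    )
    mutant_fraction_by_type: dict[str, float] = field(
        default_factory=_default_mutant_fraction_by_type
    )
    nk_pseudotime_decay: float = 2.0
    amplicon_capture_rate: float = 0.17
    transcriptome_capture_rate: float = 0.05
    reads_per_umi_mean: float = 3.0
    per_base_error_rate: float = 0.01
    umi_error_rate: float = 0.05
    barcode_length: int = 16
    umi_length: int = 12
    clone_size_alpha: float = 2.5
    shm_by_subtype: dict[str, tuple[float, float]] = field(
        default_factory=_default_shm_by_subtype
    )
    marker_fold_change: float = 4.0
    seed: int = 0

    # Generator internals not fixed by the study design; see docs/methods.md.
    umis_per_cell_mean: float = 2.0
    transcriptome_umis_per_cell_mean: float = 1.2
    missing_tag_rate: float = 0.02
    n_background_genes: int = 1500
    n_markers_per_type: int = 20
    low_quality_cell_fraction: float = 0.02
    high_mito_cell_fraction: float = 0.02
    locus: LocusSpec = field(default_factory=LocusSpec)

    def validate(self) -> None:
        for name in (
            "amplicon_capture_rate",
            "transcriptome_capture_rate",
            "per_base_error_rate",
            "umi_error_rate",
            "missing_tag_rate",
            "low_quality_cell_fraction",
            "high_mito_cell_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for name in ("n_patients", "n_cells_per_patient", "barcode_length", "umi_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if not math.isclose(sum(self.cell_type_proportions.values()), 1.0, abs_tol=1e-9):
            raise ConfigurationError("cell_type_proportions must sum to 1 within 1e-9")
        for ct, p in self.cell_type_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"cell_type_proportions[{ct}] outside [0,1]")
        for ct, p in self.mutant_fraction_by_type.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"mutant_fraction_by_type[{ct}] outside [0,1]")
        if self.nk_pseudotime_decay < 0:
            raise ConfigurationError("nk_pseudotime_decay must be >= 0")
        if self.clone_size_alpha <= 1:
            raise ConfigurationError("clone_size_alpha must exceed 1")
        for name in ("reads_per_umi_mean", "marker_fold_change", "umis_per_cell_mean",
                     "transcriptome_umis_per_cell_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for sub, (mean, conc) in self.shm_by_subtype.items():
            if not (0.0 <= mean <= 1.0) or conc <= 0:
                raise ConfigurationError(f"shm_by_subtype[{sub}] invalid: {(mean, conc)}")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shm_by_subtype"] = {k: list(v) for k, v in self.shm_by_subtype.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "locus" in d and isinstance(d["locus"], Mapping):
            d["locus"] = LocusSpec(**d["locus"])
        if "shm_by_subtype" in d:
            d["shm_by_subtype"] = {
                k: tuple(v) for k, v in d["shm_by_subtype"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters with the published defaults."""

    locus: LocusSpec = field(default_factory=LocusSpec)
    umi_threshold: int | str = "auto"  # auto => ceiling(0.1 x UMI length)
    chunk_size: int = 125_000
    sniffer_threshold: float = 0.75
    sniffer_strict_greater: bool = False
    qc_min_genes: int = 500
    qc_max_genes: int = 6000
    qc_max_mito: float = 0.05
    mito_prefix: str = "MT-"
    top_k_signature_genes: int = 250
    module_n_bins: int = 24
    module_n_ctrl: int = 100
    trajectory_n_bins: int = 20
    trajectory_min_per_bin: int = 10
    min_cells_per_type: int = 100
    expanded_clone_min: int = 21  # strictly more than 20 cells
    shm_low_max: float = 0.03
    clone_mode: str = "cdr3nt"  # or "cdr3nt+VJ"
    seed: int = 0
    out_dir: str = "scgot_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "locus" in d and isinstance(d["locus"], Mapping):
            d["locus"] = LocusSpec(**d["locus"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)
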