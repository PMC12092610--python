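"""Transcriptome-read variant calling at a single locus.

Mirrors the tag-filter / per-UMI consensus approach used on aligned 10x
expression reads: reads lacking a cell-barcode (CB) or molecular-barcode (UB)
tag are removed; within each (cell, UMI) the most common base is accepted as
the molecule's consensus only when it reaches at least 75% of the reads,
otherwise the molecule is discarded; cells are then genotyped with the same
hemizygous rule as the amplicon (GoT) caller.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .genotyping import CellGenotype

__all__ = [
    "TaggedRead",
    "SnifferResult",
    "filter_tagged_reads",
    "consensus_base_per_umi",
    "genotype_cells_from_transcriptome",
    "sniff_cells",
]

MISSING = "."
DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class TaggedRead:
    """One aligned transcriptome read overlapping the variant position.

    ``cell_barcode`` / ``umi`` are ``"."`` when the corresponding tag is
    absent; ``base_at_variant`` is WT, MUT or OTHER.
    """

    cell_barcode: str
    umi: str
    base_at_variant: str

    @property
    def has_tags(self) -> bool:
        return self.cell_barcode != MISSING and self.umi != MISSING


def filter_tagged_reads(
    reads: Iterable[TaggedRead],
) -> tuple[list[TaggedRead], dict[str, int]]:
    """Keep reads carrying both CB and UB tags; report removal counts."""
    kept: list[TaggedRead] = []
    report = {"input": 0, "removed_missing_tag": 0}
    for r in reads:
        report["input"] += 1
        if r.has_tags:
            kept.append(r)
        else:
            report["removed_missing_tag"] += 1
    return kept, report


def consensus_base_per_umi(
    bases: Iterable[str],
    threshold: float = 0.75,
    strict_greater: bool = False,
) -> str:
    """Consensus base for one (cell, UMI) group of reads.

    Unanimous reads return their base. Otherwise the most common base is
    returned only when its share of the group's reads reaches ``threshold``
    (>= by default, admitting the 3-of-4 case; ``strict_greater`` switches
    the comparison to >). Everything else — including an
    OTHER-base consensus or an empty group — is DISCARDED.
    """
    counts = Counter(bases)
    total = sum(counts.values())
    if total == 0:
        return DISCARDED
    top = max(counts.values())
    leaders = sorted(b for b, n in counts.items() if n == top)
    if len(leaders) > 1:  # tied most-common base: no consensus
        return DISCARDED
    base = leaders[0]
    share = top / total
    ok = share > threshold if strict_greater else share >= threshold
    if not ok or base not in ("WT", "MUT"):
        return DISCARDED
    return base


def genotype_cells_from_transcriptome(
    consensi_per_cell: dict[str, list[str]],
) -> list[CellGenotype]:
    """Hemizygous cell calls from per-UMI consensus bases (DISCARDED excluded).

    Identical contract to the amplicon caller: any MUT molecule makes the
    cell MUT, otherwise any WT molecule makes it WT, otherwise UNASSIGNED.
    """
    out: list[CellGenotype] = []
    for cell in sorted(consensi_per_cell):
        calls = [c for c in consensi_per_cell[cell] if c in ("WT", "MUT")]
        n_wt = calls.count("WT")
        n_mut = calls.count("MUT")
        if n_mut >= 1:
            geno = "MUT"
        elif n_wt >= 1:
            geno = "WT"
        else:
            geno = "UNASSIGNED"
        out.append(CellGenotype(cell, n_wt, n_mut, geno))
    return out


@dataclass
class SnifferResult:
    cells: list[CellGenotype]
    report: dict[str, int]

    def cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.cell_barcode, c.n_wt_umis, c.n_mut_umis, c.genotype) for c in self.cells],
            columns=["cell_barcode", "n_wt_umis", "n_mut_umis", "genotype"],
        )


def sniff_cells(
    reads: Iterable[TaggedRead],
    threshold: float = 0.75,
    strict_greater: bool = False,
) -> SnifferResult:
    """Full sniffer pass: tag filtering, per-UMI consensus, cell genotyping."""
    kept, report = filter_tagged_reads(reads)
    by_umi: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in kept:
        by_umi[(r.cell_barcode, r.umi)].append(r.base_at_variant)
    per_cell: dict[str, list[str]] = defaultdict(list)
    n_discarded = 0
    for (cell, _umi), bases in sorted(by_umi.items()):
        cons = consensus_base_per_umi(bases, threshold, strict_greater)
        if cons == DISCARDED:
            n_discarded += 1
        else:
            per_cell[cell].append(cons)
    cells = genotype_cells_from_transcriptome(per_cell)
    report["umis_discarded"] = n_discarded
    report["umis_called"] = sum(len(v) for v in per_cell.values())
    return SnifferResult(cells=cells, report=report)
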