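"""Amplicon-based genotyping of transcriptomes (GoT) for a hemizygous variant.

Reads carrying a cell barcode and UMI are grouped per cell; UMIs within a
cell are collapsed by Levenshtein distance using a greedy most-matched-first
rule; each canonical UMI receives a mutant/wild-type consensus from its read
tallies (ties removed as ambiguous); and each cell is called MUT or WT from
its UMI consensi under a hemizygous model (a single X-linked allele per
cell, so one confident molecule suffices).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import edlib
import pandas as pd

__all__ = [
    "AmpliconRead",
    "UmiConsensus",
    "CellGenotype",
    "GenotypingResult",
    "default_umi_threshold",
    "levenshtein",
    "collapse_umis",
    "genotype_umis",
    "call_cell_genotypes",
    "chunk_reads",
    "genotype_cells",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class AmpliconRead:
    """One targeted-locus read: cell barcode, UMI, and locus base call."""

    cell_barcode: str
    umi: str
    locus_base: str  # WT | MUT | OTHER

    def __post_init__(self) -> None:
        if not set(self.cell_barcode) <= _VALID_BASES:
            raise ValueError(f"invalid barcode {self.cell_barcode!r}")
        if not set(self.umi) <= _VALID_BASES:
            raise ValueError(f"invalid UMI {self.umi!r}")
        if self.locus_base not in ("WT", "MUT", "OTHER"):
            raise ValueError(f"invalid locus base {self.locus_base!r}")


@dataclass(frozen=True)
class UmiConsensus:
    """Per (cell, canonical UMI) read tallies and consensus call."""

    cell_barcode: str
    canonical_umi: str
    n_wt_reads: int
    n_mut_reads: int
    call: str  # WT | MUT | AMBIGUOUS


@dataclass(frozen=True)
class CellGenotype:
    """Per-cell genotype with supporting UMI counts."""

    cell_barcode: str
    n_wt_umis: int
    n_mut_umis: int
    genotype: str  # WT | MUT | UNASSIGNED


@dataclass
class GenotypingResult:
    """Cell genotypes plus per-UMI consensi and bookkeeping counters."""

    cells: list[CellGenotype]
    umi_consensi: list[UmiConsensus]
    n_reads_in: int = 0
    n_reads_dropped_n: int = 0
    n_ambiguous_umis: int = 0
    n_no_allele_umis: int = 0
    n_conflicted_cells: int = 0

    def cell_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.cell_barcode, c.n_wt_umis, c.n_mut_umis, c.genotype) for c in self.cells],
            columns=["cell_barcode", "n_wt_umis", "n_mut_umis", "genotype"],
        )

    def umi_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (u.cell_barcode, u.canonical_umi, u.n_wt_reads, u.n_mut_reads, u.call)
                for u in self.umi_consensi
            ],
            columns=["cell_barcode", "canonical_umi", "n_wt", "n_mut", "call"],
        )


def default_umi_threshold(umi_length: int) -> int:
    """Default UMI-collapse distance: ceiling(0.1 x UMI length).

    For the usual 12-base UMI this is 2 bases.
    """
    if umi_length < 1:
        raise ValueError(f"umi_length must be >= 1, got {umi_length}")
    return math.ceil(0.1 * umi_length)


def levenshtein(a: str, b: str) -> int:
    """Full edit distance (substitutions, insertions, deletions), unit costs."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def collapse_umis(
    umi_read_counts: Mapping[str, int], threshold: int
) -> dict[str, str]:
    """Collapse UMIs within one cell barcode by Levenshtein distance.

    UMI pairs at edit distance <= ``threshold`` are "matches". Greedily, the
    UMI with the greatest number of matches among the surviving set absorbs
    its matched partners; seed and absorbed UMIs leave the pool, and the
    process repeats with the next-highest-match UMI until no surviving UMI
    has a match. Ties on match count are broken by higher total read count,
    then lexicographically. Returns a total map UMI -> canonical UMI
    (unmatched UMIs map to themselves).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    umis = sorted(umi_read_counts)
    for u in umis:
        if not u:
            raise ValueError("empty UMI string")
    canonical: dict[str, str] = {}
    # adjacency over the current survivor set
    matches: dict[str, set[str]] = {u: set() for u in umis}
    for i, a in enumerate(umis):
        for b in umis[i + 1 :]:
            if levenshtein(a, b) <= threshold:
                matches[a].add(b)
                matches[b].add(a)
    surviving = set(umis)
    while True:
        best = None
        best_key = None
        for u in surviving:
            live = matches[u] & surviving
            if not live:
                continue
            # more matches first, then more reads, then lexicographically first
            key = (len(live), umi_read_counts[u], _neg_lex(u))
            if best is None or key > best_key:
                best, best_key = u, key
        if best is None:
            break
        absorbed = matches[best] & surviving
        canonical[best] = best
        for u in absorbed:
            canonical[u] = best
        surviving -= absorbed
        surviving.discard(best)
    for u in surviving:
        canonical[u] = u
    return canonical


class _neg_lex(str):
    """Inverts lexicographic order so that max() prefers the smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _tally_to_consensus(
    cell: str, umi: str, n_wt: int, n_mut: int
) -> UmiConsensus | None:
    """Consensus for one canonical UMI; None when no allele-informative read."""
    if n_wt == 0 and n_mut == 0:
        return None
    if n_mut > n_wt:
        call = "MUT"
    elif n_wt > n_mut:
        call = "WT"
    else:
        call = "AMBIGUOUS"
    return UmiConsensus(cell, umi, n_wt, n_mut, call)


def genotype_umis(
    reads: Iterable[AmpliconRead],
    threshold: int | None = None,
) -> tuple[list[UmiConsensus], dict[str, int]]:
    """Collapse UMIs per cell and tally WT/MUT reads per canonical UMI.

    ``OTHER`` locus bases count toward neither allele. UMIs whose WT and MUT
    tallies are equal (and nonzero) are flagged AMBIGUOUS; callers exclude
    them from cell-level genotyping. Returns the consensi plus counters
    (ambiguous and allele-less UMIs).
    """
    by_cell: dict[str, Counter] = defaultdict(Counter)
    umi_len = None
    for r in reads:
        by_cell[r.cell_barcode][(r.umi, r.locus_base)] += 1
        umi_len = len(r.umi)
    if threshold is None:
        threshold = default_umi_threshold(umi_len) if umi_len else 0
    consensi: list[UmiConsensus] = []
    counters = {"ambiguous": 0, "no_allele": 0}
    for cell in sorted(by_cell):
        tallies = by_cell[cell]
        read_counts: Counter = Counter()
        for (umi, _base), n in tallies.items():
            read_counts[umi] += n
        mapping = collapse_umis(read_counts, threshold)
        merged: dict[str, dict[str, int]] = defaultdict(lambda: {"WT": 0, "MUT": 0})
        for (umi, base), n in tallies.items():
            if base in ("WT", "MUT"):
                merged[mapping[umi]][base] += n
            else:
                merged[mapping[umi]]  # ensure canonical UMI exists even if all OTHER
        for umi in sorted(merged):
            cons = _tally_to_consensus(cell, umi, merged[umi]["WT"], merged[umi]["MUT"])
            if cons is None:
                counters["no_allele"] += 1
            else:
                if cons.call == "AMBIGUOUS":
                    counters["ambiguous"] += 1
                consensi.append(cons)
    return consensi, counters


def call_cell_genotypes(
    consensi: Iterable[UmiConsensus],
) -> tuple[list[CellGenotype], int]:
    """Hemizygous per-cell genotype from unambiguous UMI consensi.

    A cell with at least one MUT UMI is called MUT; otherwise at least one WT
    UMI gives WT; a cell with no informative UMI is UNASSIGNED. MUT takes
    precedence for cells carrying both kinds of evidence (under hemizygosity
    a true mutant can produce apparent WT reads through error far more easily
    than the reverse); the number of such conflicted cells is returned.
    """
    by_cell: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for c in consensi:
        if c.call == "AMBIGUOUS":
            continue
        if c.call == "WT":
            by_cell[c.cell_barcode][0] += 1
        else:
            by_cell[c.cell_barcode][1] += 1
    cells: list[CellGenotype] = []
    conflicted = 0
    for cell in sorted(by_cell):
        n_wt, n_mut = by_cell[cell]
        if n_mut >= 1:
            geno = "MUT"
            if n_wt >= 1:
                conflicted += 1
        elif n_wt >= 1:
            geno = "WT"
        else:
            geno = "UNASSIGNED"
        cells.append(CellGenotype(cell, n_wt, n_mut, geno))
    return cells, conflicted


def chunk_reads(
    reads: Sequence[AmpliconRead] | Iterable[AmpliconRead], chunk_size: int
) -> Iterator[list[AmpliconRead]]:
    """Split reads into chunks of at most ``chunk_size``; concatenation of the
    chunks equals the input. Genotyping is invariant to the chunking because
    tallies are re-keyed by cell barcode before UMI collapsing."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    chunk: list[AmpliconRead] = []
    for r in reads:
        chunk.append(r)
        if len(chunk) == chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def genotype_cells(
    reads: Iterable[AmpliconRead],
    threshold: int | None = None,
    chunk_size: int = 125_000,
) -> GenotypingResult:
    """Full GoT pass: chunked tallying, per-cell UMI collapse, consensus
    calling, and hemizygous cell genotyping.

    Reads with ``N`` in the barcode or UMI are dropped before grouping
    (ambiguous molecule identity). ``threshold`` defaults to
    ceiling(0.1 x UMI length).
    """
    tallies: Counter = Counter()
    n_in = 0
    n_dropped = 0
    umi_len = None
    for chunk in chunk_reads(reads, chunk_size):
        for r in chunk:
            n_in += 1
            if "N" in r.cell_barcode or "N" in r.umi:
                n_dropped += 1
                continue
            tallies[(r.cell_barcode, r.umi, r.locus_base)] += 1
            umi_len = len(r.umi)
    if threshold is None:
        threshold = default_umi_threshold(umi_len) if umi_len else 0

    clean = [
        AmpliconRead(cb, umi, base)
        for (cb, umi, base), n in sorted(tallies.items())
        for _ in range(n)
    ]
    consensi, counters = genotype_umis(clean, threshold=threshold)
    unambiguous = [c for c in consensi if c.call != "AMBIGUOUS"]
    cells, conflicted = call_cell_genotypes(unambiguous)
    return GenotypingResult(
        cells=cells,
        umi_consensi=consensi,
        n_reads_in=n_in,
        n_reads_dropped_n=n_dropped,
        n_ambiguous_umis=counters["ambiguous"],
        n_no_allele_umis=counters["no_allele"],
        n_conflicted_cells=conflicted,
    )
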