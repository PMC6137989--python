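"""Genic TSS/GB partition, island-to-gene assignment and differential calls.

Each gene is split, strand-aware, into a TSS-proximal region (250 bp
upstream to 500 bp downstream of the TSS) and a gene-body region (500 bp
downstream of the TSS to 250 bp downstream of the TTS).  Genes of length
<= 500 bp have an empty gene body and the TSS region truncates at TTS+250.
The two regions partition the gene +/- 250 bp envelope exactly.

Islands are assigned to genes on >= 1 bp overlap with the envelope; one
island may be assigned to several genes.  Differential islands set a
per-gene category (tss/gb x increase/decrease) for every region they
overlap, so an island straddling the TSS/GB boundary sets both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GeneModel

FLANK = 250
TSS_DOWNSTREAM = 500

CATEGORIES = ("tss_increase", "tss_decrease", "gb_increase", "gb_decrease")

__all__ = [
    "GeneRegions",
    "GeneDifferentialCall",
    "compute_gene_regions",
    "assign_islands_to_genes",
    "classify_differential",
    "CATEGORIES",
]


@dataclass(frozen=True)
class GeneRegions:
    """TSS-proximal / gene-body partition of one gene's envelope.

    Intervals are half-open; an empty interval has ``start == end``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_region: tuple[int, int]
    gb_region: tuple[int, int]
    envelope: tuple[int, int]


@dataclass
class GeneDifferentialCall:
    gene_id: str
    categories: frozenset[str]
    supporting: dict[str, list[str]] = field(default_factory=dict)


def _clip(interval: tuple[int, int], chrom_length: int | None) -> tuple[int, int]:
    lo, hi = interval
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    hi = max(hi, lo)
    return (lo, hi)


def compute_gene_regions(gene: GeneModel, chrom_length: int | None = None) -> GeneRegions:
    """Partition a gene's +/-250 bp envelope into TSS and GB regions.

    For minus-strand genes the TSS is the right-most coordinate and
    "downstream" extends leftward.  Intervals are clipped to chromosome
    bounds; genes of length <= 500 get an empty GB.
    """
    s, e = gene.start, gene.end
    short = gene.length <= TSS_DOWNSTREAM
    if gene.strand == "+":
        envelope = (s - FLANK, e + FLANK)
        boundary = e + FLANK if short else s + TSS_DOWNSTREAM
        tss = (s - FLANK, boundary)
        gb = (boundary, e + FLANK)
    else:
        envelope = (s - FLANK, e + FLANK)
        boundary = s - FLANK if short else e - TSS_DOWNSTREAM
        tss = (boundary, e + FLANK)
        gb = (s - FLANK, boundary)
    return GeneRegions(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        tss_region=_clip(tss, chrom_length),
        gb_region=_clip(gb, chrom_length),
        envelope=_clip(envelope, chrom_length),
    )


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _island_id(island) -> str:
    return f"{island.chrom}:{island.start}-{island.end}"


def assign_islands_to_genes(islands: Sequence, genes: Sequence[GeneModel],
                            chrom_lengths: Mapping[str, int] | None = None
                            ) -> dict[str, list[str]]:
    """Map gene_id -> ids of islands overlapping the gene +/-250 bp envelope.

    Overlap is >= 1 bp; an island spanning several envelopes is assigned to
    every one of them.  Every gene appears in the result (possibly with an
    empty list).
    """
    by_chrom: dict[str, list] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    for lst in by_chrom.values():
        lst.sort(key=lambda i: (i.start, i.end))

    out: dict[str, list[str]] = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        env = compute_gene_regions(gene, clen).envelope
        hits: list[str] = []
        chrom_islands = by_chrom.get(gene.chrom, [])
        starts = np.array([i.start for i in chrom_islands])
        # islands starting before env end are the only candidates
        hi = int(np.searchsorted(starts, env[1])) if starts.size else 0
        for isl in chrom_islands[:hi]:
            if isl.end > env[0]:
                hits.append(_island_id(isl))
        out[gene.gene_id] = hits
    return out


def classify_differential(diff_islands: Sequence, gene_regions: Sequence[GeneRegions]
                          ) -> tuple[list[GeneDifferentialCall], dict]:
    """Per-gene differential categories plus summary fractions.

    A category (e.g. ``gb_decrease``) is set iff at least one differential
    island of that direction overlaps that region by >= 1 bp.  The summary
    reports, among genes with any differential island: the fraction with a
    decrease and with an increase, and — among genes containing each change
    direction — the fraction where the change hits the TSS vs GB region.
    Genes carrying both directions count in both summaries.
    """
    by_chrom: dict[str, list] = {}
    for isl in diff_islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)

    calls: list[GeneDifferentialCall] = []
    for gr in gene_regions:
        cats: set[str] = set()
        support: dict[str, list[str]] = {}
        for isl in by_chrom.get(gr.chrom, []):
            iv = (isl.start, isl.end)
            suffix = "increase" if isl.direction == "increase" else "decrease"
            if _overlaps(iv, gr.tss_region):
                cats.add(f"tss_{suffix}")
                support.setdefault(f"tss_{suffix}", []).append(_island_id(isl))
            if _overlaps(iv, gr.gb_region):
                cats.add(f"gb_{suffix}")
                support.setdefault(f"gb_{suffix}", []).append(_island_id(isl))
        calls.append(GeneDifferentialCall(gene_id=gr.gene_id,
                                          categories=frozenset(cats),
                                          supporting=support))

    with_any = [c for c in calls if c.categories]
    summary: dict = {}
    if with_any:
        n_any = len(with_any)
        dec = [c for c in with_any if any(cat.endswith("decrease") for cat in c.categories)]
        inc = [c for c in with_any if any(cat.endswith("increase") for cat in c.categories)]
        summary["n_genes_with_differential"] = n_any
        summary["fraction_with_decrease"] = len(dec) / n_any
        summary["fraction_with_increase"] = len(inc) / n_any
        if dec:
            summary["decrease_at_tss_fraction"] = (
                sum("tss_decrease" in c.categories for c in dec) / len(dec))
            summary["decrease_at_gb_fraction"] = (
                sum("gb_decrease" in c.categories for c in dec) / len(dec))
        if inc:
            summary["increase_at_tss_fraction"] = (
                sum("tss_increase" in c.categories for c in inc) / len(inc))
            summary["increase_at_gb_fraction"] = (
                sum("gb_increase" in c.categories for c in inc) / len(inc))
        for cat in CATEGORIES:
            summary[f"fraction_{cat}"] = (
                sum(cat in c.categories for c in with_any) / n_any)
    return calls, summary
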