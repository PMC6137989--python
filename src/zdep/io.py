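"""Readers/writers for the genomic formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open.  GFF3 (1-based, inclusive)
is converted at the parsing/writing boundary; BED and bedGraph are natively
0-based half-open.  Chromosome names are matched by exact string equality.

bedGraph values are interpreted as counts attributed uniformly per bp over
the interval, expressed per ``window_size`` bp, and re-binned by bp-weighted
sum into fixed windows.  This makes ``library_size`` well defined and makes
write-then-read an identity on window-aligned tracks.

Files ending in ``.gz`` are read and written transparently compressed.
"""

from __future__ import annotations

import gzip
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOTYPES = ("PCG", "PG", "TE", "TEG")
GENOTYPES = ("WT", "arp6")

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "ExpressionTable",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_term_annotation",
    "write_term_annotation",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "PCG"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Binned read-count signal for one library.

    ``counts`` maps chromosome name to a vector of per-window counts; the
    window grid starts at position 0 with fixed ``window_size``.
    """

    sample_id: str
    window_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        clean = {}
        for chrom, vec in self.counts.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: counts must be a vector")
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise ValueError(f"{chrom}: counts must be finite and >= 0")
            clean[chrom] = arr
        self.counts = clean

    @property
    def library_size(self) -> float:
        return float(sum(vec.sum() for vec in self.counts.values()))

    @property
    def n_windows(self) -> int:
        return int(sum(vec.size for vec in self.counts.values()))

    def chrom_length(self, chrom: str) -> int:
        return int(self.counts[chrom].size * self.window_size)

    def same_grid(self, other: "CoverageTrack") -> bool:
        if self.window_size != other.window_size:
            return False
        if set(self.counts) != set(other.counts):
            return False
        return all(
            self.counts[c].size == other.counts[c].size for c in self.counts
        )


@dataclass
class ExpressionTable:
    """Raw RNA counts (genes x samples) plus per-sample metadata.

    ``samples`` is indexed by sample_id with columns ``genotype``,
    ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        vals = self.counts.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count table")

    def sample_ids(self, condition: str | None = None, genotype: str | None = None):
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if condition is not None:
            mask &= meta["condition"] == condition
        if genotype is not None:
            mask &= meta["genotype"] == genotype
        return [s for s in self.counts.columns if s in meta.index[mask]]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path) -> list[GeneModel]:
    """Parse gene features from a GFF3 file.

    Only rows with feature type ``gene`` are consumed.  1-based inclusive
    coordinates are converted to internal 0-based half-open.  Unknown
    biotypes default to PCG with a logged warning.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            attr_map = _parse_attributes(attrs, path, lineno)
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene row lacks ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            biotype = attr_map.get("biotype", attr_map.get("gene_biotype", "PCG"))
            if biotype not in BIOTYPES:
                logger.warning(
                    "%s:%d: unknown biotype %r for %s; defaulting to PCG",
                    path, lineno, biotype, gene_id,
                )
                biotype = "PCG"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    biotype=biotype,
                )
            )
    return genes


def _parse_attributes(attrs: str, path, lineno: int) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"{path}:{lineno}: malformed attribute {part!r}")
        key, value = part.split("=", 1)
        out[key] = value
    return out


def write_gff3(genes: Sequence[GeneModel], path, chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        if chrom_sizes:
            for chrom in sorted(chrom_sizes):
                fh.write(f"##sequence-region {chrom} 1 {chrom_sizes[chrom]}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tzdep\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path, window_size: int, chrom_sizes: Mapping[str, int] | None = None,
                  sample_id: str | None = None) -> CoverageTrack:
    """Read a bedGraph into a fixed-window :class:`CoverageTrack`.

    Interval values are counts per ``window_size`` bp spread uniformly over
    the interval; a window receives ``value * overlap_bp / window_size``.
    Intervals must be sorted and non-overlapping per chromosome; gaps are
    zero-filled.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value")
            ivs = per_chrom.setdefault(chrom, [])
            if ivs and start < ivs[-1][1]:
                if start < ivs[-1][0]:
                    raise ValueError(f"{path}:{lineno}: intervals not sorted")
                raise ValueError(f"{path}:{lineno}: overlapping intervals")
            ivs.append((start, end, value))

    counts: dict[str, np.ndarray] = {}
    for chrom, ivs in per_chrom.items():
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            n_win = math.ceil(chrom_sizes[chrom] / window_size)
        else:
            n_win = math.ceil(ivs[-1][1] / window_size)
        vec = np.zeros(n_win, dtype=float)
        for start, end, value in ivs:
            density = value / window_size  # counts per bp
            w0 = start // window_size
            w1 = (end - 1) // window_size
            if w0 == w1:
                vec[w0] += density * (end - start)
            else:
                vec[w0] += density * ((w0 + 1) * window_size - start)
                if w1 > w0 + 1:
                    vec[w0 + 1:w1] += density * window_size
                vec[w1] += density * (end - w1 * window_size)
        counts[chrom] = vec
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            counts.setdefault(chrom, np.zeros(math.ceil(size / window_size)))
    return CoverageTrack(
        sample_id=sample_id or Path(path).name.split(".")[0],
        window_size=window_size,
        counts=counts,
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph, run-length coalescing equal-valued windows.

    Zero windows are written too, so the chromosome extent (and hence the
    window grid) round-trips exactly.
    """
    W = track.window_size
    with _open(path, "wt") as fh:
        fh.write(f"#bedGraph sample={track.sample_id} window={W}\n")
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            if vec.size == 0:
                continue
            run_start = 0
            for i in range(1, vec.size + 1):
                if i == vec.size or vec[i] != vec[run_start]:
                    value = vec[run_start]
                    value_repr = int(value) if float(value).is_integer() else value
                    fh.write(f"{chrom}\t{run_start * W}\t{i * W}\t{value_repr}\n")
                    run_start = i


# ---------------------------------------------------------------------------
# BED output for islands
# ---------------------------------------------------------------------------


def write_bed(islands: Sequence, path, score_cap: float = 300.0) -> None:
    """Write islands (or differential islands) as BED6+.

    score = -log10(q) capped at ``score_cap``; for differential islands the
    direction is encoded in the name field.  Input must be sorted by
    (chrom, start).
    """
    keys = [(getattr(i, "chrom"), getattr(i, "start")) for i in islands]
    if keys != sorted(keys):
        raise ValueError("islands must be sorted by (chrom, start)")
    with _open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tp_value\tq_value\n")
        for idx, isl in enumerate(islands):
            q = getattr(isl, "q_value")
            score = score_cap if q <= 0 else min(-math.log10(q), score_cap)
            direction = getattr(isl, "direction", None)
            name = (
                f"diff_{idx + 1}_{direction}" if direction is not None else f"island_{idx + 1}"
            )
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\t{name}\t{score:.6g}\t.\t"
                f"{isl.p_value:.6g}\t{q:.6g}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"genotype", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_term_annotation(path) -> dict[str, set[str]]:
    """Read a two-column (gene_id, term_id) TSV into term -> gene-set."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("term annotation needs gene_id and term_id columns")
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        terms.setdefault(str(term), set()).add(str(gene))
    return terms


def write_term_annotation(terms: Mapping[str, Iterable[str]], path) -> None:
    rows = [
        {"gene_id": gene, "term_id": term}
        for term in sorted(terms)
        for gene in sorted(terms[term])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)
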