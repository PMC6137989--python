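"""Synthetic fixture generator with the statistical structure the analysis
assumes.

Genes carry one of three deposition archetypes — broad gene-body signal
(k1_broad), a sharp TSS peak (k2_tss), or depletion (k3_depleted) — on
non-overlapping intervals.  A "stress" condition redistributes expected
ChIP signal from the TSS region to the gene body genome-wide and applies
per-gene planted changes; RNA counts are negative-binomial with planted
differential expression, and a configurable coupling rule ties DE
direction to a planted gene-body H2A.Z change so the end-to-end analysis
can recover (or, decoupled, fail to find) the association.

Coverage is produced directly as Poisson counts in 200-bp windows (reads
are modeled as fragment midpoints; no alignment).  A single seed plus
named substreams per (role, sample, chromosome) makes every artifact
byte-deterministic and insensitive to which other samples are generated.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BIOTYPES,
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    write_bedgraph,
    write_counts_tsv,
    write_gff3,
    write_sample_sheet,
    write_term_annotation,
)
from .regions import compute_gene_regions

CLASSES = ("k1_broad", "k2_tss", "k3_depleted")
CONDITIONS = ("control", "stress")
LIBRARY_ROLES = ("chip", "input", "preimmune")
CHANGES = ("tss_up", "tss_down", "gb_up", "gb_down", "none")

WINDOW = 200
MIN_GENE_LEN, MAX_GENE_LEN = 1000, 5000
END_CLEARANCE = 1000   # flanks stay on-chromosome
MIN_GAP = 2100         # +/-1 kb flanks of neighbours never overlap

# class-conditional log10 expression baseline ranges; k2 (TSS-peak) genes are
# high-expressed and k1/k3 low, reproducing the inverse coupling between
# gene-body signal and expression that the quintile stratification probes
_BASELINE_LOG10 = {
    "k1_broad": (0.5, 2.5),
    "k2_tss": (2.0, 4.0),
    "k3_depleted": (0.0, 1.0),
}

__all__ = [
    "SimulationConfig",
    "CapacityError",
    "SimBundle",
    "generate_annotation",
    "expected_chip_mean",
    "generate_chip_coverage",
    "generate_rna_counts",
    "generate_term_annotation",
    "simulate_bundle",
    "write_fixture_bundle",
]


class CapacityError(ValueError):
    """Genes cannot be placed without overlap under the given config."""


def _default_coupling() -> dict[str, str]:
    return {"up": "gb_down", "down": "gb_up"}


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 400
    class_proportions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    biotype_proportions: tuple[float, float, float, float] = (0.85, 0.05, 0.05, 0.05)
    fragment_mean: int = 200
    chip_depth: int = 500_000        # nominal; echoed in config, not enforced
    rna_depth: int = 2_000_000       # nominal
    n_replicates: int = 2
    tss_peak_height: float = 60.0    # expected reads per 200-bp window
    gb_level: float = 25.0
    background_level: float = 5.0
    redistribution_effect: float = 0.15
    de_fraction: float = 0.2
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    zero_expr_fraction: float = 0.1
    planted_change_effect: float = 0.6
    coupling_rule: dict[str, str] | None = field(default_factory=_default_coupling)
    n_terms: int = 10
    term_odds_ratio: float = 8.0
    term_base_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        self.class_proportions = tuple(float(x) for x in self.class_proportions)
        self.biotype_proportions = tuple(float(x) for x in self.biotype_proportions)
        for name, props in (("class_proportions", self.class_proportions),
                            ("biotype_proportions", self.biotype_proportions)):
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in props):
                raise ValueError(f"{name} must be non-negative")
        if len(self.class_proportions) != len(CLASSES):
            raise ValueError("class_proportions must have 3 entries")
        if len(self.biotype_proportions) != len(BIOTYPES):
            raise ValueError("biotype_proportions must have 4 entries")
        if self.n_genes < 0 or self.n_chromosomes < 1:
            raise ValueError("n_genes >= 0 and n_chromosomes >= 1 required")
        if self.coupling_rule:
            bad = set(self.coupling_rule.values()) - set(CHANGES)
            if bad:
                raise ValueError(f"unknown planted changes in coupling_rule: {bad}")
        per_chrom = -(-self.n_genes // self.n_chromosomes)  # ceil
        if per_chrom > 0:
            needed = (2 * END_CLEARANCE + per_chrom * MAX_GENE_LEN
                      + (per_chrom - 1) * MIN_GAP)
            if needed > self.chrom_length:
                raise CapacityError(
                    f"{per_chrom} genes need up to {needed} bp but chromosomes "
                    f"are {self.chrom_length} bp"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def n_windows_per_chrom(self) -> int:
        return self.chrom_length // WINDOW


@dataclass
class SimBundle:
    config: SimulationConfig
    genes: list[GeneModel]
    truth: pd.DataFrame
    tracks: dict[str, CoverageTrack]
    expr: ExpressionTable
    terms: dict[str, set[str]]


def _rng(seed: int, *tags) -> np.random.Generator:
    key = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Annotation + truth table
# ---------------------------------------------------------------------------


def generate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes and draw the planted truth table."""
    empty_truth = pd.DataFrame(
        columns=["planted_class", "planted_biotype", "planted_de",
                 "planted_h2az_change", "planted_zero", "planted_terms"]
    ).rename_axis("gene_id")
    if config.n_genes == 0:
        return [], empty_truth

    counts = [len(chunk) for chunk in
              np.array_split(np.arange(config.n_genes), config.n_chromosomes)]
    genes: list[GeneModel] = []
    idx = 0
    placeholders: list[tuple[str, int, int, str]] = []
    for chrom, n_c in zip(config.chrom_names, counts):
        if n_c == 0:
            continue
        rng = _rng(config.seed, "annot", chrom)
        lengths = rng.integers(MIN_GENE_LEN, MAX_GENE_LEN + 1, size=n_c)
        slack = (config.chrom_length - 2 * END_CLEARANCE
                 - int(lengths.sum()) - (n_c - 1) * MIN_GAP)
        if slack < 0:
            raise CapacityError(f"genes cannot fit on {chrom}")
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        strands = rng.choice(["+", "-"], size=n_c)
        pos = END_CLEARANCE
        for j in range(n_c):
            pos += int(extra[j]) + (MIN_GAP if j > 0 else 0)
            start = pos
            end = start + int(lengths[j])
            placeholders.append((chrom, start, end, strands[j]))
            pos = end
        idx += n_c

    n = config.n_genes
    classes = _rng(config.seed, "class").choice(CLASSES, size=n,
                                                p=config.class_proportions)
    biotypes = _rng(config.seed, "biotype").choice(BIOTYPES, size=n,
                                                   p=config.biotype_proportions)
    zero = _rng(config.seed, "zero").random(n) < config.zero_expr_fraction
    f = config.de_fraction
    de = _rng(config.seed, "de").choice(["up", "down", "null"], size=n,
                                        p=[f / 2, f / 2, 1 - f])
    de = np.where(zero, "null", de)
    rule = config.coupling_rule or {}
    changes = np.array([rule.get(d, "none") for d in de], dtype=object)

    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    genes = [
        GeneModel(gene_id=gid, chrom=chrom, start=start, end=end,
                  strand=strand, biotype=bt)
        for gid, (chrom, start, end, strand), bt
        in zip(gene_ids, placeholders, biotypes)
    ]
    truth = pd.DataFrame(
        {
            "planted_class": classes,
            "planted_biotype": biotypes,
            "planted_de": de,
            "planted_h2az_change": changes,
            "planted_zero": zero,
            "planted_terms": [""] * n,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return genes, truth


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------


def _add_uniform(mu: np.ndarray, start: int, end: int, level: float) -> None:
    """Add `level` expected reads per fully-covered window, bp-weighted."""
    if end <= start:
        return
    lo, hi = max(start, 0), min(end, mu.size * WINDOW)
    if hi <= lo:
        return
    w0, w1 = lo // WINDOW, (hi - 1) // WINDOW
    if w0 == w1:
        mu[w0] += level * (hi - lo) / WINDOW
        return
    mu[w0] += level * ((w0 + 1) * WINDOW - lo) / WINDOW
    if w1 > w0 + 1:
        mu[w0 + 1:w1] += level
    mu[w1] += level * (hi - w1 * WINDOW) / WINDOW


def _add_gaussian(mu: np.ndarray, center: float, sd: float, height: float) -> None:
    w0 = max(int((center - 4 * sd) // WINDOW), 0)
    w1 = min(int((center + 4 * sd) // WINDOW) + 1, mu.size)
    if w1 <= w0:
        return
    x = (np.arange(w0, w1) + 0.5) * WINDOW
    mu[w0:w1] += height * np.exp(-((x - center) ** 2) / (2 * sd**2))


def _overlap_fractions(n_win: int, w_off: int, interval: tuple[int, int]) -> np.ndarray:
    """Per-window bp overlap fraction with `interval` for windows w_off..w_off+n."""
    starts = (np.arange(n_win) + w_off) * WINDOW
    lo = np.maximum(starts, interval[0])
    hi = np.minimum(starts + WINDOW, interval[1])
    return np.clip(hi - lo, 0, None) / WINDOW


def expected_chip_mean(genes: list[GeneModel], truth: pd.DataFrame,
                       config: SimulationConfig,
                       condition: str) -> dict[str, np.ndarray]:
    """Expected per-window ChIP read counts for one condition.

    Background is uniform; each gene adds a class-specific signal (TSS
    Gaussian for k2, broad gene-body level with 1-3 sub-peaks for k1,
    nothing for k3).  Under stress, the signal component in the TSS region
    is scaled by (1 - redistribution_effect), in the GB region by
    (1 + redistribution_effect), then planted per-gene changes multiply
    their region further by (1 +/- planted_change_effect).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n_win = config.n_windows_per_chrom
    mu = {c: np.full(n_win, float(config.background_level))
          for c in config.chrom_names}
    sd_peak = 150.0 + config.fragment_mean / 2.0

    for gene in genes:
        cls = truth.loc[gene.gene_id, "planted_class"]
        if cls == "k3_depleted":
            continue
        regions = compute_gene_regions(gene, config.chrom_length)
        sig = np.zeros(n_win)
        if cls == "k2_tss":
            tss = gene.start if gene.strand == "+" else gene.end
            center = tss + 125 if gene.strand == "+" else tss - 125
            _add_gaussian(sig, center, sd_peak, config.tss_peak_height)
        else:  # k1_broad
            gb = regions.gb_region
            _add_uniform(sig, gb[0], gb[1], config.gb_level)
            arch = _rng(config.seed, "arch", gene.gene_id)
            for _ in range(int(arch.integers(1, 4))):
                if gb[1] > gb[0]:
                    _add_gaussian(sig, float(arch.uniform(gb[0], gb[1])), 300.0,
                                  0.5 * config.gb_level)

        f_tss, f_gb = 1.0, 1.0
        if condition == "stress":
            e = config.redistribution_effect
            f_tss *= 1.0 - e
            f_gb *= 1.0 + e
            change = truth.loc[gene.gene_id, "planted_h2az_change"]
            pce = config.planted_change_effect
            if change == "tss_up":
                f_tss *= 1.0 + pce
            elif change == "tss_down":
                f_tss *= 1.0 - pce
            elif change == "gb_up":
                f_gb *= 1.0 + pce
            elif change == "gb_down":
                f_gb *= 1.0 - pce
        if f_tss != 1.0 or f_gb != 1.0:
            frac_tss = _overlap_fractions(n_win, 0, regions.tss_region)
            frac_gb = _overlap_fractions(n_win, 0, regions.gb_region)
            sig *= 1.0 + (f_tss - 1.0) * frac_tss + (f_gb - 1.0) * frac_gb
        mu[gene.chrom] += sig
    return mu


def generate_chip_coverage(genes: list[GeneModel], truth: pd.DataFrame,
                           config: SimulationConfig, condition: str,
                           library_role: str, replicate: int = 1) -> CoverageTrack:
    """Poisson-sample a windowed coverage track for one library.

    ``input`` and ``preimmune`` libraries are uniform at the background
    level; the replicate index selects an RNG substream only and does not
    change expectations.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if library_role not in LIBRARY_ROLES:
        raise ValueError(f"unknown library role {library_role!r}")
    if library_role == "chip":
        mu = expected_chip_mean(genes, truth, config, condition)
    else:
        mu = {c: np.full(config.n_windows_per_chrom, float(config.background_level))
              for c in config.chrom_names}
    counts = {}
    for chrom in config.chrom_names:
        rng = _rng(config.seed, "cov", condition, library_role, replicate, chrom)
        counts[chrom] = rng.poisson(mu[chrom]).astype(float)
    return CoverageTrack(
        sample_id=f"{condition}_{library_role}_r{replicate}",
        window_size=WINDOW,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


def generate_rna_counts(genes: list[GeneModel], truth: pd.DataFrame,
                        config: SimulationConfig) -> ExpressionTable:
    """NB counts for control/stress with planted log2 fold changes.

    Baselines are log-uniform within class-specific ranges (k2 high, k1/k3
    low) and span four orders of magnitude overall; planted-zero genes are
    0 in every sample.
    """
    if config.n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    lo = np.array([_BASELINE_LOG10[c][0] for c in truth["planted_class"]])
    hi = np.array([_BASELINE_LOG10[c][1] for c in truth["planted_class"]])
    u = _rng(config.seed, "rna", "baseline").random(n)
    base = 10.0 ** (lo + u * (hi - lo))
    base = np.where(truth["planted_zero"].to_numpy(bool), 0.0, base)

    shift = np.select(
        [truth["planted_de"] == "up", truth["planted_de"] == "down"],
        [2.0**config.lfc_magnitude, 2.0**-config.lfc_magnitude],
        default=1.0,
    )
    means = {"control": base, "stress": base * shift}

    disp = config.nb_dispersion
    data = {}
    meta_rows = []
    for condition in CONDITIONS:
        mu = means[condition]
        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config.seed, "rna", condition, rep)
            if disp > 0:
                r = 1.0 / disp
                p = r / (r + np.maximum(mu, 1e-300))
                counts = np.where(mu > 0, rng.negative_binomial(r, p), 0)
            else:
                counts = np.where(mu > 0, rng.poisson(mu), 0)
            sample_id = f"{condition}_{rep}"
            data[sample_id] = counts.astype(np.int64)
            meta_rows.append({"sample_id": sample_id, "genotype": "WT",
                              "condition": condition, "replicate": rep})
    counts_df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionTable(counts_df, samples)


# ---------------------------------------------------------------------------
# Term annotation
# ---------------------------------------------------------------------------


def generate_term_annotation(truth: pd.DataFrame,
                             config: SimulationConfig) -> dict[str, set[str]]:
    """Random term memberships with one term enriched in k1 and one in k2.

    Background membership probability is ``term_base_rate`` for every term;
    the first two terms get odds scaled by ``term_odds_ratio`` inside their
    target class.  Fills ``planted_terms`` in the truth table in place.
    """
    if config.n_terms == 0:
        truth["planted_terms"] = [""] * len(truth)
        return {}
    gene_ids = list(truth.index)
    classes = truth["planted_class"].to_numpy()
    r = config.term_base_rate
    odds = r / (1 - r) * config.term_odds_ratio
    p_enriched = odds / (1 + odds)

    target_class = {1: "k1_broad", 2: "k2_tss"}
    terms: dict[str, set[str]] = {}
    membership: dict[str, list[str]] = {g: [] for g in gene_ids}
    for i in range(1, config.n_terms + 1):
        term_id = f"T{i:03d}"
        rng = _rng(config.seed, "term", term_id)
        p = np.full(len(gene_ids), r)
        if i in target_class and config.term_odds_ratio != 1.0:
            p = np.where(classes == target_class[i], p_enriched, p)
        hit = rng.random(len(gene_ids)) < p
        terms[term_id] = {g for g, h in zip(gene_ids, hit) if h}
        for g in terms[term_id]:
            membership[g].append(term_id)
    truth["planted_terms"] = [",".join(sorted(membership[g])) for g in gene_ids]
    return terms


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


def simulate_bundle(config: SimulationConfig) -> SimBundle:
    """Generate the complete in-memory fixture set for one config."""
    genes, truth = generate_annotation(config)
    terms = generate_term_annotation(truth, config)
    tracks: dict[str, CoverageTrack] = {}
    for condition in CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            for role in ("chip", "input"):
                t = generate_chip_coverage(genes, truth, config, condition, role, rep)
                tracks[t.sample_id] = t
        t = generate_chip_coverage(genes, truth, config, condition, "preimmune", 1)
        tracks[t.sample_id] = t
    expr = generate_rna_counts(genes, truth, config)
    return SimBundle(config, genes, truth, tracks, expr, terms)


def write_fixture_bundle(bundle: SimBundle, outdir) -> dict[str, str]:
    """Write every artifact as plain text; returns name -> relative path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "coverage").mkdir(exist_ok=True)
    paths: dict[str, str] = {}

    write_gff3(bundle.genes, outdir / "annotation.gff3",
               chrom_sizes=bundle.config.chrom_sizes)
    paths["annotation"] = "annotation.gff3"

    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t")
    paths["truth"] = "truth.tsv"

    for sample_id, track in sorted(bundle.tracks.items()):
        rel = f"coverage/{sample_id}.bedgraph"
        write_bedgraph(track, outdir / rel)
        paths[f"track:{sample_id}"] = rel

    write_counts_tsv(bundle.expr.counts, outdir / "rna_counts.tsv")
    paths["rna_counts"] = "rna_counts.tsv"
    write_sample_sheet(bundle.expr.samples, outdir / "samples.tsv")
    paths["samples"] = "samples.tsv"
    write_term_annotation(bundle.terms, outdir / "terms.tsv")
    paths["terms"] = "terms.tsv"

    echo = dataclasses.asdict(bundle.config)
    with open(outdir / "config.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["config"] = "config.json"
    return paths
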