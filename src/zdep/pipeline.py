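"""End-to-end orchestration: simulate or load inputs, call islands,
differential islands, gene assignment, metaprofiles, DE, bootstrap overlap,
term enrichment and interaction clustering, with a machine-readable
manifest.

The manifest is deterministic for a fixed config+seed (no wall-clock
content); per-stage timing goes to the run log only, which is excluded
from the checksum table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, expression, metaprofile, regions, simulate
from .io import (
    CoverageTrack,
    ExpressionTable,
    read_bedgraph,
    read_counts_tsv,
    read_gff3,
    read_sample_sheet,
    read_term_annotation,
    write_bed,
)
from .islands import IslandParams, call_differential, call_islands, merge_island_union

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "pool_tracks"]


@dataclass
class RunConfig:
    simulate: simulate.SimulationConfig | None = None
    inputs: dict | None = None
    island_fdr: float = 0.01
    window: int = 200
    gap: int = 200
    de_fdr: float = 0.001
    sea_alpha: float = 0.05
    bootstrap_iters: int = 1000
    interaction_k: int = 6
    conditions: tuple[str, str] = ("control", "stress")
    seed: int = 0

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of a simulate block or input paths")
        for name in ("island_fdr", "de_fdr", "sea_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.bootstrap_iters < 1:
            raise ValueError("bootstrap_iters must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = simulate.SimulationConfig(**sim)
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(simulate=sim, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pool_tracks(tracks: list[CoverageTrack], sample_id: str) -> CoverageTrack:
    """Sum replicate tracks window-wise into one pooled track."""
    if not tracks:
        raise ValueError("no tracks to pool")
    base = tracks[0]
    for t in tracks[1:]:
        if not base.same_grid(t):
            raise ValueError("pooled tracks must share a window grid")
    counts = {
        chrom: sum(t.counts[chrom] for t in tracks) for chrom in base.counts
    }
    return CoverageTrack(sample_id=sample_id, window_size=base.window_size,
                         counts=counts)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    for key in ("annotation", "counts", "samples", "tracks"):
        if key not in paths:
            raise ValueError(f"inputs block missing {key!r}")
    genes = read_gff3(paths["annotation"])
    chrom_sizes = paths.get("chrom_sizes")
    tracks = {}
    for sample_id, spec in paths["tracks"].items():
        tracks[sample_id] = read_bedgraph(spec["path"], cfg.window,
                                          chrom_sizes=chrom_sizes,
                                          sample_id=sample_id)
        tracks[sample_id].condition = spec["condition"]
        tracks[sample_id].role = spec["role"]
    counts = read_counts_tsv(paths["counts"])
    samples = read_sample_sheet(paths["samples"])
    expr = ExpressionTable(counts, samples)
    terms = read_term_annotation(paths["terms"]) if paths.get("terms") else {}
    return genes, None, tracks, expr, terms


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage; write artifacts + manifest under ``outdir``.

    Returns the manifest dict.  Any stage failure raises with the stage
    name prefixed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("zdep")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    manifest: dict = {"stages": {}, "files": {}, "parameters": {}}
    manifest["parameters"] = {
        "island_fdr": cfg.island_fdr,
        "de_fdr": cfg.de_fdr,
        "sea_alpha": cfg.sea_alpha,
        "bootstrap_iters": cfg.bootstrap_iters,
        "window": cfg.window,
        "gap": cfg.gap,
        "seed": cfg.seed,
        "conditions": list(cfg.conditions),
    }
    if cfg.simulate is not None:
        manifest["parameters"]["simulate"] = dataclasses.asdict(cfg.simulate)

    stage = "setup"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            logger.info("stage=%s", stage)
            bundle = simulate.simulate_bundle(cfg.simulate)
            paths = simulate.write_fixture_bundle(bundle, outdir / "inputs")
            manifest["stages"]["simulate"] = {"n_genes": len(bundle.genes),
                                              "files": paths}
            genes, truth = bundle.genes, bundle.truth
            tracks, expr, terms = bundle.tracks, bundle.expr, bundle.terms
            cond_of = {sid: sid.split("_")[0] for sid in tracks}
            role_of = {sid: sid.split("_")[1] for sid in tracks}
        else:
            stage = "load_inputs"
            logger.info("stage=%s", stage)
            genes, truth, tracks, expr, terms = _load_inputs(cfg)
            cond_of = {sid: t.condition for sid, t in tracks.items()}
            role_of = {sid: t.role for sid, t in tracks.items()}

        cond_a, cond_b = cfg.conditions
        params = IslandParams(window=cfg.window, gap=cfg.gap,
                              island_fdr=cfg.island_fdr)

        stage = "island_calling"
        logger.info("stage=%s", stage)
        pooled = {}
        islands = {}
        for cond in (cond_a, cond_b):
            chips = [t for s, t in sorted(tracks.items())
                     if cond_of[s] == cond and role_of[s] == "chip"]
            inputs = [t for s, t in sorted(tracks.items())
                      if cond_of[s] == cond and role_of[s] == "input"]
            if not chips or not inputs:
                raise ValueError(f"missing chip or input tracks for {cond}")
            pooled[(cond, "chip")] = pool_tracks(chips, f"{cond}_chip_pooled")
            pooled[(cond, "input")] = pool_tracks(inputs, f"{cond}_input_pooled")
            islands[cond] = call_islands(pooled[(cond, "chip")],
                                         pooled[(cond, "input")], params)
            write_bed(islands[cond], outdir / f"islands_{cond}.bed")
            manifest["stages"].setdefault("island_calling", {})[cond] = {
                "n_islands": len(islands[cond])
            }

        stage = "differential_islands"
        logger.info("stage=%s", stage)
        union = merge_island_union(islands[cond_a], islands[cond_b])
        diff = call_differential(pooled[(cond_a, "chip")], pooled[(cond_b, "chip")],
                                 union, params)
        write_bed(diff, outdir / "differential_islands.bed")
        manifest["stages"]["differential_islands"] = {
            "n_union": len(union), "n_differential": len(diff),
        }

        stage = "gene_assignment"
        logger.info("stage=%s", stage)
        chrom_lengths = {c: pooled[(cond_a, "chip")].chrom_length(c)
                         for c in pooled[(cond_a, "chip")].counts}
        gene_regions = [regions.compute_gene_regions(g, chrom_lengths[g.chrom])
                        for g in genes]
        assignment = regions.assign_islands_to_genes(
            islands[cond_a] + islands[cond_b], genes, chrom_lengths)
        calls, summary = regions.classify_differential(diff, gene_regions)
        call_rows = [
            {"gene_id": c.gene_id,
             "categories": ",".join(sorted(c.categories)),
             "n_islands": len(assignment.get(c.gene_id, []))}
            for c in calls
        ]
        pd.DataFrame(call_rows).to_csv(outdir / "gene_differential_calls.tsv",
                                       sep="\t", index=False)
        manifest["stages"]["gene_assignment"] = {"summary": summary}

        stage = "metaprofile"
        logger.info("stage=%s", stage)
        matrix = metaprofile.build_matrix(pooled[(cond_a, "chip")],
                                          pooled[(cond_a, "input")], genes)
        pd.DataFrame(matrix.values, index=matrix.gene_ids).to_csv(
            outdir / "metaprofile_matrix.tsv", sep="\t")
        lengths = pd.Series({g.gene_id: g.length for g in genes})
        fpkm_df = expression.fpkm(expr.counts, lengths)
        quintiles = metaprofile.assign_quintiles(expr, fpkm_df, cond_a,
                                                 matrix=matrix, seed=cfg.seed)
        clusters = metaprofile.cluster_patterns(matrix, k=3, seed=cfg.seed)
        strat = pd.DataFrame({
            "quintile": pd.Series(quintiles.assignments),
            "q0_subgroup": pd.Series(quintiles.q0_sub),
            "pattern_cluster": pd.Series(clusters.assignments),
        }).rename_axis("gene_id")
        strat.to_csv(outdir / "gene_stratification.tsv", sep="\t")
        manifest["stages"]["metaprofile"] = {
            "cluster_sizes": {k: len(clusters.genes_in(k))
                              for k in sorted(set(clusters.assignments.values()))},
            "replicate_concordance": _replicate_qc(tracks, cond_of, role_of),
        }

        stage = "differential_expression"
        logger.info("stage=%s", stage)
        groups = {s: cond_of_sample
                  for s, cond_of_sample in expr.samples["condition"].items()
                  if cond_of_sample in (cond_a, cond_b)}
        factors = expression.size_factors(expr.counts[list(groups)])
        de = expression.de_test(expr.counts[list(groups)], groups, factors,
                                alpha_fdr=cfg.de_fdr)
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        manifest["stages"]["differential_expression"] = {
            "n_up": int((de["direction"] == "up").sum()),
            "n_down": int((de["direction"] == "down").sum()),
        }

        stage = "bootstrap_overlap"
        logger.info("stage=%s", stage)
        expressed = set(expr.counts.index[(expr.counts > 0).any(axis=1)])
        pcg = {g.gene_id for g in genes if g.biotype == "PCG"}
        background = sorted(expressed & pcg)
        boot = enrichment.overlap_summary(de, calls, background,
                                         n_iter=cfg.bootstrap_iters, seed=cfg.seed)
        boot_rows = [
            {"deg_direction": d, "category": c, "observed": r.observed_overlap,
             "null_mean": r.null_mean, "null_sd": r.null_sd,
             "binomial_p": r.binomial_p, "direction": r.direction,
             "m": r.deg_set_size, "K": r.category_size, "N": r.background_size}
            for (d, c), r in sorted(boot.items())
        ]
        pd.DataFrame(boot_rows).to_csv(outdir / "bootstrap_overlap.tsv",
                                       sep="\t", index=False)
        manifest["stages"]["bootstrap_overlap"] = {
            f"{d}:{c}": {"p": r.binomial_p, "direction": r.direction}
            for (d, c), r in sorted(boot.items())
        }

        stage = "term_enrichment"
        logger.info("stage=%s", stage)
        sea_stats = {}
        for direction in ("up", "down"):
            degs = set(de.index[de["direction"] == direction]) & set(background)
            if degs and terms:
                sea = enrichment.sea_enrichment(degs, terms, background,
                                                alpha=cfg.sea_alpha)
                sea.to_csv(outdir / f"sea_{direction}.tsv", sep="\t", index=False)
                sea_stats[direction] = int(sea["significant"].sum())
        manifest["stages"]["term_enrichment"] = sea_stats

        stage = "interaction_clustering"
        logger.info("stage=%s", stage)
        de_union = de.index[de["q_value"] < cfg.de_fdr]
        if len(de_union) >= cfg.interaction_k:
            rlog = expression.rlog_like(expr.counts.loc[de_union], factors)
            ic = expression.cluster_interactions(rlog, k=cfg.interaction_k,
                                                 seed=cfg.seed)
            ic.memberships.to_csv(outdir / "interaction_memberships.tsv", sep="\t")
            assigned = pd.Series({g: (a or "unassigned")
                                  for g, a in ic.assignments.items()},
                                 name="cluster").rename_axis("gene_id")
            assigned.to_csv(outdir / "interaction_clusters.tsv", sep="\t")
            manifest["stages"]["interaction_clustering"] = {
                "n_genes": int(len(de_union)),
                "n_assigned": int(sum(a is not None for a in ic.assignments.values())),
            }
        else:
            manifest["stages"]["interaction_clustering"] = {
                "skipped": f"only {len(de_union)} DE genes for k={cfg.interaction_k}"
            }
    except Exception as exc:
        root.removeHandler(log_handler)
        log_handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name not in ("run.log", "manifest.json"):
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d files", len(manifest["files"]))
    root.removeHandler(log_handler)
    log_handler.close()
    return manifest


def _replicate_qc(tracks, cond_of, role_of) -> dict:
    out = {}
    by_cond: dict[str, list] = {}
    for sid, t in tracks.items():
        if role_of[sid] == "chip":
            by_cond.setdefault(cond_of[sid], []).append(t)
    for cond, ts in sorted(by_cond.items()):
        if len(ts) >= 2:
            r = metaprofile.replicate_concordance(ts[0], ts[1])
            out[cond] = None if np.isnan(r) else round(float(r), 4)
    return out
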