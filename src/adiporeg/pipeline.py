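"""End-to-end orchestration: simulate/load inputs, cluster, scan, enrich, PPI.

A run is driven by one :class:`PipelineConfig` and one global seed; each
stage gets a stable sub-seed derived from the global one, so stages are
individually reproducible.  Every output file carries a header comment
with the package version, the seed and a hash of the resolved parameters,
and a manifest lists every produced file with a content digest.  Two runs
with the same config and seed produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import CD2314ClusterAssigner
from .enrichment import MotifEnrichment
from .motifs import CONSERVATION_MODES, parse_pwm_collection, scan_promoters
from .ppi import induced_subgraph, map_orthologs, read_ortholog_table
from .promoters import (
    dedupe_overlapping,
    extract_promoter_windows,
    read_bedgraph,
    read_tss_bed,
)
from .simulate import (
    ExpressionSimConfig,
    GenomeSimConfig,
    random_pwm,
    shuffle_pwm_columns,
    simulate_expression,
    simulate_genome,
    simulate_ppi,
    write_jaspar,
)

log = logging.getLogger("adiporeg")

__all__ = ["PipelineConfig", "derive_seed", "run_all", "run_demo"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run.

    With ``demo=True`` every input is generated by the synthetic-data
    module at the sizes below; otherwise the ``*_path`` entries must point
    at existing files.
    """

    outdir: str = "adiporeg_out"
    seed: int = 0
    demo: bool = True

    # analysis parameters
    fdr_q: float = 0.05
    cluster5_direction: str = "same"
    upstream: int = 2000
    downstream: int = 1000
    max_overlap: int = 1500
    alpha: float = 0.01
    min_fold: float = 1.8
    pseudocount: float = 0.25
    correction_factor: int | None = None
    clusters_to_enrich: tuple[int, ...] = (1, 2, 3, 4, 5)

    # demo problem sizes
    demo_n_genes: int = 5000
    demo_n_per_cluster: int = 200
    demo_effect: float = 2.0
    demo_noise_sd: float = 0.25
    demo_n_background_promoters: int = 2000
    demo_n_pwms: int = 20
    demo_pwm_width: int = 10
    demo_foreground_rate: float = 0.4
    demo_background_rate: float = 0.05
    demo_n_human_proteins: int = 600
    demo_n_ppi_edges: int = 1000
    demo_frac_ambiguous: float = 0.3

    # external inputs (used when demo=False)
    matrix_path: str | None = None
    design_path: str | None = None
    tss_path: str | None = None
    genome_path: str | None = None
    conservation_path: str | None = None
    pwm_paths: tuple[tuple[str, str], ...] = ()  # (path, format)
    ppi_edges_path: str | None = None
    orthologs_path: str | None = None

    def validate(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_fold < 0:
            raise ValueError("min_fold must be non-negative")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window sizes must be non-negative")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if not self.demo:
            required = {
                "matrix_path": self.matrix_path,
                "design_path": self.design_path,
                "tss_path": self.tss_path,
                "genome_path": self.genome_path,
            }
            missing = [k for k, v in required.items() if not v]
            if missing:
                raise ValueError(f"demo=False but inputs missing: {missing}")

    def params_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = asdict(self)
        for key in list(params):
            if key.endswith("_path") or key in {"outdir", "pwm_paths"}:
                params.pop(key)
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("clusters_to_enrich", "pwm_paths"):
            if key in data and data[key] is not None:
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in data[key]
                )
        return cls(**data)


def _header(cfg: PipelineConfig) -> str:
    return f"# adiporeg v{__version__} seed={cfg.seed} config={cfg.params_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False):
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_demo(outdir: str | Path, seed: int = 0, **overrides) -> dict:
    """One-command synthetic demo at the default problem sizes."""
    cfg = PipelineConfig(outdir=str(outdir), seed=seed, demo=True, **overrides)
    return run_all(cfg)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns key in-memory results."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    results: dict = {}

    # -- stage 1: expression matrix -------------------------------------
    stage = "expression"
    try:
        if cfg.demo:
            sim_cfg = ExpressionSimConfig(
                n_per_cluster={c: cfg.demo_n_per_cluster for c in range(1, 6)},
                effect_day6=cfg.demo_effect,
                effect_day11=cfg.demo_effect,
                noise_sd=cfg.demo_noise_sd,
            )
            matrix, expr_truth = simulate_expression(
                cfg.demo_n_genes, config=sim_cfg, seed=derive_seed(cfg.seed, stage)
            )
            from .simulate import default_design

            design = default_design()
            _write_tsv(matrix, out / "matrix.tsv", cfg, index=True)
            _write_tsv(design, out / "design.tsv", cfg)
            _write_tsv(expr_truth, out / "expression_truth.tsv", cfg)
        else:
            matrix = pd.read_csv(cfg.matrix_path, sep="\t", comment="#", index_col=0)
            design = pd.read_csv(cfg.design_path, sep="\t", comment="#")
            expr_truth = None
        log.info("expression matrix: %d genes x %d samples", *matrix.shape)

        # -- stage 2: contrasts and cluster assignment -------------------
        stage = "clusters"
        assigner = CD2314ClusterAssigner(
            q=cfg.fdr_q, cluster5_direction=cfg.cluster5_direction
        ).fit(matrix, design)
        _write_tsv(assigner.contrasts_, out / "contrasts.tsv", cfg)
        _write_tsv(
            assigner.labels_.reset_index().rename(columns={0: "cluster"}),
            out / "clusters.tsv", cfg,
        )
        cluster_sizes = {
            c: len(assigner.cluster_genes(c)) for c in cfg.clusters_to_enrich
        }
        log.info("cluster sizes: %s", cluster_sizes)
        results["assigner"] = assigner

        # -- stage 3: promoter universe ----------------------------------
        stage = "promoters"
        if cfg.demo:
            planted_pwm = random_pwm(
                "PLANTED01", width=cfg.demo_pwm_width,
                seed=derive_seed(cfg.seed, "planted_pwm"),
            )
            fg_ids = expr_truth.loc[
                expr_truth.planted_cluster == 1, "gene_id"
            ].tolist()
            rng = np.random.default_rng(derive_seed(cfg.seed, "bg_choice"))
            unplanted = expr_truth.loc[
                expr_truth.planted_cluster == 0, "gene_id"
            ].tolist()
            bg_ids = list(
                rng.choice(unplanted, size=cfg.demo_n_background_promoters,
                           replace=False)
            )
            genome = simulate_genome(
                len(fg_ids), len(bg_ids), planted_pwm,
                config=GenomeSimConfig(
                    foreground_rate=cfg.demo_foreground_rate,
                    background_rate=cfg.demo_background_rate,
                ),
                seed=derive_seed(cfg.seed, "genome"),
                outdir=out,
                promoter_length=cfg.upstream + cfg.downstream,
                foreground_ids=fg_ids, background_ids=bg_ids,
            )
            tss_path, genome_path = genome["tss"], genome["fasta"]
            cons_path = genome["conservation"]
        else:
            tss_path, genome_path = cfg.tss_path, cfg.genome_path
            cons_path = cfg.conservation_path
        tss = read_tss_bed(tss_path)
        conservation = read_bedgraph(cons_path) if cons_path else None
        promoters = extract_promoter_windows(
            tss, genome_path, conservation,
            upstream=cfg.upstream, downstream=cfg.downstream,
        )
        promoters = dedupe_overlapping(
            promoters, seed=derive_seed(cfg.seed, "dedupe"),
            max_overlap=cfg.max_overlap,
        )
        log.info("promoter universe: %d promoters", len(promoters))
        with open(out / "promoters.fa", "w") as fh:
            for p in promoters:
                fh.write(f">{p.gene_id}|{p.chrom}:{p.start}-{p.end}({p.strand})\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i : i + 60] + "\n")
        with open(out / "promoter_conservation.tsv", "w") as fh:
            fh.write(_header(cfg))
            fh.write("gene_id\tconservation\n")
            for p in promoters:
                vals = ",".join(f"{v:.4f}" for v in p.conservation)
                fh.write(f"{p.gene_id}\t{vals}\n")
        results["promoters"] = promoters

        # -- stage 4: PWM collection -------------------------------------
        stage = "pwms"
        if cfg.demo:
            decoys = [
                shuffle_pwm_columns(
                    planted_pwm, seed=derive_seed(cfg.seed, f"decoy{i}"),
                    motif_id=f"DECOY{i:02d}",
                )
                for i in range(cfg.demo_n_pwms - 1)
            ]
            pwm_path = write_jaspar([planted_pwm] + decoys, out / "pwms.jaspar")
            pwms = parse_pwm_collection(pwm_path.read_text(), "jaspar")
        else:
            pwms = []
            for path, fmt in cfg.pwm_paths:
                pwms.extend(parse_pwm_collection(Path(path).read_text(), fmt))
        for pwm in pwms:
            pwm.pseudocount = cfg.pseudocount
        log.info("PWM collection: %d matrices", len(pwms))

        # -- stage 5: scanning -------------------------------------------
        stage = "scan"
        scores = scan_promoters(promoters, pwms, CONSERVATION_MODES)
        _write_tsv(scores, out / "scores.tsv", cfg)

        # -- stage 6: enrichment per cluster -----------------------------
        stage = "enrich"
        universe_ids = {p.gene_id for p in promoters}
        results["enrichment"] = {}
        for cluster in cfg.clusters_to_enrich:
            genes = set(assigner.cluster_genes(cluster)) & universe_ids
            if not genes:
                enriched = pd.DataFrame()
            else:
                enriched = MotifEnrichment(
                    alpha=cfg.alpha, min_fold=cfg.min_fold,
                    correction_factor=cfg.correction_factor,
                ).fit(scores, genes).records_
            _write_tsv(enriched, out / f"enrichment_cluster{cluster}.tsv", cfg)
            results["enrichment"][cluster] = enriched
            if len(enriched):
                log.info("cluster %d: %d enriched motifs", cluster, len(enriched))

        # -- stage 7: PPI subnetworks ------------------------------------
        stage = "ppi"
        if cfg.demo:
            # tie mouse ids to expression genes: cluster genes first so the
            # induced modules are non-trivial
            order = expr_truth.assign(
                unplanted=expr_truth.planted_cluster == 0
            ).sort_values(
                ["unplanted", "planted_cluster", "gene_id"], kind="mergesort"
            )
            planted_first = order["gene_id"].tolist()
            ppi = simulate_ppi(
                cfg.demo_n_human_proteins, cfg.demo_n_ppi_edges,
                cfg.demo_frac_ambiguous,
                seed=derive_seed(cfg.seed, "ppi"),
                mouse_id_pool=planted_first,
            )
            edges_df, ortho_df = ppi["edges"], ppi["orthologs"]
            _write_tsv(edges_df, out / "human_edges.tsv", cfg)
            _write_tsv(ortho_df, out / "orthologs.tsv", cfg)
            _write_tsv(ppi["truth"], out / "ppi_truth.tsv", cfg)
        else:
            if cfg.ppi_edges_path and cfg.orthologs_path:
                edges_df = pd.read_csv(cfg.ppi_edges_path, sep="\t", comment="#",
                                       dtype=str)
                ortho_df = pd.read_csv(cfg.orthologs_path, sep="\t", comment="#",
                                       dtype=str)
            else:
                edges_df = ortho_df = None
        if edges_df is not None:
            orthologs = read_ortholog_table(ortho_df)
            human_edges = list(
                zip(edges_df.iloc[:, 0].astype(str), edges_df.iloc[:, 1].astype(str))
            )
            mouse_edges = map_orthologs(human_edges, orthologs)
            _write_tsv(
                pd.DataFrame(sorted(mouse_edges), columns=["mouse_a", "mouse_b"]),
                out / "mouse_edges.tsv", cfg,
            )
            results["mouse_edges"] = mouse_edges
            for cluster in cfg.clusters_to_enrich:
                genes = assigner.cluster_genes(cluster)
                module = induced_subgraph(mouse_edges, genes)
                rows = [
                    {"gene_id": n, "component": module.nodes[n]["component"]}
                    for n in sorted(module.nodes)
                ]
                _write_tsv(
                    pd.DataFrame(rows, columns=["gene_id", "component"]),
                    out / f"ppi_cluster{cluster}_components.tsv", cfg,
                )
                _write_tsv(
                    pd.DataFrame(sorted(map(sorted, module.edges)),
                                 columns=["mouse_a", "mouse_b"]),
                    out / f"ppi_cluster{cluster}_edges.tsv", cfg,
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- manifest and resolved config ------------------------------------
    resolved = asdict(cfg)
    resolved.pop("outdir")  # derivable from the file location; keeps trees comparable
    resolved["version"] = __version__
    resolved["config_hash"] = cfg.params_hash()
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
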