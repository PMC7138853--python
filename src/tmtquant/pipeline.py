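"""End-to-end pipeline orchestration from a YAML config.

Stage order: quantify per plex -> integrate -> impute -> batch-correct ->
differential expression (all configured contrasts, pooled over imputations)
-> GSEA -> signatures -> clustering/PCA.  Every run writes a manifest
listing each stage's inputs, outputs and parameters; a single global seed
fans out to per-stage seeds through a fixed SeedSequence derivation so any
stage can be rerun in isolation with identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gsea as gsea_mod
from . import signatures as sig_mod
from . import stats as stats_mod
from .impute import ImputeConfig, batch_correct, pmm_impute
from .quant import FilterCriteria, quantify_cohort
from .signatures import SignatureThresholds
from .stats import DeThresholds

logger = logging.getLogger("tmtquant")

# per-stage seed derivation codes (SeedSequence([global_seed, code, ...]))
STAGE_SEEDS = {"impute": 11, "gsea": 22}


@dataclass
class PipelineConfig:
    """Validated, path-resolved pipeline configuration."""

    psm_tables: list
    design: Path
    annotation: Path
    gene_sets: Path | None = None
    homologs: Path | None = None
    mouse_de: Path | None = None
    rollup_by: str = "gene"
    pooled_reference: bool = False
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    de_thresholds: DeThresholds = field(default_factory=DeThresholds)
    signature_thresholds: SignatureThresholds = field(
        default_factory=SignatureThresholds)
    contrasts: list = field(default_factory=list)
    signature_contrast: str | None = None
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_weight_exponent: float = 1.0
    cluster_axis: str = "samples"
    cluster_median_center: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def p(x):
            return None if x is None else (base / x)

        sections = {
            "filter": FilterCriteria, "impute": ImputeConfig,
            "de_thresholds": DeThresholds,
            "signature_thresholds": SignatureThresholds,
        }
        kwargs = {}
        for key, klass in sections.items():
            kwargs[key] = klass(**(raw.get(key) or {}))
        return cls(
            psm_tables=[p(x) for x in raw.get("psm_tables", [])],
            design=p(raw.get("design")),
            annotation=p(raw.get("annotation")),
            gene_sets=p(raw.get("gene_sets")),
            homologs=p(raw.get("homologs")),
            mouse_de=p(raw.get("mouse_de")),
            rollup_by=raw.get("rollup_by", "gene"),
            pooled_reference=bool(raw.get("pooled_reference", False)),
            contrasts=list(raw.get("contrasts", [])),
            signature_contrast=raw.get("signature_contrast"),
            gsea_n_perm=int(raw.get("gsea", {}).get("n_perm", 1000)),
            gsea_min_size=int(raw.get("gsea", {}).get("min_size", 5)),
            gsea_max_size=int(raw.get("gsea", {}).get("max_size", 500)),
            gsea_weight_exponent=float(
                raw.get("gsea", {}).get("weight_exponent", 1.0)),
            cluster_axis=raw.get("cluster", {}).get("axis", "samples"),
            cluster_median_center=bool(
                raw.get("cluster", {}).get("median_center", True)),
            seed=int(raw.get("seed", 0)),
            **kwargs,
        )


def validate_config(path) -> list:
    """Schema and path checks; returns an itemized failure list (empty when
    valid).  Never touches data contents."""
    failures = []
    try:
        cfg = PipelineConfig.from_yaml(path)
    except (TypeError, ValueError, yaml.YAMLError) as exc:
        return [f"config parse error: {exc}"]
    if not cfg.psm_tables:
        failures.append("psm_tables: at least one PSM table required")
    for name in ("design", "annotation"):
        if getattr(cfg, name) is None:
            failures.append(f"{name}: required path missing")
    for name in ("psm_tables",):
        for pth in cfg.psm_tables:
            if pth is not None and not Path(pth).exists():
                failures.append(f"psm_tables: path does not exist: {pth}")
    for name in ("design", "annotation", "gene_sets", "homologs", "mouse_de"):
        pth = getattr(cfg, name)
        if pth is not None and not Path(pth).exists():
            failures.append(f"{name}: path does not exist: {pth}")
    for section in ("filter", "impute", "de_thresholds",
                    "signature_thresholds"):
        try:
            getattr(cfg, section).validate()
        except ValueError as exc:
            failures.append(f"{section}: {exc}")
    if cfg.rollup_by not in ("gene", "protein"):
        failures.append("rollup_by: must be 'gene' or 'protein'")
    if cfg.cluster_axis not in ("samples", "proteins"):
        failures.append("cluster.axis: must be 'samples' or 'proteins'")
    for c in cfg.contrasts:
        if ":" not in c:
            failures.append(f"contrasts: malformed contrast {c!r}")
    return failures


def _contrast_slug(contrast: str) -> str:
    return contrast.replace(":", "_vs_").replace("+", "-")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True):
    df.to_csv(path, sep="\t", index=index, na_rep="")
    return path


def run_pipeline(config: PipelineConfig, output_dir) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    A stage failure aborts with the stage name and cause; outputs written by
    earlier stages are retained.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}
    stage = "setup"

    def rel(p):
        p = Path(p)
        try:
            return str(p.relative_to(out))
        except ValueError:
            return str(p)

    def record(name, inputs, outputs, params):
        manifest["stages"].append({
            "stage": name,
            "inputs": [rel(i) for i in inputs],
            "outputs": [rel(o) for o in outputs],
            "params": params,
        })

    try:
        # ---- load -----------------------------------------------------
        stage = "load"
        design = pd.read_csv(config.design, sep="\t")
        annotation = pd.read_csv(config.annotation, sep="\t")
        plex_ids = list(design["plex_id"].unique())
        designs = [design[design["plex_id"] == p].reset_index(drop=True)
                   for p in plex_ids]
        psm_tables = [pd.read_csv(p, sep="\t") for p in config.psm_tables]

        # ---- quantify -------------------------------------------------
        stage = "quantify"
        quant = quantify_cohort(psm_tables, designs, criteria=config.filter,
                                by=config.rollup_by,
                                pooled_reference=config.pooled_reference)
        ab = quant.abundance.copy()
        ab.index.name = config.rollup_by
        outputs = [
            _write_tsv(ab, out / "abundance.tsv"),
            _write_tsv(quant.normalized.ratios.rename_axis(config.rollup_by),
                       out / "normalized_ratios.tsv"),
            _write_tsv(pd.DataFrame(quant.filter_reports, index=plex_ids)
                       .rename_axis("plex"), out / "filter_report.tsv"),
        ]
        record("quantify", config.psm_tables + [config.design],
               outputs, {"rollup_by": config.rollup_by,
                         "filter": dataclasses.asdict(config.filter),
                         "pooled_reference": config.pooled_reference})

        # ---- impute ---------------------------------------------------
        stage = "impute"
        icfg = dataclasses.replace(
            config.impute,
            seed=np.random.SeedSequence(
                [config.seed, STAGE_SEEDS["impute"]]).generate_state(1)[0]
            % (2 ** 31))
        imputed = pmm_impute(quant.abundance, icfg)
        outputs = [
            _write_tsv(m.rename_axis(config.rollup_by),
                       out / f"imputed_{i + 1}.tsv")
            for i, m in enumerate(imputed)
        ]
        record("impute", [out / "abundance.tsv"], outputs,
               {"m": icfg.m, "maxit": icfg.maxit, "donors": icfg.donors,
                "seed": int(icfg.seed)})

        # ---- batch-correct -------------------------------------------
        stage = "batch-correct"
        batches = annotation.set_index("sample_id")["batch"]
        corrected = [batch_correct(m, batches) for m in imputed]
        consensus = sum(corrected) / len(corrected)
        outputs = [
            _write_tsv(m.rename_axis(config.rollup_by),
                       out / f"batch_corrected_{i + 1}.tsv")
            for i, m in enumerate(corrected)
        ]
        outputs.append(_write_tsv(consensus.rename_axis(config.rollup_by),
                                  out / "expression_matrix.tsv"))
        record("batch-correct",
               [out / f"imputed_{i + 1}.tsv" for i in range(len(imputed))],
               outputs, {"batches": "annotation.batch"})

        # ---- differential expression ---------------------------------
        stage = "de"
        de_tables = {}
        de_outputs = []
        for contrast in config.contrasts:
            ga, gb = stats_mod.resolve_contrast(annotation, contrast)
            de = stats_mod.differential_expression_pooled(corrected, ga, gb)
            de_tables[contrast] = de
            de_outputs.append(_write_tsv(
                de.rename_axis(config.rollup_by),
                out / f"de_{_contrast_slug(contrast)}.tsv"))
        record("de", [out / "expression_matrix.tsv"], de_outputs,
               {"contrasts": config.contrasts, "pooling": "rubin"})

        # ---- gsea -----------------------------------------------------
        stage = "gsea"
        if config.gene_sets is not None and de_tables:
            universe = list(quant.abundance.index)
            collection = gsea_mod.read_gmt(
                config.gene_sets, universe=universe,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size)
            outputs = []
            for i, (contrast, de) in enumerate(de_tables.items()):
                ranked = de["log2fc"].dropna()
                seed = np.random.SeedSequence(
                    [config.seed, STAGE_SEEDS["gsea"], i]
                ).generate_state(1)[0] % (2 ** 31)
                res = gsea_mod.preranked_gsea(
                    ranked, collection, n_perm=config.gsea_n_perm,
                    seed=int(seed),
                    weight_exponent=config.gsea_weight_exponent)
                outputs.append(_write_tsv(
                    res, out / f"gsea_{_contrast_slug(contrast)}.tsv"))
            record("gsea", [config.gene_sets] + de_outputs, outputs,
                   {"n_perm": config.gsea_n_perm,
                    "min_size": config.gsea_min_size,
                    "max_size": config.gsea_max_size,
                    "weight_exponent": config.gsea_weight_exponent})

        # ---- signatures ----------------------------------------------
        stage = "signatures"
        if de_tables:
            contrast = config.signature_contrast or config.contrasts[0]
            de = de_tables[contrast]
            up = sig_mod.significant_proteins(
                de, config.signature_thresholds, "up")
            down = sig_mod.significant_proteins(
                de, config.signature_thresholds, "down")
            outputs = []
            if config.mouse_de is not None and config.homologs is not None:
                mouse_de = pd.read_csv(config.mouse_de, sep="\t",
                                       index_col=0)
                m_up = sig_mod.significant_proteins(
                    mouse_de, config.signature_thresholds, "up")
                m_down = sig_mod.significant_proteins(
                    mouse_de, config.signature_thresholds, "down")
                hmap = sig_mod.load_homolog_map(config.homologs)
                m_up = sig_mod.map_homologs(m_up, hmap).mapped
                m_down = sig_mod.map_homologs(m_down, hmap).mapped
                overlap = sig_mod.overlap_signature(up, down, m_up, m_down)
                outputs.append(_write_tsv(overlap.membership,
                                          out / "signature_membership.tsv"))
                venn_path = out / "signature_venn.json"
                venn_path.write_text(json.dumps(overlap.venn, indent=2,
                                                sort_keys=True))
                outputs.append(venn_path)
                up_out, down_out = overlap.up, overlap.down
            else:
                up_out, down_out = up, down
            sig_df = pd.DataFrame(
                {"gene": sorted(up_out) + sorted(down_out),
                 "direction": ["up"] * len(up_out) + ["down"] * len(down_out)})
            outputs.append(_write_tsv(sig_df, out / "signature.tsv",
                                      index=False))
            record("signatures",
                   [out / f"de_{_contrast_slug(contrast)}.tsv"],
                   outputs,
                   {"contrast": contrast,
                    "thresholds": dataclasses.asdict(
                        config.signature_thresholds)})

        # ---- clustering / PCA ----------------------------------------
        stage = "cluster"
        clus = stats_mod.hierarchical_cluster(
            consensus, axis=config.cluster_axis,
            median_center=config.cluster_median_center)
        (out / "dendrogram.newick").write_text(clus.newick + "\n")
        leaf = pd.DataFrame({"leaf": clus.leaf_order})
        scores, evr = stats_mod.pca_scores(consensus, n_components=2)
        groups = annotation.set_index("sample_id")["group"]
        anova = stats_mod.anova_oneway(consensus, groups)
        outputs = [
            out / "dendrogram.newick",
            _write_tsv(leaf, out / "leaf_order.tsv", index=False),
            _write_tsv(scores.rename_axis("sample_id"),
                       out / "pca_scores.tsv"),
            _write_tsv(anova.rename_axis(config.rollup_by),
                       out / "anova.tsv"),
        ]
        record("cluster", [out / "expression_matrix.tsv"], outputs,
               {"axis": config.cluster_axis,
                "median_center": config.cluster_median_center,
                "linkage": "complete", "metric": "uncentered_correlation",
                "pca_explained_variance": [float(v) for v in evr]})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
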