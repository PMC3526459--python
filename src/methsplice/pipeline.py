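"""End-to-end orchestration: load inputs, run every analysis, write TSVs.

Stage order: load annotation and methylation calls -> classify gene
methylation and feature inclusion -> boundary meta-profiles -> gene-body
quintile profiles -> correlation, splicing enrichment and size contrasts
-> conservation contrasts.  All canonical outputs are headered TSVs plus
one JSON manifest (config echo, input checksums, per-stage row counts);
identical inputs and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_FPKM_GRID,
    distribution_contrast,
    methylation_expression_correlation,
    splicing_enrichment,
)
from .conservation import (
    CONSERVATION_EVALUE_THRESHOLD,
    conservation_contrast,
    load_evalue_table,
)
from .expression import GeneModel, classify_alternative_splicing, classify_inclusion, load_annotation
from .methylation import classify_gene_methylation, load_methylation_calls, region_methylation
from .profiles import ProfileConfig, boundary_profile_test, genebody_quintile_profile

__all__ = ["PipelineConfig", "run_pipeline", "gene_feature_tables"]


@dataclass
class PipelineConfig:
    """Inputs, analysis settings and output location of one run."""

    annotation: Path
    methylation: Path
    expression: Path
    outdir: Path
    conservation: Path | None = None
    fpkm_grid: tuple = DEFAULT_FPKM_GRID
    alpha: float = 0.05
    correction: str = "none"
    one_based_methylation: bool = False
    flank_bp: int = 200
    n_bins: int = 20
    genebody_flank_bp: int = 2000
    genebody_n_bins: int = 40
    min_fpkm_expressed: float = 0.0
    evalue_threshold: float = CONSERVATION_EVALUE_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        self.annotation = Path(self.annotation)
        self.methylation = Path(self.methylation)
        self.expression = Path(self.expression)
        self.outdir = Path(self.outdir)
        if self.conservation is not None:
            self.conservation = Path(self.conservation)

    def validate_paths(self) -> None:
        for name in ("annotation", "methylation", "expression", "conservation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")

    def to_jsonable(self) -> dict:
        # paths reduce to basenames and the output directory is omitted so
        # that identical inputs + settings give a byte-identical manifest
        # wherever the run lands
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return {k: (v.name if isinstance(v, Path) else v) for k, v in d.items()}


def gene_feature_tables(models: list[GeneModel]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene exon and intron interval tables with deterministic ids.

    Exons are the gene's merged exon union in genomic order, ids
    ``<gene>.e<k>``; introns are the gaps between consecutive union
    exons, ids ``<gene>.i<k>``.  This is the id convention quantification
    tables must follow.
    """
    ex_rows, in_rows = [], []
    for m in models:
        union = m.exon_union
        for k, (s, e) in enumerate(union, start=1):
            ex_rows.append((f"{m.gene_id}.e{k}", m.gene_id, m.chrom, s, e, m.strand))
        for k, ((_, e0), (s1, _)) in enumerate(zip(union, union[1:]), start=1):
            if s1 > e0:
                in_rows.append((f"{m.gene_id}.i{k}", m.gene_id, m.chrom, e0, s1, m.strand))
    cols = ["feature_id", "gene_id", "chrom", "start", "end", "strand"]
    return pd.DataFrame(ex_rows, columns=cols), pd.DataFrame(in_rows, columns=cols)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _contingency_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        rows.append(
            {
                "threshold": r.threshold_context,
                "a": a, "b": b, "c": c, "d": d,
                "proportion_a": r.proportion_a,
                "proportion_b": r.proportion_b,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "testable": r.testable,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle.

    Aborts before writing anything if an input path is missing.  The
    result dict mirrors what is written under ``config.outdir``.
    """
    config.validate_paths()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- load
    models = load_annotation(config.annotation)
    sites = load_methylation_calls(config.methylation, one_based=config.one_based_methylation)
    expr = pd.read_csv(config.expression, sep="\t")
    counts["genes"] = len(models)
    counts["cpg_sites"] = len(sites)
    counts["expression_records"] = len(expr)

    exon_iv, intron_iv = gene_feature_tables(models)
    tr_fpkm = (
        expr[expr["feature_type"] == "transcript"]
        .set_index("feature_id")["value"]
        .astype(float)
    )
    feat_cols = ["feature_id", "value"]
    exon_expr = expr.loc[expr["feature_type"] == "exon", feat_cols].merge(
        exon_iv, on="feature_id"
    )
    intron_expr = expr.loc[expr["feature_type"] == "intron", feat_cols].merge(
        intron_iv, on="feature_id"
    )

    # --- classify
    methylated = classify_gene_methylation(sites, models)
    exon_expr["included"] = classify_inclusion(exon_expr)
    intron_expr["included"] = classify_inclusion(intron_expr)
    gene_fpkm = tr_fpkm.groupby(
        tr_fpkm.index.to_series().map({t.transcript_id: m.gene_id for m in models for t in m.transcripts})
    ).sum()
    gene_fpkm.index.name = "gene_id"
    splice0 = {
        m.gene_id: classify_alternative_splicing(m, tr_fpkm, min_fpkm=0.0) for m in models
    }
    gene_summary = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "chrom": [m.chrom for m in models],
            "start": [m.start for m in models],
            "end": [m.end for m in models],
            "strand": [m.strand for m in models],
            "gene_length_bp": [m.gene_length_bp for m in models],
            "max_exon_count": [m.max_exon_count for m in models],
            "methylated": [bool(methylated[m.gene_id]) for m in models],
            "gene_fpkm": [float(gene_fpkm.get(m.gene_id, 0.0)) for m in models],
            "expressed": [splice0[m.gene_id].expressed for m in models],
            "alternatively_spliced": [splice0[m.gene_id].alternatively_spliced for m in models],
        }
    )
    gm = {m.gene_id: m for m in models}
    body = {
        m.gene_id: region_methylation(sites, m.chrom, m.start, m.end) for m in models
    }
    gene_summary["meth_relative"] = [body[g].relative for g in gene_summary["gene_id"]]
    gene_summary["meth_absolute"] = [body[g].absolute for g in gene_summary["gene_id"]]
    _write(gene_summary, outdir / "gene_summary.tsv")
    counts["methylated_genes"] = int(gene_summary["methylated"].sum())

    # --- boundary profiles: included vs skipped features of genes that are
    # both methylated and expressed (the population in which inclusion and
    # methylation are jointly observable)
    focus = set(
        gene_summary.loc[
            gene_summary["methylated"] & gene_summary["expressed"], "gene_id"
        ]
    )
    profiles = {}
    for feat_name, feat in (("exons", exon_expr), ("introns", intron_expr)):
        sub = feat[feat["gene_id"].isin(focus)]
        inc = sub[sub["included"]]
        skp = sub[~sub["included"]]
        for anchor in ("start", "end"):
            key = f"{feat_name}_{anchor}"
            if len(inc) == 0 or len(skp) == 0:
                profiles[key] = None
                continue
            pconf = ProfileConfig(
                flank_bp=config.flank_bp,
                n_bins=config.n_bins,
                anchor=anchor,
                alpha=config.alpha,
                correction=config.correction,
            )
            prof = boundary_profile_test(inc, skp, sites, pconf)
            profiles[key] = prof
            prof.to_tsv(outdir / f"profile_{key}.tsv")

    # --- gene-body quintile profiles
    gb_conf = {}
    for metric in ("relative", "absolute"):
        cfg = ProfileConfig(
            flank_bp=config.genebody_flank_bp,
            n_bins=config.genebody_n_bins,
            metric=metric,
        )
        tab = genebody_quintile_profile(gene_summary, gene_fpkm, sites, cfg)
        gb_conf[metric] = tab
        _write(tab, outdir / f"genebody_quintiles_{metric}.tsv")

    # --- correlation (expressed-and-methylated genes)
    corr_rows = []
    correlations = {}
    for metric in ("relative", "absolute"):
        res = methylation_expression_correlation(
            gene_fpkm,
            gene_summary.set_index("gene_id")[f"meth_{metric}"],
            methylated,
            min_fpkm=config.min_fpkm_expressed,
        )
        correlations[metric] = res
        corr_rows.append(
            {
                "metric": metric,
                "n": res.n,
                "pearson_r": res.pearson_r,
                "pearson_p": res.pearson_p,
                "spearman_rho": res.spearman_rho,
                "spearman_p": res.spearman_p,
                "defined": res.defined,
            }
        )
    _write(pd.DataFrame(corr_rows), outdir / "correlation.tsv")

    # --- splicing enrichment across the FPKM grid
    enrich = splicing_enrichment(methylated, models, tr_fpkm, config.fpkm_grid)
    _write(_contingency_frame(enrich), outdir / "enrichment.tsv")

    # --- size distribution contrasts (panels of the length/exon figures)
    expressed_set = gene_summary[gene_summary["expressed"]]
    contrast_rows = []
    contrasts = {}
    for metric in ("gene_length_bp", "max_exon_count"):
        panels = {
            "methylated_vs_unmethylated": (
                gene_summary[gene_summary["methylated"]][metric],
                gene_summary[~gene_summary["methylated"]][metric],
            ),
            "spliced_vs_unspliced": (
                expressed_set[expressed_set["alternatively_spliced"]][metric],
                expressed_set[~expressed_set["alternatively_spliced"]][metric],
            ),
            "methylated_vs_unmethylated_within_unspliced": (
                expressed_set[~expressed_set["alternatively_spliced"] & expressed_set["methylated"]][metric],
                expressed_set[~expressed_set["alternatively_spliced"] & ~expressed_set["methylated"]][metric],
            ),
            "methylated_vs_unmethylated_within_spliced": (
                expressed_set[expressed_set["alternatively_spliced"] & expressed_set["methylated"]][metric],
                expressed_set[expressed_set["alternatively_spliced"] & ~expressed_set["methylated"]][metric],
            ),
        }
        for panel, (va, vb) in panels.items():
            if len(va) == 0 or len(vb) == 0:
                continue
            c = distribution_contrast(va, vb, metric=metric)
            contrasts[(metric, panel)] = c
            contrast_rows.append(
                {
                    "metric": metric,
                    "panel": panel,
                    "n_a": c.n_a,
                    "n_b": c.n_b,
                    "median_a": float(np.median(va)),
                    "median_b": float(np.median(vb)),
                    "wilcoxon_p": c.wilcoxon_p,
                }
            )
    _write(pd.DataFrame(contrast_rows), outdir / "contrasts.tsv")

    # --- conservation contrasts
    cons_rows = []
    conservation = {}
    if config.conservation is not None:
        calls = load_evalue_table(config.conservation, threshold=config.evalue_threshold)
        gs = gene_summary.set_index("gene_id")
        meth_labels = gs["methylated"]
        as_labels = gs.loc[gs["expressed"], "alternatively_spliced"]
        families = {
            "methylated_vs_unmethylated": (meth_labels, "methylated", "unmethylated"),
            "spliced_vs_unspliced": (as_labels, "spliced", "unspliced"),
            "spliced_vs_unspliced_within_methylated": (
                as_labels[gs.loc[as_labels.index, "methylated"]],
                "methylated_spliced", "methylated_unspliced",
            ),
            "methylated_vs_unmethylated_within_spliced": (
                meth_labels[gs["expressed"] & gs["alternatively_spliced"]],
                "spliced_methylated", "spliced_unmethylated",
            ),
        }
        for sp in sorted(calls["species"].unique()):
            for family, (labels, name_a, name_b) in families.items():
                cc = conservation_contrast(calls, labels, sp, name_a, name_b)
                conservation[(family, sp)] = cc
                cons_rows.append(
                    {
                        "family": family,
                        "species": sp,
                        "n_a": cc.n_a,
                        "n_b": cc.n_b,
                        "proportion_a": cc.proportion_a,
                        "proportion_b": cc.proportion_b,
                        "p_value": cc.p_value,
                    }
                )
        _write(pd.DataFrame(cons_rows), outdir / "conservation_contrasts.tsv")

    # --- manifest
    inputs = {
        "annotation": config.annotation,
        "methylation": config.methylation,
        "expression": config.expression,
    }
    if config.conservation is not None:
        inputs["conservation"] = config.conservation
    manifest = {
        "version": __version__,
        "config": config.to_jsonable(),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "models": models,
        "sites": sites,
        "gene_summary": gene_summary,
        "gene_fpkm": gene_fpkm,
        "methylated": methylated,
        "profiles": profiles,
        "genebody": gb_conf,
        "correlations": correlations,
        "enrichment": enrich,
        "contrasts": contrasts,
        "conservation": conservation,
        "manifest": manifest,
    }
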