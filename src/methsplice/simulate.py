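"""Synthetic annotation, methylation, expression and conservation data.

The generator emulates the four inputs of the analysis — a multi-exon
gene annotation, a per-CpG bisulfite methylation-call table, exon/intron
RPKM and transcript FPKM tables, and a per-(gene, species) best-hit
E-value table — with a fully known planted structure:

* each gene carries planted methylated / alternatively-spliced /
  expressed flags, with the splicing flag drawn conditionally on the
  methylation flag so that the population odds ratio between the two is
  exactly ``splicing_odds_ratio``;
* CpG sites get a true methylation level drawn from a context-specific
  Beta family (included exon, skipped exon, intron, intergenic), with
  genes planted unmethylated set to a true level of exactly 0 so the
  "any mCG > 0" gene classification is exactly recoverable;
* skipped exons and introns get RPKM exactly 0 (a noise switch can relax
  this), included features of expressed genes get strictly positive
  lognormal values;
* conservation flags are Bernoulli with per-(species, category)
  probabilities, realised as E-values on either side of the conservation
  threshold; a fraction of non-conserved genes is dropped from the table
  entirely (no BLAST hit).

Identical config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import GeneModel, Transcript

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SizingError",
    "generate_annotation",
    "generate_methylation",
    "generate_expression",
    "generate_conservation",
    "simulate_bundle",
    "write_gff3",
]

CATEGORY_KEYS = (
    "methylated_spliced",
    "methylated_unspliced",
    "unmethylated_spliced",
    "unmethylated_unspliced",
)

DEFAULT_SPECIES = (
    "H_sapiens",
    "C_intestinalis",
    "A_pisum",
    "N_vitripennis",
    "D_melanogaster",
)


def _default_conservation_probs() -> dict[str, dict[str, float]]:
    # Conservation is most likely for genes that are both methylated and
    # alternatively spliced, least likely for genes that are neither,
    # loosely shaped like the honeybee cross-species proportions.
    base = {
        "H_sapiens": 0.10,
        "C_intestinalis": 0.06,
        "A_pisum": 0.15,
        "N_vitripennis": 0.30,
        "D_melanogaster": 0.18,
    }
    probs = {}
    for sp, p in base.items():
        probs[sp] = {
            "methylated_spliced": min(1.0, 2.8 * p),
            "methylated_unspliced": min(1.0, 1.8 * p),
            "unmethylated_spliced": min(1.0, 1.4 * p),
            "unmethylated_unspliced": p,
        }
    return probs


class SizingError(ValueError):
    """Raised when the configured genes cannot fit on the chromosomes."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic genome, with study-scale defaults.

    Beta parameters are (alpha, beta); an alpha of 0 degenerates to a
    point mass at 0 (and beta 0 to a point mass at 1), used to force
    exactly-zero methylation contexts.  ``meth_length_scale`` and
    ``meth_exon_factor`` plant the longer-gene / more-exon structure of
    methylated genes by scaling their feature lengths and exon counts.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 4_000_000
    n_genes: int = 2000
    exons_min: int = 2
    exons_max: int = 8
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (100, 600)
    intergenic_gap: tuple[int, int] = (300, 1500)
    cpg_spacing: float = 60.0
    read_depth: float = 30.0
    meth_level_included: tuple[float, float] = (4.0, 6.0)
    meth_level_skipped: tuple[float, float] = (1.0, 19.0)
    meth_level_intron: tuple[float, float] = (1.0, 49.0)
    meth_level_intergenic: tuple[float, float] = (1.0, 99.0)
    frac_genes_methylated: float = 0.5
    frac_exons_skipped: float = 0.2
    frac_introns_skipped: float = 0.5
    expression_lognormal: tuple[float, float] = (1.0, 1.2)
    frac_genes_expressed: float = 0.7
    frac_genes_spliced: float = 0.3
    splicing_odds_ratio: float = 3.0
    meth_length_scale: float = 2.0
    meth_exon_factor: float = 1.5
    conservation_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_conservation_probs
    )
    conserved_evalue: float = 1e-200
    nonconserved_evalue: float = 1e-100
    frac_no_hit: float = 0.3
    skipped_rpkm_noise: float = 0.0

    def __post_init__(self) -> None:
        fracs = {
            "frac_genes_methylated": self.frac_genes_methylated,
            "frac_exons_skipped": self.frac_exons_skipped,
            "frac_introns_skipped": self.frac_introns_skipped,
            "frac_genes_expressed": self.frac_genes_expressed,
            "frac_genes_spliced": self.frac_genes_spliced,
            "frac_no_hit": self.frac_no_hit,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name in ("n_chromosomes", "chromosome_length", "n_genes", "exons_min", "exons_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("exon_length", "intron_length", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (min, max) pair")
        if self.exons_max < self.exons_min:
            raise ValueError("exons_max must be >= exons_min")
        if self.splicing_odds_ratio <= 0:
            raise ValueError("splicing_odds_ratio must be > 0")
        if self.cpg_spacing <= 0 or self.read_depth <= 0:
            raise ValueError("cpg_spacing and read_depth must be > 0")
        if self.meth_length_scale <= 0 or self.meth_exon_factor <= 0:
            raise ValueError("methylated-gene scale factors must be > 0")
        for beta_name in (
            "meth_level_included",
            "meth_level_skipped",
            "meth_level_intron",
            "meth_level_intergenic",
        ):
            a, b = getattr(self, beta_name)
            if a < 0 or b < 0 or (a == 0 and b == 0):
                raise ValueError(f"{beta_name} must be valid beta parameters")
        for sp, cats in self.conservation_probs.items():
            missing = set(CATEGORY_KEYS) - set(cats)
            if missing:
                raise ValueError(f"conservation_probs[{sp!r}] missing categories {sorted(missing)}")
            for key, p in cats.items():
                if key not in CATEGORY_KEYS:
                    raise ValueError(f"unknown conservation category {key!r} for {sp!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"conservation_probs[{sp!r}][{key!r}] not in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("exon_length", "intron_length", "intergenic_gap",
                    "meth_level_included", "meth_level_skipped",
                    "meth_level_intron", "meth_level_intergenic",
                    "expression_lognormal"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted labels for every simulated gene, exon, intron and site."""

    genes: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    sites: pd.DataFrame | None = None
    conservation: pd.DataFrame | None = None


def splicing_rates(config: SimulationConfig) -> tuple[float, float]:
    """Conditional splicing probabilities (methylated, unmethylated).

    Solved so that the marginal spliced fraction equals
    ``frac_genes_spliced`` while odds(p_meth)/odds(p_unmeth) equals the
    planted ``splicing_odds_ratio``.
    """
    p_m, s, o = config.frac_genes_methylated, config.frac_genes_spliced, config.splicing_odds_ratio
    if s in (0.0, 1.0) or o == 1.0:
        return s, s
    def gap(p0: float) -> float:
        p1 = o * p0 / (1 - p0 + o * p0)
        return p_m * p1 + (1 - p_m) * p0 - s
    p0 = brentq(gap, 1e-12, 1 - 1e-12)
    p1 = o * p0 / (1 - p0 + o * p0)
    return p1, p0


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def generate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Place non-overlapping multi-exon genes and plant all gene/exon labels.

    Returns the gene models together with the ground truth holding the
    planted per-gene methylated / spliced / expressed flags and the
    per-exon and per-intron inclusion labels.  Alternatively spliced
    genes get a second transcript missing one exon; all other genes have
    a single transcript.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    methylated = rng.random(n) < config.frac_genes_methylated
    p1, p0 = splicing_rates(config)
    spliced = rng.random(n) < np.where(methylated, p1, p0)
    expressed = rng.random(n) < config.frac_genes_expressed
    strand = np.where(rng.integers(0, 2, n) == 0, "+", "-")

    n_ex = rng.integers(config.exons_min, config.exons_max + 1, n)
    if config.meth_exon_factor != 1.0:
        n_ex = np.where(
            methylated,
            np.maximum(1, np.rint(n_ex * config.meth_exon_factor).astype(np.int64)),
            n_ex,
        )
    n_ex = np.where(spliced, np.maximum(n_ex, 2), n_ex)
    n_in = n_ex - 1

    scale = np.where(methylated, config.meth_length_scale, 1.0)
    exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, int(n_ex.sum()))
    exon_lens = np.maximum(1, np.rint(exon_lens * np.repeat(scale, n_ex)).astype(np.int64))
    intron_lens = rng.integers(
        config.intron_length[0], config.intron_length[1] + 1, int(n_in.sum())
    )
    intron_lens = np.maximum(1, np.rint(intron_lens * np.repeat(scale, n_in)).astype(np.int64))
    gaps = rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1, n)

    exon_skip = rng.random(int(n_ex.sum())) < config.frac_exons_skipped
    intron_skip = rng.random(int(n_in.sum())) < config.frac_introns_skipped
    drop_pick = rng.random(n)  # fractional position of the dropped exon in AS genes

    ex_off = np.concatenate([[0], np.cumsum(n_ex)])
    in_off = np.concatenate([[0], np.cumsum(n_in)])

    models: list[GeneModel] = []
    gene_rows, exon_rows, intron_rows = [], [], []
    chrom_i, cursor = 0, 0
    width = len(str(n))
    for i in range(n):
        lens_e = exon_lens[ex_off[i]:ex_off[i + 1]]
        lens_i = intron_lens[in_off[i]:in_off[i + 1]]
        glen = int(lens_e.sum() + lens_i.sum())
        start = cursor + int(gaps[i])
        while start + glen > config.chromosome_length:
            chrom_i += 1
            if chrom_i >= config.n_chromosomes:
                raise SizingError(
                    f"gene {i + 1}/{n} does not fit: increase chromosome_length "
                    f"or n_chromosomes, or reduce gene sizes"
                )
            cursor = 0
            start = int(gaps[i])
        chrom = f"chr{chrom_i + 1}"
        # alternate exon/intron blocks from the gene start
        exons = []
        pos = start
        for k, le in enumerate(lens_e):
            exons.append((pos, pos + int(le)))
            pos += int(le)
            if k < len(lens_i):
                pos += int(lens_i[k])
        end = pos
        cursor = end

        gid = f"g{i + 1:0{width}d}"
        t1 = Transcript(f"{gid}.t1", gid, tuple(exons))
        transcripts = [t1]
        if spliced[i]:
            drop = int(drop_pick[i] * len(exons))
            kept = tuple(iv for k, iv in enumerate(exons) if k != drop)
            transcripts.append(Transcript(f"{gid}.t2", gid, kept))
        models.append(GeneModel(gid, chrom, str(strand[i]), tuple(transcripts)))

        gene_rows.append(
            (gid, chrom, start, end, str(strand[i]),
             bool(methylated[i]), bool(spliced[i]), bool(expressed[i]),
             end - start, len(exons))
        )
        for k, (s_, e_) in enumerate(exons):
            skip = bool(exon_skip[ex_off[i] + k])
            exon_rows.append(
                (f"{gid}.e{k + 1}", gid, chrom, s_, e_, skip,
                 bool(expressed[i]) and not skip)
            )
        for k, ((_, e0), (s1, _)) in enumerate(zip(exons, exons[1:])):
            skip = bool(intron_skip[in_off[i] + k])
            intron_rows.append(
                (f"{gid}.i{k + 1}", gid, chrom, e0, s1, skip,
                 bool(expressed[i]) and not skip)
            )

    cols_feat = ["chrom", "start", "end", "skipped", "included"]
    truth = GroundTruth(
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "start", "end", "strand", "methylated",
                     "spliced", "expressed", "gene_length_bp", "n_exons"],
        ),
        exons=pd.DataFrame(exon_rows, columns=["exon_id", "gene_id"] + cols_feat),
        introns=pd.DataFrame(intron_rows, columns=["intron_id", "gene_id"] + cols_feat),
    )
    return models, truth


def _draw_levels(rng: np.random.Generator, params: tuple[float, float], size: int) -> np.ndarray:
    a, b = params
    if size == 0:
        return np.zeros(0)
    if a == 0:
        return np.zeros(size)
    if b == 0:
        return np.ones(size)
    return rng.beta(a, b, size)


def generate_methylation(
    models: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the per-CpG methylation-call table.

    CpG sites are laid down as a Poisson process with mean spacing
    ``cpg_spacing`` along every chromosome.  Each site's true level is a
    Beta draw for its genomic context — the context of an exonic site
    follows the exon's planted skip label, introns and intergenic space
    have their own families — and is forced to exactly 0 inside genes
    planted unmethylated.  Read counts are Binomial(depth, level) with
    Poisson depth; zero-depth sites are unobserved and dropped.

    Returns (calls, site_truth): calls has columns (chrom, pos,
    meth_reads, unmeth_reads); site_truth adds the true level, the
    context label and the owning gene.
    """
    rng = _rng(config, 2)
    n_chrom_used = max(int(m.chrom[3:]) for m in models) if models else config.n_chromosomes

    # disjoint labelled intervals: exons (context by planted skip), introns
    feat = pd.concat(
        [
            truth.exons.assign(code=np.where(truth.exons["skipped"], 2, 1)),
            truth.introns.assign(code=3),
        ],
        ignore_index=True,
    )
    meth_by_gene = truth.genes.set_index("gene_id")["methylated"]
    feat["gene_methylated"] = feat["gene_id"].map(meth_by_gene).to_numpy()

    frames_calls, frames_truth = [], []
    context_names = {0: "intergenic", 1: "included_exon", 2: "skipped_exon", 3: "intron"}
    for ci in range(n_chrom_used):
        chrom = f"chr{ci + 1}"
        L = config.chromosome_length
        est = int(1.3 * L / config.cpg_spacing) + 100
        gaps = np.maximum(1, rng.exponential(config.cpg_spacing, est).astype(np.int64))
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] < L:
            more = np.maximum(1, rng.exponential(config.cpg_spacing, 1000).astype(np.int64))
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        pos = pos[pos < L]

        sub = feat[feat["chrom"] == chrom].sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        codes = sub["code"].to_numpy(dtype=np.int64)
        gmeth = sub["gene_methylated"].to_numpy(dtype=bool)
        gids = sub["gene_id"].to_numpy()

        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, max(len(ends) - 1, 0))]) if len(ends) else np.zeros(pos.size, bool)
        code = np.zeros(pos.size, dtype=np.int64)
        site_gene = np.full(pos.size, "", dtype=object)
        site_gmeth = np.zeros(pos.size, dtype=bool)
        if len(ends):
            code[inside] = codes[idx[inside]]
            site_gene[inside] = gids[idx[inside]]
            site_gmeth[inside] = gmeth[idx[inside]]

        level = np.empty(pos.size)
        for c, params in (
            (0, config.meth_level_intergenic),
            (1, config.meth_level_included),
            (2, config.meth_level_skipped),
            (3, config.meth_level_intron),
        ):
            mask = code == c
            level[mask] = _draw_levels(rng, params, int(mask.sum()))
        level[inside & ~site_gmeth] = 0.0  # genes planted unmethylated

        depth = rng.poisson(config.read_depth, pos.size)
        keep = depth > 0
        meth = rng.binomial(depth[keep], level[keep])
        frames_calls.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "meth_reads": meth,
                    "unmeth_reads": depth[keep] - meth,
                }
            )
        )
        frames_truth.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "true_level": level[keep],
                    "context": pd.Series(code[keep]).map(context_names).to_numpy(),
                    "gene_id": site_gene[keep],
                }
            )
        )
    calls = pd.concat(frames_calls, ignore_index=True)
    site_truth = pd.concat(frames_truth, ignore_index=True)
    return calls, site_truth


def generate_expression(
    models: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate transcript FPKM and exon/intron RPKM tables.

    Every transcript of an expressed gene gets a lognormal FPKM;
    unexpressed genes get 0 for all transcripts.  Included exons/introns
    of expressed genes get a strictly positive lognormal RPKM; skipped
    (or unexpressed-gene) features get exactly 0, plus optional uniform
    noise below ``skipped_rpkm_noise`` when that switch is on.

    Returns one long table with columns (feature_id, feature_type,
    gene_id, value).
    """
    rng = _rng(config, 3)
    mu, sigma = config.expression_lognormal
    expressed = truth.genes.set_index("gene_id")["expressed"]

    tr_rows = [(t.transcript_id, m.gene_id) for m in models for t in m.transcripts]
    tr = pd.DataFrame(tr_rows, columns=["feature_id", "gene_id"])
    tr_expr = tr["gene_id"].map(expressed).to_numpy(dtype=bool)
    tr_val = np.where(tr_expr, rng.lognormal(mu, sigma, len(tr)), 0.0)

    def feature_values(df: pd.DataFrame) -> np.ndarray:
        inc = df["included"].to_numpy(dtype=bool)
        vals = np.where(inc, rng.lognormal(mu, sigma, len(df)), 0.0)
        if config.skipped_rpkm_noise > 0:
            noise = rng.uniform(0.0, config.skipped_rpkm_noise, len(df))
            vals = np.where(inc, vals, noise)
        return vals

    ex_val = feature_values(truth.exons)
    in_val = feature_values(truth.introns)

    out = pd.concat(
        [
            pd.DataFrame(
                {"feature_id": tr["feature_id"], "feature_type": "transcript",
                 "gene_id": tr["gene_id"], "value": tr_val}
            ),
            pd.DataFrame(
                {"feature_id": truth.exons["exon_id"], "feature_type": "exon",
                 "gene_id": truth.exons["gene_id"], "value": ex_val}
            ),
            pd.DataFrame(
                {"feature_id": truth.introns["intron_id"], "feature_type": "intron",
                 "gene_id": truth.introns["gene_id"], "value": in_val}
            ),
        ],
        ignore_index=True,
    )
    return out


def generate_conservation(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the per-(gene, species) best-hit E-value table.

    Each gene is conserved in each species with the probability of its
    planted (methylated, spliced) category.  Conserved genes get
    ``conserved_evalue`` (below the threshold), non-conserved genes get
    ``nonconserved_evalue``; a fraction ``frac_no_hit`` of non-conserved
    genes is omitted from the table (no hit at all).

    Returns (evalue_table, conservation_truth).
    """
    rng = _rng(config, 4)
    genes = truth.genes
    cat = np.where(
        genes["methylated"],
        np.where(genes["spliced"], "methylated_spliced", "methylated_unspliced"),
        np.where(genes["spliced"], "unmethylated_spliced", "unmethylated_unspliced"),
    )
    rows, truth_rows = [], []
    for sp in config.conservation_probs:
        p = np.array([config.conservation_probs[sp][c] for c in cat])
        conserved = rng.random(len(genes)) < p
        nohit = (~conserved) & (rng.random(len(genes)) < config.frac_no_hit)
        ev = np.where(conserved, config.conserved_evalue, config.nonconserved_evalue)
        for gid, cons, nh, e in zip(genes["gene_id"], conserved, nohit, ev):
            truth_rows.append((gid, sp, bool(cons)))
            if not nh:
                rows.append((gid, sp, float(e)))
    table = pd.DataFrame(rows, columns=["gene_id", "species", "evalue"])
    cons_truth = pd.DataFrame(truth_rows, columns=["gene_id", "species", "conserved"])
    return table, cons_truth


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed, gene/mRNA/exon)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tsim\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for t in m.transcripts:
                fh.write(
                    f"{m.chrom}\tsim\tmRNA\t{t.start + 1}\t{t.end}\t.\t{m.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={m.gene_id}\n"
                )
                for k, (s, e) in enumerate(t.exons):
                    fh.write(
                        f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={t.transcript_id}.ex{k + 1};Parent={t.transcript_id}\n"
                    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all four generators and write a complete input bundle.

    Writes annotation.gff3, methylation.tsv, expression.tsv,
    conservation.tsv, the ground-truth sidecar TSVs and the serialized
    config; returns the path of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, truth = generate_annotation(config)
    calls, site_truth = generate_methylation(models, truth, config)
    expr = generate_expression(models, truth, config)
    cons_table, cons_truth = generate_conservation(truth, config)
    truth.sites = site_truth
    truth.conservation = cons_truth

    paths = {
        "config": outdir / "config.json",
        "annotation": outdir / "annotation.gff3",
        "methylation": outdir / "methylation.tsv",
        "expression": outdir / "expression.tsv",
        "conservation": outdir / "conservation.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_exons": outdir / "truth_exons.tsv",
        "truth_introns": outdir / "truth_introns.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_conservation": outdir / "truth_conservation.tsv",
    }
    paths["config"].write_text(config.to_json() + "\n")
    write_gff3(models, paths["annotation"])
    _write_tsv(calls, paths["methylation"])
    _write_tsv(expr, paths["expression"])
    _write_tsv(cons_table, paths["conservation"])
    _write_tsv(truth.genes, paths["truth_genes"])
    _write_tsv(truth.exons, paths["truth_exons"])
    _write_tsv(truth.introns, paths["truth_introns"])
    _write_tsv(site_truth, paths["truth_sites"])
    _write_tsv(cons_truth, paths["truth_conservation"])
    return paths
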