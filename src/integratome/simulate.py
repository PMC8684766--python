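"""Seeded synthetic two-group, two-tissue studies with recorded ground truth.

The generator emulates the study design the pipeline targets: a small
surgical cohort (12 case / 13 control individuals, each contributing a
subcutaneous and a visceral adipose sample), array-style methylation beta
values, log-scale bulk expression, a scale-free tissue-specific regulatory
network, a labeled TF binding-site catalogue, and external validation gene
sets.  Planted effects — promoter-hypermethylated and downregulated module
genes wired as a dense subnetwork, multi-probe DMRs, binding-site
methylation shifts, ordinary DEGs — are recorded in a :class:`GroundTruth`
object sufficient to score recall/precision of every detection stage.

Methylation noise is applied on the logit scale (keeps betas in range and
variance realistic near the extremes); expression noise is normal on the
log2 scale.  Everything is deterministic per seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffmeth import m_to_beta
from .io import (
    BetaMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    IntervalSet,
    ProbeAnnotation,
    SampleSheet,
    write_bed,
    write_gmt,
    write_matrix,
    write_network,
    write_probe_annotation,
)

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "StudyData",
    "generate_network",
    "generate_methylome",
    "generate_transcriptome",
    "generate_study_data",
    "generate_study",
]


@dataclass(frozen=True)
class StudyConfig:
    """Defaults mirror the target study design at desk scale.

    12 case / 13 control individuals with one sample per tissue each;
    300 genes with 5-20 probes per gene plus intergenic probes.  Effect
    sizes: promoter delta-beta +0.15 with log2 fold change -1 for the
    planted module, +/-0.2 delta-beta five-probe DMRs, +0.15 delta-beta
    binding-site shifts, |lfc| = 1 for ordinary DEGs.
    """

    n_case: int = 12
    n_control: int = 13
    tissues: tuple = ("SAT", "VAT")
    n_genes: int = 300
    probes_per_gene: tuple = (5, 20)
    intergenic_probes: int = 100
    attachment: int = 2
    module_size: int = 8
    module_genes: tuple | None = None  # explicit plant; validated against genes
    module_delta_beta: float = 0.15
    module_lfc: float = -1.0
    n_de_genes: int = 30
    de_lfc: float = 1.0
    n_dmr_common: int = 1
    n_dmr_specific: int = 1  # per tissue
    dmr_probes: int = 5
    dmr_delta_beta: float = 0.2
    n_tfs: int = 20
    probes_per_tf: int = 60
    n_shifted_tfs: int = 2
    tfbs_delta_beta: float = 0.15
    expr_sigma: float = 0.5
    meth_logit_sd: float = 0.35
    validation_fraction: float = 0.75
    validation_set_size: int = 30


@dataclass
class GroundTruth:
    """Planted effects, serialized alongside the generated study."""

    seed: int
    module_genes: dict = field(default_factory=dict)  # tissue -> [gene]
    dmr_intervals: dict = field(default_factory=dict)  # tissue -> [dict]
    shifted_tfs: list = field(default_factory=list)
    de_genes: dict = field(default_factory=dict)  # gene -> lfc
    dm_probes: dict = field(default_factory=dict)  # tissue -> {probe: delta}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StudyData:
    """In-memory study bundle (what :func:`generate_study` writes to disk)."""

    config: StudyConfig
    sheet: SampleSheet
    annotation: ProbeAnnotation
    beta: dict  # tissue -> BetaMatrix
    expression: dict  # tissue -> ExpressionMatrix
    network: dict  # tissue -> nx.Graph
    tfbs: IntervalSet
    cgi: IntervalSet
    genesets: list  # [GeneSetCollection]
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_network(
    n_genes: int,
    attachment_parameter: int = 2,
    seed: int = 0,
    clique: tuple = (),
) -> nx.Graph:
    """Connected preferential-attachment (scale-free) gene network.

    ``clique`` genes, if given, are additionally wired into a dense planted
    subnetwork (modules are densely interconnected gene sets).
    Deterministic per seed.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    genes = _gene_names(n_genes)
    ba = nx.barabasi_albert_graph(n_genes, attachment_parameter, seed=seed)
    graph = nx.relabel_nodes(ba, dict(enumerate(genes)))
    unknown = set(clique) - set(genes)
    if unknown:
        raise ValueError(f"planted module genes not in network: {sorted(unknown)}")
    for i, a in enumerate(clique):
        for b in list(clique)[i + 1 :]:
            graph.add_edge(a, b)
    return graph


def _generate_annotation(cfg: StudyConfig, rng: np.random.Generator, dmr_genes):
    """Probe layout: per-gene promoter cluster plus gene-body probes.

    Promoter probes sit within 1.5 kb upstream of the TSS at 150 bp spacing
    (one genomic cluster per gene at the default 1 kb gap); body probes start
    2.5 kb downstream so they never merge with the promoter cluster.  Genes
    carrying a planted DMR get exactly ``cfg.dmr_probes`` promoter probes so
    the planted region is a whole cluster.
    """
    genes = _gene_names(cfg.n_genes)
    dmr_genes = set(dmr_genes)
    rows = []
    promoter: dict[str, list] = {}
    probe_no = 0
    for i, gene in enumerate(genes):
        chrom = f"chr{(i % 22) + 1}"
        tss = 50_000 + (i // 22) * 100_000
        lo, hi = cfg.probes_per_gene
        total = int(rng.integers(lo, hi + 1))
        n_prom = cfg.dmr_probes if gene in dmr_genes else int(rng.integers(3, 7))
        n_prom = min(n_prom, total) if total >= 3 else total
        promoter[gene] = []
        for j in range(n_prom):
            pid = f"cg{probe_no:06d}"
            probe_no += 1
            pos = tss - 1500 + 150 * j
            rc = ("TSS1500", "TSS200", "5UTR")[int(rng.integers(0, 3))]
            rows.append((pid, chrom, pos, gene, rc, "island"))
            promoter[gene].append(pid)
        for j in range(max(total - n_prom, 0)):
            pid = f"cg{probe_no:06d}"
            probe_no += 1
            pos = tss + 2_500 + 800 * j
            rc = "body" if j < max(total - n_prom, 1) - 1 else "3UTR"
            cgi = ("shore", "shelf", "open_sea")[int(rng.integers(0, 3))]
            rows.append((pid, chrom, pos, gene, rc, cgi))
    for j in range(cfg.intergenic_probes):
        pid = f"cg{probe_no:06d}"
        probe_no += 1
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = 10_000_000 + 5_000 * j
        rows.append((pid, chrom, pos, "", "intergenic", "open_sea"))
    frame = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene", "region_class", "cgi_relation"]
    ).set_index("probe_id")
    return ProbeAnnotation(frame), promoter


def _baseline_beta(annotation: ProbeAnnotation, rng: np.random.Generator) -> pd.Series:
    """Bimodal baseline methylation: low at islands, high elsewhere."""
    cgi = annotation.frame["cgi_relation"]
    mu = np.empty(len(cgi))
    island = (cgi == "island").to_numpy()
    shore = cgi.isin(["shore", "shelf"]).to_numpy()
    mu[island] = rng.uniform(0.05, 0.25, island.sum())
    mu[shore] = rng.uniform(0.25, 0.6, shore.sum())
    rest = ~(island | shore)
    mu[rest] = rng.uniform(0.5, 0.9, rest.sum())
    return pd.Series(mu, index=annotation.frame.index)


def generate_methylome(
    annotation: ProbeAnnotation,
    sheet: SampleSheet,
    effects: dict,
    logit_sd: float = 0.35,
    baseline: pd.Series | None = None,
    seed: int = 0,
) -> BetaMatrix:
    """Beta-value matrix for all samples in ``sheet``.

    ``effects`` maps probe id -> case-group delta-beta (within (-0.5, 0.5)),
    added to the baseline mean before logit-scale noise; all betas are kept
    strictly inside (0, 1).
    """
    unknown = sorted(set(effects) - set(annotation.frame.index))
    if unknown:
        raise ValueError(f"planted effects reference unknown probes: {unknown[:5]}")
    bad = [p for p, d in effects.items() if not -0.5 < d < 0.5]
    if bad:
        raise ValueError(f"planted delta-beta outside (-0.5, 0.5): {bad[:5]}")
    rng = np.random.default_rng(seed)
    if baseline is None:
        baseline = _baseline_beta(annotation, rng)
    probes = annotation.frame.index
    mu = baseline.loc[probes].to_numpy()
    delta = np.array([effects.get(p, 0.0) for p in probes])
    is_case = np.array([g == "case" for g in sheet.frame["group"]])
    mu_mat = mu[:, None] + np.where(is_case[None, :], delta[:, None], 0.0)
    mu_mat = np.clip(mu_mat, 0.02, 0.98)
    logit = np.log2(mu_mat / (1.0 - mu_mat))
    noisy = logit + rng.normal(0.0, logit_sd, mu_mat.shape)
    beta = m_to_beta(noisy)
    beta = np.clip(beta, 1e-4, 1 - 1e-4)
    return BetaMatrix(
        pd.DataFrame(beta, index=probes, columns=sheet.sample_ids)
    )


def generate_transcriptome(
    genes,
    sheet: SampleSheet,
    lfc: dict,
    sigma: float = 0.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Log2-scale expression matrix with planted case-group fold changes.

    Gene baselines are normal around log2 abundance 6 (log-normal on the
    natural scale); ``lfc`` maps gene -> log2 fold change applied to case
    samples.  Deterministic per seed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    baseline = rng.normal(6.0, 1.5, len(genes))
    shift = np.array([lfc.get(g, 0.0) for g in genes])
    is_case = np.array([g == "case" for g in sheet.frame["group"]])
    vals = (
        baseline[:, None]
        + np.where(is_case[None, :], shift[:, None], 0.0)
        + rng.normal(0.0, sigma, (len(genes), len(is_case)))
    )
    vals = np.clip(vals, 0.0, None)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=sheet.sample_ids)
    )


def _make_sheet(cfg: StudyConfig) -> SampleSheet:
    rows = []
    for i in range(cfg.n_case + cfg.n_control):
        pid = f"P{i + 1:02d}"
        group = "case" if i < cfg.n_case else "control"
        for tissue in cfg.tissues:
            rows.append((f"{pid}_{tissue}", group, tissue))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "group", "tissue"]))


def generate_study_data(cfg: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate a complete in-memory study with planted ground truth."""
    cfg = cfg or StudyConfig()
    genes = _gene_names(cfg.n_genes)
    layout_rng = np.random.default_rng([seed, 0])
    sheet = _make_sheet(cfg)

    # --- choose planted entities (disjoint gene pools) -------------------
    pool = list(genes)
    layout_rng.shuffle(pool)
    if cfg.module_genes is not None:
        module_genes = sorted(cfg.module_genes)
        unknown = set(module_genes) - set(genes)
        if unknown:
            raise ValueError(f"module genes not in gene universe: {sorted(unknown)}")
        pool = [g for g in pool if g not in set(module_genes)]
    else:
        module_genes = sorted(pool[: cfg.module_size])
        pool = pool[cfg.module_size:]
    n_spec = cfg.n_dmr_specific * len(cfg.tissues)
    dmr_common = sorted(pool[: cfg.n_dmr_common])
    pool = pool[cfg.n_dmr_common:]
    dmr_specific = {}
    for tissue in cfg.tissues:
        dmr_specific[tissue] = sorted(pool[: cfg.n_dmr_specific])
        pool = pool[cfg.n_dmr_specific:]
    de_genes = sorted(pool[: cfg.n_de_genes])
    pool = pool[cfg.n_de_genes:]
    de_lfc = {
        g: cfg.de_lfc * (1 if i % 2 == 0 else -1) for i, g in enumerate(de_genes)
    }
    all_dmr_genes = set(dmr_common) | {g for gs in dmr_specific.values() for g in gs}

    # --- annotation, baselines, intervals --------------------------------
    annotation, promoter = _generate_annotation(cfg, layout_rng, all_dmr_genes)
    baseline = _baseline_beta(annotation, np.random.default_rng([seed, 4]))
    # planted DMR probes get an intermediate baseline so +/- shifts fit in range
    for g in all_dmr_genes:
        baseline.loc[promoter[g]] = 0.45

    # TF binding sites: shifted TFs get dedicated probes outside other plants
    ann = annotation.frame
    planted_promoters = {
        p for g in (set(module_genes) | all_dmr_genes) for p in promoter[g]
    }
    eligible = [
        p
        for p in ann.index
        if p not in planted_promoters
        and ann.loc[p, "region_class"] in ("body", "3UTR", "intergenic")
    ]
    layout_rng.shuffle(eligible)
    tf_names = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    shifted_tfs = tf_names[: cfg.n_shifted_tfs]
    tf_probes: dict[str, list] = {}
    k = 0
    for tf in shifted_tfs:
        tf_probes[tf] = sorted(eligible[k : k + cfg.probes_per_tf])
        k += cfg.probes_per_tf
    remaining = eligible[k:]
    for tf in tf_names[cfg.n_shifted_tfs:]:
        idx = layout_rng.choice(len(remaining), size=min(cfg.probes_per_tf, len(remaining)), replace=False)
        tf_probes[tf] = sorted(remaining[i] for i in idx)
    bed_rows = []
    for tf in tf_names:
        for p in tf_probes[tf]:
            pos0 = int(ann.loc[p, "pos"]) - 1
            bed_rows.append((ann.loc[p, "chrom"], pos0 - 5, pos0 + 6, tf))
    tfbs = IntervalSet(
        "tfbs", pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "label"])
    )
    cgi_rows = []
    for i, gene in enumerate(genes):
        chrom = f"chr{(i % 22) + 1}"
        tss = 50_000 + (i // 22) * 100_000
        cgi_rows.append((chrom, tss - 1_600, tss + 100, ""))
    cgi = IntervalSet(
        "cpg_islands", pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "label"])
    )

    # --- per-tissue planted methylation effects --------------------------
    dm_probes: dict[str, dict] = {}
    dmr_intervals: dict[str, list] = {}
    for tissue in cfg.tissues:
        eff: dict[str, float] = {}
        for g in module_genes:
            for p in promoter[g]:
                eff[p] = cfg.module_delta_beta
        intervals = []
        for g in dmr_common:
            for p in promoter[g]:
                eff[p] = -cfg.dmr_delta_beta  # shared hypomethylated region
            intervals.append(_dmr_record(annotation, promoter[g], g, -cfg.dmr_delta_beta))
        for g in dmr_specific[tissue]:
            for p in promoter[g]:
                eff[p] = cfg.dmr_delta_beta
            intervals.append(_dmr_record(annotation, promoter[g], g, cfg.dmr_delta_beta))
        for tf in shifted_tfs:
            for p in tf_probes[tf]:
                eff[p] = cfg.tfbs_delta_beta
        dm_probes[tissue] = eff
        dmr_intervals[tissue] = intervals

    # --- matrices and networks -------------------------------------------
    beta = {}
    expression = {}
    network = {}
    lfc = dict(de_lfc)
    for g in module_genes:
        lfc[g] = cfg.module_lfc
    for ti, tissue in enumerate(cfg.tissues):
        tsheet = sheet.for_tissue(tissue)
        beta[tissue] = generate_methylome(
            annotation,
            tsheet,
            dm_probes[tissue],
            logit_sd=cfg.meth_logit_sd,
            baseline=baseline,
            seed=int(np.random.default_rng([seed, 1, ti]).integers(2**31)),
        )
        expression[tissue] = generate_transcriptome(
            genes,
            tsheet,
            lfc,
            sigma=cfg.expr_sigma,
            seed=int(np.random.default_rng([seed, 2, ti]).integers(2**31)),
        )
        network[tissue] = generate_network(
            cfg.n_genes,
            cfg.attachment,
            seed=seed * 101 + ti,
            clique=tuple(module_genes),
        )

    # --- validation gene sets --------------------------------------------
    gmt_rng = np.random.default_rng([seed, 3])
    planted_pool = sorted(set(module_genes) | all_dmr_genes | set(de_genes))
    other = [g for g in genes if g not in set(planted_pool)]
    genesets = []
    for cat in ("comorbidity", "druggability", "eQTL", "GWAS", "TFBS", "TF", "T2Di"):
        size = cfg.validation_set_size
        n_planted = round(cfg.validation_fraction * size)
        chosen = [
            str(g)
            for g in gmt_rng.choice(
                planted_pool, size=min(n_planted, len(planted_pool)), replace=False
            )
        ]
        fill = [
            str(g)
            for g in gmt_rng.choice(
                other, size=min(size - len(chosen), len(other)), replace=False
            )
        ]
        genesets.append(
            GeneSetCollection(sets={f"{cat}_set": frozenset(chosen + fill)}, category=cat)
        )

    truth = GroundTruth(
        seed=seed,
        module_genes={t: list(module_genes) for t in cfg.tissues},
        dmr_intervals=dmr_intervals,
        shifted_tfs=list(shifted_tfs),
        de_genes=lfc,
        dm_probes=dm_probes,
    )
    return StudyData(
        config=cfg,
        sheet=sheet,
        annotation=annotation,
        beta=beta,
        expression=expression,
        network=network,
        tfbs=tfbs,
        cgi=cgi,
        genesets=genesets,
        truth=truth,
    )


def _dmr_record(annotation, probe_ids, gene, delta):
    sub = annotation.frame.loc[probe_ids]
    return {
        "chrom": str(sub["chrom"].iloc[0]),
        "start": int(sub["pos"].min()),
        "end": int(sub["pos"].max()),
        "gene": gene,
        "delta_beta": float(delta),
        "probes": list(probe_ids),
    }


def generate_study(cfg: StudyConfig | None = None, seed: int = 0, outdir=".") -> dict:
    """Write a complete study to ``outdir``; returns the path map.

    Emits the sample sheet (with study-style group tokens), per-tissue beta
    and expression matrices, the probe annotation, per-tissue networks, the
    TFBS and CpG-island BEDs, seven validation GMTs, the ground-truth JSON,
    and a ready-to-run ``run_config.yaml``.
    """
    from .pipeline import write_default_run_config  # local import: no cycle at module load

    data = generate_study_data(cfg, seed)
    cfg = data.config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    sheet_frame = data.sheet.frame.copy()
    sheet_frame["group"] = sheet_frame["group"].map({"case": "T2D", "control": "control"})
    sheet_path = out / "samples.csv"
    sheet_frame.to_csv(sheet_path, index=False)
    paths["sample_sheet"] = sheet_path

    ann_path = out / "probe_annotation.csv"
    write_probe_annotation(data.annotation, ann_path)
    paths["annotation"] = ann_path

    paths["beta"], paths["expression"], paths["network"] = {}, {}, {}
    for tissue in cfg.tissues:
        paths["beta"][tissue] = out / f"beta_{tissue}.tsv"
        write_matrix(data.beta[tissue], paths["beta"][tissue])
        paths["expression"][tissue] = out / f"expr_{tissue}.tsv"
        write_matrix(data.expression[tissue], paths["expression"][tissue])
        paths["network"][tissue] = out / f"network_{tissue}.tsv"
        write_network(data.network[tissue], paths["network"][tissue])

    paths["tfbs"] = out / "tfbs.bed"
    write_bed(data.tfbs, paths["tfbs"])
    paths["cgi"] = out / "cgi.bed"
    write_bed(data.cgi, paths["cgi"])

    paths["genesets"] = {}
    for coll in data.genesets:
        p = out / f"genesets_{coll.category}.gmt"
        write_gmt(coll, p)
        paths["genesets"][coll.category] = p

    paths["truth"] = out / "truth.json"
    data.truth.to_json(paths["truth"])

    paths["run_config"] = write_default_run_config(out, cfg, seed)
    return paths
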