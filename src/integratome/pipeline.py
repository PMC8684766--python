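"""Stage orchestration: run the per-tissue analyses and cross-tissue
integration from a single YAML run configuration.

Every stage reads plain files and writes plain files (TSV/JSON/BED-style),
so stages are independently re-runnable and the CLI subcommands compose.
One global seed determines every stochastic stage; per-stage seeds are
derived deterministically from it and recorded in the run manifest together
with a frozen copy of all parameters and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import biomarkers as bm
from . import diffexpr, diffmeth, dmr as dmr_mod, modules as mod, tfbs as tfbs_mod
from .io import (
    read_bed,
    read_gmt,
    read_matrix,
    read_network,
    read_probe_annotation,
    read_sample_sheet,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "write_default_run_config",
           "stage_de", "stage_dm", "stage_dmr", "stage_tfbs", "stage_modules",
           "stage_validate"]

FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    sample_sheet: str
    annotation: str
    beta: dict
    expression: dict
    network: dict
    tfbs: str
    genesets: dict = field(default_factory=dict)  # category -> path
    features: str | None = None  # e.g. CpG islands BED for context profiles
    outdir: str = "results"
    tissues: tuple = ("SAT", "VAT")
    seed: int = 0
    q_threshold: float = 0.1
    dmr_max_gap: int = 1000
    dmr_min_probes: int = 3
    dmr_min_abs_delta: float = 0.05
    dmr_B: int = 1000
    tfbs_min_probes: int = 10
    tfbs_test: str = "ks"
    module_n_seeds: int = 10
    module_min_size: int = 4
    module_max_size: int = 50
    module_B: int = 999
    context_bins: tuple = (-5000, -2000, -500, 0, 1, 500, 2000, 5000)

    def __post_init__(self) -> None:
        self.tissues = tuple(self.tissues)
        self.context_bins = tuple(self.context_bins)

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=True)

    def validate_paths(self) -> None:
        paths = [self.sample_sheet, self.annotation, self.tfbs]
        for t in self.tissues:
            paths += [self.beta[t], self.expression[t], self.network[t]]
        if self.features:
            paths.append(self.features)
        paths += list(self.genesets.values())
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise StageError(f"missing input files: {missing}")

    def out(self, name: str) -> Path:
        return Path(self.outdir) / name


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _require(config: RunConfig, names: list, needed_by: str, produced_by: str) -> None:
    missing = [n for n in names if not config.out(n).exists()]
    if missing:
        raise StageError(
            f"stage {needed_by!r} requires outputs of stage {produced_by!r} "
            f"(missing: {missing}); run {produced_by!r} first"
        )


def _stage_seed(config: RunConfig, offset: int, tissue_index: int = 0) -> int:
    return int(
        np.random.default_rng([config.seed, offset, tissue_index]).integers(2**31)
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_de(config: RunConfig) -> dict:
    """Differential expression per tissue -> de_{tissue}.tsv."""
    sheet = read_sample_sheet(config.sample_sheet)
    out = {}
    for tissue in config.tissues:
        expr = read_matrix(config.expression[tissue], "expression")
        stats = diffexpr.moderated_t(expr, sheet, tissue)
        _write(stats, config.out(f"de_{tissue}.tsv"))
        out[tissue] = stats
    return out


def stage_dm(config: RunConfig) -> dict:
    """Probe and promoter-level methylation statistics, context profiles."""
    sheet = read_sample_sheet(config.sample_sheet)
    annotation = read_probe_annotation(config.annotation)
    features = read_bed(config.features, "features") if config.features else None
    out = {}
    for tissue in config.tissues:
        beta = read_matrix(config.beta[tissue], "beta")
        probe_stats = diffmeth.probe_differential(beta, sheet, tissue)
        _write(probe_stats, config.out(f"probe_stats_{tissue}.tsv"))
        gene_stats = diffmeth.summarize_gene_methylation(probe_stats, annotation)
        _write(gene_stats, config.out(f"gene_meth_{tissue}.tsv"))
        if features is not None:
            profile = diffmeth.context_profile(
                beta, sheet, tissue, annotation, features, config.context_bins
            )
            _write(profile, config.out(f"context_{tissue}.tsv"), index=False)
        out[tissue] = probe_stats
    return out


def stage_dmr(config: RunConfig) -> dict:
    """Permutation-based DMR calling per tissue plus cross-tissue overlap."""
    _require(
        config,
        [f"probe_stats_{t}.tsv" for t in config.tissues],
        needed_by="dmr",
        produced_by="dm",
    )
    sheet = read_sample_sheet(config.sample_sheet)
    annotation = read_probe_annotation(config.annotation)
    called = {}
    for ti, tissue in enumerate(config.tissues):
        beta = read_matrix(config.beta[tissue], "beta")
        dmrs = dmr_mod.call_dmrs(
            beta,
            sheet,
            tissue,
            annotation,
            max_gap=config.dmr_max_gap,
            min_probes=config.dmr_min_probes,
            min_abs_delta=config.dmr_min_abs_delta,
            B=config.dmr_B,
            seed=_stage_seed(config, 10, ti),
            q_threshold=config.q_threshold,
        )
        _write(dmr_mod.dmrs_to_frame(dmrs), config.out(f"dmrs_{tissue}.tsv"), index=False)
        called[tissue] = dmrs
    if set(config.tissues) == {"SAT", "VAT"}:
        cmp_res = dmr_mod.compare_dmrs(called["SAT"], called["VAT"])
        rows = []
        for group in cmp_res["common"]:
            for d in group:
                rows.append(("common", d.chrom, d.start, d.end, d.direction))
        for key in ("sat_specific", "vat_specific"):
            for d in cmp_res[key]:
                rows.append((key, d.chrom, d.start, d.end, d.direction))
        _write(
            pd.DataFrame(rows, columns=["status", "chrom", "start", "end", "direction"]),
            config.out("dmr_comparison.tsv"),
            index=False,
        )
    return called


def stage_tfbs(config: RunConfig) -> dict:
    """Binding-site differential methylation per TF and concordance."""
    _require(
        config,
        [f"probe_stats_{t}.tsv" for t in config.tissues],
        needed_by="tfbs",
        produced_by="dm",
    )
    annotation = read_probe_annotation(config.annotation)
    catalogue = read_bed(config.tfbs, "tfbs")
    results = {}
    for tissue in config.tissues:
        probe_stats = pd.read_csv(
            config.out(f"probe_stats_{tissue}.tsv"), sep="\t", index_col=0
        )
        res = tfbs_mod.tfbs_differential(
            probe_stats,
            annotation,
            catalogue,
            min_probes=config.tfbs_min_probes,
            test=config.tfbs_test,
        )
        _write(res, config.out(f"tfbs_{tissue}.tsv"))
        results[tissue] = res
    if set(config.tissues) == {"SAT", "VAT"}:
        conc = tfbs_mod.tfbs_concordance(
            results["SAT"], results["VAT"], q_threshold=config.q_threshold
        )
        _write(conc, config.out("tfbs_concordance.tsv"))
    return results


def stage_modules(config: RunConfig) -> dict:
    """Weighted-network construction and module discovery per tissue."""
    _require(
        config,
        [f"de_{t}.tsv" for t in config.tissues],
        needed_by="modules",
        produced_by="de",
    )
    _require(
        config,
        [f"gene_meth_{t}.tsv" for t in config.tissues],
        needed_by="modules",
        produced_by="dm",
    )
    detected = {}
    for ti, tissue in enumerate(config.tissues):
        expr_stats = pd.read_csv(config.out(f"de_{tissue}.tsv"), sep="\t", index_col=0)
        meth_stats = pd.read_csv(
            config.out(f"gene_meth_{tissue}.tsv"), sep="\t", index_col=0
        )
        network = read_network(config.network[tissue])
        wnet = mod.integrate_statistics(meth_stats, expr_stats, network)
        mods = mod.detect_modules(
            wnet,
            n_seeds=config.module_n_seeds,
            min_size=config.module_min_size,
            max_size=config.module_max_size,
            B=config.module_B,
            q_threshold=config.q_threshold,
            seed=_stage_seed(config, 20, ti),
            tissue=tissue,
        )
        _write(mod.modules_to_frame(mods), config.out(f"modules_{tissue}.tsv"), index=False)
        edge_rows = []
        for i, m in enumerate(mods):
            sub = wnet.graph.subgraph(m.members)
            for u, v, data in sorted(sub.edges(data=True)):
                edge_rows.append((i, m.seed_gene, u, v, data["edge_w"]))
        _write(
            pd.DataFrame(
                edge_rows, columns=["module", "seed_gene", "gene1", "gene2", "edge_w"]
            ),
            config.out(f"module_edges_{tissue}.tsv"),
            index=False,
        )
        detected[tissue] = mods
    if set(config.tissues) == {"SAT", "VAT"}:
        shared = sorted(mod.shared_genes(detected["SAT"], detected["VAT"]))
        config.out("shared_genes.txt").write_text("\n".join(shared) + "\n")
    return detected


def _modules_from_file(path: Path) -> list:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, row in frame.iterrows():
        members = frozenset(str(row["members"]).split(",")) if row["n_genes"] else frozenset()
        out.append(SimpleNamespace(members=members, seed_gene=row["seed_gene"]))
    return out


def _dmrs_from_file(path: Path) -> list:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, row in frame.iterrows():
        genes = tuple(str(row["genes"]).split(",")) if pd.notna(row["genes"]) and row["genes"] else ()
        out.append(SimpleNamespace(genes=genes))
    return out


def stage_validate(config: RunConfig) -> dict:
    """Biomarker classification and external gene-set validation."""
    needed = [f"modules_{t}.tsv" for t in config.tissues] + [
        f"dmrs_{t}.tsv" for t in config.tissues
    ]
    _require(config, needed, needed_by="validate", produced_by="modules (and dmr)")
    collections = [
        read_gmt(path, category) for category, path in sorted(config.genesets.items())
    ]
    tables = []
    summaries = {}
    for tissue in config.tissues:
        modules = _modules_from_file(config.out(f"modules_{tissue}.tsv"))
        dmrs = _dmrs_from_file(config.out(f"dmrs_{tissue}.tsv"))
        expr_stats = pd.read_csv(config.out(f"de_{tissue}.tsv"), sep="\t", index_col=0)
        meth_stats = pd.read_csv(
            config.out(f"gene_meth_{tissue}.tsv"), sep="\t", index_col=0
        )
        network = read_network(config.network[tissue])
        table = bm.classify_biomarkers(
            modules,
            dmrs,
            expr_stats,
            meth_stats,
            network,
            q_threshold=config.q_threshold,
            tissue=tissue,
        )
        _write(table, config.out(f"biomarkers_{tissue}.tsv"))
        tables.append(table)
        if collections:
            summaries[tissue] = bm.validate_biomarkers(table, collections).to_dict()
    pooled = pd.concat(tables) if tables else pd.DataFrame()
    if len(pooled):
        dedup = pooled.groupby(level=0).agg(
            {
                "tissue": lambda s: "+".join(sorted(set(s))),
                "source": lambda s: "+".join(
                    sorted({tok for v in s for tok in str(v).split("+")})
                ),
                "class": lambda s: "t2d_biomarker" if "t2d_biomarker" in set(s) else s.iloc[0],
                "evidence": lambda s: sorted(set(s) - {"none"})[0] if set(s) - {"none"} else "none",
            }
        )
        _write(dedup, config.out("biomarkers_all.tsv"))
        if collections:
            summaries["pooled"] = bm.validate_biomarkers(dedup, collections).to_dict()
    if collections:
        with open(config.out("validation_summary.json"), "w") as fh:
            json.dump(_plain(summaries), fh, indent=1, sort_keys=True)
        rows = [
            (scope, s["n_biomarkers"], s["pct_validated_any"], s["pct_tf"])
            for scope, s in sorted(summaries.items())
        ]
        _write(
            pd.DataFrame(
                rows, columns=["scope", "n_biomarkers", "pct_validated_any", "pct_tf"]
            ),
            config.out("validation_summary.tsv"),
            index=False,
        )
    return summaries


_STAGES = [
    ("de", stage_de),
    ("dm", stage_dm),
    ("dmr", stage_dmr),
    ("tfbs", stage_tfbs),
    ("modules", stage_modules),
    ("validate", stage_validate),
]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order and write the run manifest.

    Returns the output directory.  Any stage error aborts with the stage
    name; a rerun with the same config and seed reproduces byte-identical
    statistic tables.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config_frozen.yaml")
    for name, fn in _STAGES:
        try:
            fn(config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    checksums = {}
    for path in sorted(outdir.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "seed": config.seed,
        "parameters": _plain(dataclasses.asdict(config)),
        "outputs": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def write_default_run_config(study_dir, cfg, seed: int) -> Path:
    """Emit a run_config.yaml pointing at a generated study's files."""
    study_dir = Path(study_dir)
    categories = ("comorbidity", "druggability", "eQTL", "GWAS", "TFBS", "TF", "T2Di")
    config = RunConfig(
        sample_sheet=str(study_dir / "samples.csv"),
        annotation=str(study_dir / "probe_annotation.csv"),
        beta={t: str(study_dir / f"beta_{t}.tsv") for t in cfg.tissues},
        expression={t: str(study_dir / f"expr_{t}.tsv") for t in cfg.tissues},
        network={t: str(study_dir / f"network_{t}.tsv") for t in cfg.tissues},
        tfbs=str(study_dir / "tfbs.bed"),
        features=str(study_dir / "cgi.bed"),
        genesets={c: str(study_dir / f"genesets_{c}.gmt") for c in categories},
        outdir=str(study_dir / "results"),
        tissues=tuple(cfg.tissues),
        seed=seed,
    )
    path = study_dir / "run_config.yaml"
    config.to_yaml(path)
    return path
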