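"""Biomarker classification and external gene-set validation.

Candidate biomarkers are the genes surfaced by module discovery and DMR
calling.  A gene with differential expression or methylation (FDR below the
threshold in either layer) is a disease ("T2D") biomarker; a candidate with
no differential signal of its own counts as a control biomarker only when it
interacts with a disease biomarker in the regulatory network, otherwise it
is dropped.  Validation is pure set overlap against externally supplied
gene-set collections (comorbidity, druggability, eQTL, GWAS, TFBS, TF,
T2Di); percentages are reported to one decimal place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["classify_biomarkers", "validate_biomarkers", "ValidationSummary"]


@dataclass(frozen=True)
class ValidationSummary:
    n_biomarkers: int
    category_hits: dict
    pct_validated_any: float
    pct_tf: float

    def to_dict(self) -> dict:
        return {
            "n_biomarkers": self.n_biomarkers,
            "category_hits": dict(self.category_hits),
            "pct_validated_any": self.pct_validated_any,
            "pct_tf": self.pct_tf,
        }


def classify_biomarkers(
    modules,
    dmrs,
    expr_stats: pd.DataFrame,
    meth_gene_stats: pd.DataFrame,
    network: nx.Graph,
    q_threshold: float = 0.1,
    tissue: str = "",
) -> pd.DataFrame:
    """Classify module/DMR genes into disease vs control biomarkers.

    Returns a frame indexed by gene with columns ``tissue``, ``source``
    (``module``, ``DMR`` or ``module+DMR``), ``class`` (``t2d_biomarker`` /
    ``control_biomarker``) and ``evidence`` (``expression``, ``methylation``,
    ``both``).  Candidates without evidence and without a differential
    network neighbor are dropped (logged).
    """
    module_genes: set = set()
    for m in modules:
        module_genes |= m.members
    dmr_genes: set = set()
    for d in dmrs:
        dmr_genes |= set(d.genes)
    candidates = module_genes | dmr_genes
    if not candidates:
        return pd.DataFrame(
            columns=["tissue", "source", "class", "evidence"]
        ).rename_axis("gene")

    def _sig(stats: pd.DataFrame, gene: str) -> bool:
        if gene not in stats.index:
            return False
        q = stats.loc[gene, "q"]
        return bool(pd.notna(q) and q < q_threshold)

    evidence = {}
    for gene in candidates:
        e_expr = _sig(expr_stats, gene)
        e_meth = _sig(meth_gene_stats, gene)
        if e_expr and e_meth:
            evidence[gene] = "both"
        elif e_expr:
            evidence[gene] = "expression"
        elif e_meth:
            evidence[gene] = "methylation"
        else:
            evidence[gene] = "none"

    t2d = {g for g in candidates if evidence[g] != "none"}
    rows = []
    for gene in sorted(candidates):
        source = (
            "module+DMR"
            if gene in module_genes and gene in dmr_genes
            else ("module" if gene in module_genes else "DMR")
        )
        if gene in t2d:
            rows.append((gene, tissue, source, "t2d_biomarker", evidence[gene]))
        else:
            neighbors = set(network.neighbors(gene)) if gene in network else set()
            if neighbors & t2d:
                rows.append((gene, tissue, source, "control_biomarker", "none"))
            else:
                logger.info(
                    "classify_biomarkers: %r has no differential signal and no "
                    "differential neighbor; dropped",
                    gene,
                )
    out = pd.DataFrame(
        rows, columns=["gene", "tissue", "source", "class", "evidence"]
    ).set_index("gene")
    # invariant: every control biomarker touches a disease biomarker
    for gene in out.index[out["class"] == "control_biomarker"]:
        assert set(network.neighbors(gene)) & t2d, gene
    return out


def validate_biomarkers(table: pd.DataFrame, collections) -> ValidationSummary:
    """Overlap biomarkers with external gene-set collections.

    A biomarker hits a category if it appears in any set of that category
    (counted once per category).  ``pct_validated_any`` is the percentage of
    biomarkers with at least one category hit; ``pct_tf`` the percentage
    present in the TF category.  Percentages are rounded to one decimal.
    """
    collections = list(collections)
    if not collections:
        raise ValueError("at least one gene-set collection is required")
    genes = list(table.index)
    n = len(genes)
    category_genes: dict[str, set] = {}
    for coll in collections:
        category_genes.setdefault(coll.category, set()).update(coll.all_genes())
    hits = {cat: sum(1 for g in genes if g in members)
            for cat, members in category_genes.items()}
    validated = sum(
        1 for g in genes if any(g in members for members in category_genes.values())
    )
    tf_members = category_genes.get("TF", set())
    n_tf = sum(1 for g in genes if g in tf_members)
    pct_any = round(100.0 * validated / n, 1) if n else 0.0
    pct_tf = round(100.0 * n_tf / n, 1) if n else 0.0
    return ValidationSummary(
        n_biomarkers=n,
        category_hits=hits,
        pct_validated_any=pct_any,
        pct_tf=pct_tf,
    )
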