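"""Probe-level differential methylation, promoter-level gene summaries, and
global methylation-context profiles.

Testing is done on M-values (logit2 of beta, a variance-stabilized scale)
while effect sizes are reported as delta-beta (difference of group mean
methylation fractions), the conventional compromise between power and
interpretability on methylation arrays.  The moderated-t engine is shared
with the expression analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffexpr import bh_fdr, moderated_t_from_arrays
from .io import BetaMatrix, IntervalSet, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "probe_differential",
    "summarize_gene_methylation",
    "context_profile",
    "PROMOTER_CLASSES",
]

PROMOTER_CLASSES = frozenset({"TSS200", "TSS1500", "5UTR"})


def beta_to_m(beta, epsilon: float = 1e-6):
    """Logit2 transform: ``M = log2(b' / (1 - b'))`` with beta clipped to
    ``[epsilon, 1 - epsilon]``.  Strictly increasing in beta."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` on the unclipped range."""
    x = np.exp2(np.asarray(m, dtype=float))
    return x / (1.0 + x)


def probe_differential(
    beta: BetaMatrix,
    sheet: SampleSheet,
    tissue: str,
    epsilon: float = 1e-6,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t on M-values, delta-beta on the beta scale.

    Returns a frame indexed by probe id with ``delta_beta``, ``statistic``,
    ``p``, ``q``.  Probes constant across all samples (e.g. fully
    unmethylated everywhere) get statistic 0 and p 1.
    """
    case_ids = sorted(set(sheet.ids_for("case", tissue)) & set(beta.samples))
    ctrl_ids = sorted(set(sheet.ids_for("control", tissue)) & set(beta.samples))
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"tissue {tissue!r}: need >=2 samples per group "
            f"(case={len(case_ids)}, control={len(ctrl_ids)})"
        )
    b1 = beta.values[case_ids].to_numpy()
    b2 = beta.values[ctrl_ids].to_numpy()
    res = moderated_t_from_arrays(
        beta_to_m(b1, epsilon), beta_to_m(b2, epsilon), prior_df=prior_df
    )
    delta_beta = b1.mean(axis=1) - b2.mean(axis=1)
    stat, p = res.statistic, res.p
    # degenerate probes: no spread and no difference on the M scale
    return pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "statistic": stat,
            "p": p,
            "q": bh_fdr(p),
        },
        index=pd.Index(beta.features, name="probe_id"),
    )


def summarize_gene_methylation(
    probe_stats: pd.DataFrame,
    annotation: ProbeAnnotation,
    region_classes=PROMOTER_CLASSES,
    method: str = "min_p",
) -> pd.DataFrame:
    """Promoter-centric gene-level methylation statistics.

    For each gene, over its probes in ``region_classes``: the representative
    statistic is the probe with minimum p (ties broken by largest
    ``|delta_beta|``, then lexicographic probe id); the gene effect is that
    probe's delta-beta.  ``method="mean"`` averages statistic and delta-beta
    instead.  Genes with no qualifying probes are omitted; q is BH across the
    reported genes.  Output is invariant to probe input order.
    """
    region_classes = set(region_classes)
    if not region_classes:
        raise ValueError("region_classes must be non-empty")
    unknown = region_classes - set(annotation.frame["region_class"].unique()) - {
        "TSS200",
        "TSS1500",
        "5UTR",
        "body",
        "3UTR",
        "intergenic",
    }
    if unknown:
        raise ValueError(f"unknown region classes: {sorted(unknown)}")
    ann = annotation.subset(probe_stats.index).frame
    keep = ann["region_class"].isin(region_classes) & (ann["gene"] != "")
    merged = probe_stats.loc[keep].copy()
    merged["gene"] = ann.loc[keep, "gene"]
    if merged.empty:
        return pd.DataFrame(
            columns=["effect", "statistic", "p", "q", "probe_id", "n_probes"]
        ).rename_axis("gene")
    merged = merged.rename_axis("probe_id").reset_index()
    merged["probe_id"] = merged["probe_id"].astype(str)
    rows = []
    for gene, sub in merged.groupby("gene", sort=True):
        if method == "min_p":
            sub = sub.assign(_neg_abs=-sub["delta_beta"].abs())
            sub = sub.sort_values(by=["p", "_neg_abs", "probe_id"], kind="stable")
            top = sub.iloc[0]
            rows.append(
                (gene, top["delta_beta"], top["statistic"], top["p"], top["probe_id"], len(sub))
            )
        elif method == "mean":
            rows.append(
                (
                    gene,
                    sub["delta_beta"].mean(),
                    sub["statistic"].mean(),
                    float(np.nan),
                    "",
                    len(sub),
                )
            )
        else:
            raise ValueError(f"unknown summarization method {method!r}")
    out = pd.DataFrame(
        rows, columns=["gene", "effect", "statistic", "p", "probe_id", "n_probes"]
    ).set_index("gene")
    if method == "mean":
        # two-sided normal reference on the averaged statistic is not defined;
        # rank-consumers use |statistic| directly, p/q left as NaN
        out["q"] = np.nan
    else:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _signed_distance(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Signed distance from 0-based probe points to the nearest interval.

    0 inside; negative upstream of the interval start; positive downstream of
    its last base.  ``starts``/``ends`` need not be sorted or disjoint.
    """
    dist = np.full(pos0.shape, np.inf)
    for s, e in zip(starts, ends):
        d = np.where(pos0 < s, pos0 - s, np.where(pos0 >= e, pos0 - (e - 1), 0))
        closer = np.abs(d) < np.abs(dist)
        dist[closer] = d[closer]
    return dist


def context_profile(
    beta: BetaMatrix,
    sheet: SampleSheet,
    tissue: str,
    annotation: ProbeAnnotation,
    features: IntervalSet,
    bins,
) -> pd.DataFrame:
    """Mean methylation per group binned by signed distance to a feature set.

    ``bins`` are strictly increasing signed-distance edges in bp; probes are
    assigned to ``[edge_i, edge_{i+1})``; probes inside a feature have
    distance 0.  Probes on chromosomes without features are unassigned.
    Returns one row per (bin, group) including empty bins (``n_probes`` 0,
    mean missing).
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be strictly increasing edges (>=2 values)")
    if len(features) == 0:
        raise ValueError("features must be non-empty")
    ann = annotation.subset(beta.features).frame
    dist = np.full(len(ann), np.inf)
    for chrom, sub in features.frame.groupby("chrom"):
        sel = (ann["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos0 = ann.loc[sel, "pos"].to_numpy() - 1
        dist[sel] = _signed_distance(
            pos0, sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    bin_idx = np.digitize(dist, edges) - 1  # -1 below range; len-1 at/above top
    in_range = (bin_idx >= 0) & (bin_idx < len(edges) - 1) & np.isfinite(dist)
    if not in_range.any():
        raise ValueError("no probe falls in any distance bin")
    rows = []
    for group in ("case", "control"):
        ids = sorted(set(sheet.ids_for(group, tissue)) & set(beta.samples))
        vals = beta.values[ids].to_numpy().mean(axis=1) if ids else None
        for b in range(len(edges) - 1):
            mask = in_range & (bin_idx == b)
            n = int(mask.sum())
            mean_beta = float(vals[mask].mean()) if (n and vals is not None) else np.nan
            rows.append((edges[b], edges[b + 1], group, n, mean_beta))
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "group", "n_probes", "mean_beta"]
    )
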