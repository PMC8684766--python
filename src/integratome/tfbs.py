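"""Per-TF differential methylation of binding-site probe sets.

Each transcription factor's binding sites (a labeled interval catalogue) are
mapped to overlapping methylation probes; the distribution of probe-level
differential-methylation statistics inside the TF's sites is compared to the
TF's own complement (all probes not overlapping any of its sites) with a
two-sample Kolmogorov-Smirnov test.  A distributional test is used because
binding-site methylation changes need not shift every site in the same
direction.  Cross-tissue concordance classifies significant TFs as similar,
divergent, or tissue-specific.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_fdr
from .io import IntervalSet, ProbeAnnotation, probes_by_label

logger = logging.getLogger(__name__)

__all__ = ["tfbs_differential", "tfbs_concordance"]


def tfbs_differential(
    probe_stats: pd.DataFrame,
    annotation: ProbeAnnotation,
    tfbs: IntervalSet,
    min_probes: int = 10,
    test: str = "ks",
) -> pd.DataFrame:
    """Distributional test of binding-site probe statistics per TF.

    Returns a frame indexed by TF name with ``n_probes``, ``ks_d``, ``shift``
    (median statistic difference, sites minus background), ``p``, ``q`` and
    an ``excluded`` flag for TFs with fewer than ``min_probes`` overlapping
    probes (those carry no p).  BH is computed across tested TFs only.
    """
    if test not in ("ks", "mannwhitney"):
        raise ValueError(f"unknown test {test!r}")
    if not tfbs.labels:
        raise ValueError("TFBS catalogue has no TF labels")
    ann = annotation.subset(probe_stats.index)
    stats_by_probe = probe_stats["statistic"]
    mapping = probes_by_label(ann, tfbs)
    rows = []
    for tf in sorted(mapping):
        probes = sorted(mapping[tf] & set(probe_stats.index))
        n = len(probes)
        if n == 0:
            logger.info("tfbs_differential: TF %r overlaps no probes; excluded", tf)
        if n < min_probes:
            rows.append((tf, n, np.nan, np.nan, np.nan, True))
            continue
        fg = stats_by_probe.loc[probes].to_numpy()
        bg = stats_by_probe.drop(index=probes).to_numpy()
        if test == "ks":
            res = sps.ks_2samp(fg, bg, method="auto")
            ks_d, p = float(res.statistic), float(res.pvalue)
        else:
            res = sps.mannwhitneyu(fg, bg, alternative="two-sided")
            ks_d = float(sps.ks_2samp(fg, bg).statistic)
            p = float(res.pvalue)
        shift = float(np.median(fg) - np.median(bg))
        rows.append((tf, n, ks_d, shift, min(p, 1.0), False))
    out = pd.DataFrame(
        rows, columns=["tf", "n_probes", "ks_d", "shift", "p", "excluded"]
    ).set_index("tf")
    tested = ~out["excluded"]
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out


def tfbs_concordance(
    results_sat: pd.DataFrame,
    results_vat: pd.DataFrame,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Partition TFs significant in at least one tissue.

    Significant in both: ``similar`` when the median shifts agree in sign,
    ``divergent`` otherwise.  Significant in exactly one: ``sat_only`` /
    ``vat_only``.  The partition is exhaustive and mutually exclusive over
    TFs significant in >=1 tissue.
    """
    sig_sat = results_sat[(~results_sat["excluded"]) & (results_sat["q"] < q_threshold)]
    sig_vat = results_vat[(~results_vat["excluded"]) & (results_vat["q"] < q_threshold)]
    rows = []
    for tf in sorted(set(sig_sat.index) | set(sig_vat.index)):
        in_sat, in_vat = tf in sig_sat.index, tf in sig_vat.index
        if in_sat and in_vat:
            same = np.sign(sig_sat.loc[tf, "shift"]) == np.sign(sig_vat.loc[tf, "shift"])
            status = "similar" if same else "divergent"
        elif in_sat:
            status = "sat_only"
        else:
            status = "vat_only"
        rows.append((tf, status))
    return pd.DataFrame(rows, columns=["tf", "status"]).set_index("tf")
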