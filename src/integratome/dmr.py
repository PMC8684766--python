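"""Differentially methylated region (DMR) calling.

Adjacent probes are clustered by genomic gap, each cluster is scored with a
Stouffer combination of signed probe-level z-scores, and candidate regions
(enough probes, large enough mean delta-beta) are tested against a
group-label permutation null.  The null records, for each permutation, the
maximum |combined z| over all candidates (a maxT-style null shared by every
candidate), so the resulting add-one empirical p-values are jointly valid
and never zero.  Candidates at BH FDR < 0.1 are reported as DMRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_fdr, fit_variance_prior
from .diffmeth import beta_to_m, probe_differential
from .io import BetaMatrix, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "DMR",
    "ProbeCluster",
    "cluster_probes",
    "score_region",
    "call_dmrs",
    "compare_dmrs",
    "dmrs_to_frame",
]


@dataclass(frozen=True)
class ProbeCluster:
    chrom: str
    probe_ids: tuple  # sorted by position
    positions: tuple  # 1-based, ascending

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass(frozen=True)
class DMR:
    """A called region: clustered probes with a combined statistic.

    ``start``/``end`` are the 1-based positions of the first and last member
    probe (inclusive).  ``direction`` is ``hyper`` when the mean delta-beta is
    positive in cases, ``hypo`` otherwise.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple
    n_probes: int
    mean_delta_beta: float
    combined_z: float
    p_perm: float
    q: float
    direction: str
    genes: tuple = field(default_factory=tuple)


def cluster_probes(annotation: ProbeAnnotation, max_gap_bp: int) -> list[ProbeCluster]:
    """Maximal runs of probes with inter-probe gap <= ``max_gap_bp`` per
    chromosome.  Input order does not matter (sorted internally)."""
    clusters: list[ProbeCluster] = []
    frame = annotation.frame
    for chrom in sorted(frame["chrom"].unique()):
        sub = frame[frame["chrom"] == chrom].sort_values(
            ["pos"], kind="stable"
        )
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
        for chunk_ids, chunk_pos in zip(
            np.split(ids, breaks), np.split(pos, breaks)
        ):
            clusters.append(
                ProbeCluster(
                    chrom=chrom,
                    probe_ids=tuple(chunk_ids.tolist()),
                    positions=tuple(int(p) for p in chunk_pos),
                )
            )
    return clusters


def _z_from_p_sign(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed normal quantile of a two-sided p-value; clipped for stability."""
    z = sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    z = np.clip(z, 0.0, 40.0)
    return np.where(sign == 0, 0.0, np.sign(sign) * z)


def score_region(probe_stats: pd.DataFrame) -> tuple[float, float]:
    """Stouffer-combined signed z and mean delta-beta for one cluster.

    ``probe_stats`` carries columns ``statistic``, ``p``, ``delta_beta`` for
    the cluster's probes.  ``combined_z = sum(z_i) / sqrt(n)`` where ``z_i``
    is the signed normal quantile transform of each probe's two-sided p.
    Degenerate probes (p = 1, statistic 0) contribute z = 0.
    """
    if len(probe_stats) == 0:
        raise ValueError("cluster is empty")
    z = _z_from_p_sign(
        probe_stats["p"].to_numpy(), probe_stats["statistic"].to_numpy()
    )
    combined = float(z.sum() / np.sqrt(len(z)))
    return combined, float(probe_stats["delta_beta"].to_numpy().mean())


def _permutation_stats(
    m_values: np.ndarray, case_masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and p for many label permutations at once.

    ``m_values`` is probes x samples; ``case_masks`` is B x samples boolean.
    Returns (t, p), each probes x B.  The variance prior is re-fit per
    permutation, mirroring the observed-statistic computation.
    """
    X = m_values
    C = case_masks.T.astype(float)  # samples x B
    D = 1.0 - C
    n1 = C.sum(axis=0)
    n2 = D.sum(axis=0)
    s1 = X @ C
    s2_ = X @ D
    ss1 = (X**2) @ C
    ss2 = (X**2) @ D
    m1 = s1 / n1
    m2 = s2_ / n2
    v1 = np.maximum(ss1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(ss2 - n2 * m2**2, 0.0) / (n2 - 1)
    df = n1 + n2 - 2  # constant across permutations
    effect = m1 - m2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t = np.empty_like(effect)
    p = np.empty_like(effect)
    for b in range(s2.shape[1]):
        s0_sq, d0 = fit_variance_prior(s2[:, b], int(df[b]))
        if np.isinf(d0):
            st2 = np.full_like(s2[:, b], s0_sq)
            dft = np.inf
        else:
            st2 = (d0 * s0_sq + df[b] * s2[:, b]) / (d0 + df[b])
            dft = d0 + df[b]
        se = np.sqrt(st2 * (1.0 / n1[b] + 1.0 / n2[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(se > 0, effect[:, b] / np.where(se > 0, se, 1.0), 0.0)
        if np.isinf(dft):
            pb = 2.0 * sps.norm.sf(np.abs(tb))
        else:
            pb = 2.0 * sps.t.sf(np.abs(tb), dft)
        pb = np.where((se == 0) & (effect[:, b] == 0), 1.0, pb)
        t[:, b] = tb
        p[:, b] = pb
    return t, p


def call_dmrs(
    beta: BetaMatrix,
    sheet: SampleSheet,
    tissue: str,
    annotation: ProbeAnnotation,
    max_gap: int = 1000,
    min_probes: int = 3,
    min_abs_delta: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.1,
    epsilon: float = 1e-6,
) -> list[DMR]:
    """Cluster-and-permute DMR calling within one tissue.

    Candidates are clusters with ``n_probes >= min_probes`` and
    ``|mean delta-beta| >= min_abs_delta``.  ``B`` group-label permutations
    (within tissue) build the null of the per-permutation max |combined z|;
    add-one empirical p-values are BH-adjusted across candidates and regions
    with q < ``q_threshold`` are returned (sorted by |z| descending).
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    tsheet = sheet.for_tissue(tissue)
    ids = sorted(set(tsheet.sample_ids) & set(beta.samples))
    case_set = set(tsheet.ids_for("case"))
    sub = beta.subset_samples(ids)  # canonical sample order for determinism
    n = len(ids)
    n1 = sum(1 for s in ids if s in case_set)
    if comb(n, n1) < B:
        raise ValueError(
            f"only {comb(n, n1)} distinct group-label permutations available "
            f"for n={n}, n_case={n1}; choose a smaller B"
        )
    ann = annotation.subset(sub.features)
    obs = probe_differential(sub, sheet, tissue, epsilon=epsilon)

    clusters = cluster_probes(ann, max_gap)
    eligible = [cl for cl in clusters if len(cl) >= min_probes]
    candidates = []
    for cl in eligible:
        stats_cl = obs.loc[list(cl.probe_ids)]
        z, mdb = score_region(stats_cl)
        if abs(mdb) >= min_abs_delta:
            candidates.append((cl, z, mdb))
    if not candidates:
        return []

    # Permutation null: within each permutation the candidate filter is
    # re-applied (bumphunting-style), and the max |combined z| over the
    # permutation's own candidates is recorded.  Mirroring the selection
    # step in the null is what keeps the p-values honest: observed
    # candidates are chosen for large |delta-beta|, so comparing them to
    # unselected permutation scores would be anti-conservative.
    rng = np.random.default_rng(seed)
    obs_mask = np.array([s in case_set for s in ids])
    masks = np.empty((B, n), dtype=bool)
    for b in range(B):
        masks[b] = rng.permutation(obs_mask)
    probe_index = {p: i for i, p in enumerate(sub.features)}
    bvals = sub.values.to_numpy()
    mvals = beta_to_m(bvals, epsilon)
    t_perm, p_perm_mat = _permutation_stats(mvals, masks)
    C = masks.T.astype(float)
    D = 1.0 - C
    delta_perm = (bvals @ C) / C.sum(axis=0) - (bvals @ D) / D.sum(axis=0)
    null_max = np.zeros(B)
    for cl in eligible:
        idx = [probe_index[p] for p in cl.probe_ids]
        zmat = _z_from_p_sign(p_perm_mat[idx], t_perm[idx])
        combined = np.abs(zmat.sum(axis=0) / np.sqrt(len(idx)))
        selected = np.abs(delta_perm[idx].mean(axis=0)) >= min_abs_delta
        null_max = np.maximum(null_max, np.where(selected, combined, 0.0))

    p_emp = np.array(
        [(1.0 + np.sum(null_max >= abs(z))) / (B + 1.0) for _, z, _ in candidates]
    )
    q = bh_fdr(p_emp)
    dmrs = []
    for (cl, z, mdb), p_c, q_c in zip(candidates, p_emp, q):
        if q_c >= q_threshold:
            continue
        genes = tuple(
            sorted(
                set(ann.frame.loc[list(cl.probe_ids), "gene"]) - {""}
            )
        )
        dmrs.append(
            DMR(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                probe_ids=cl.probe_ids,
                n_probes=len(cl),
                mean_delta_beta=mdb,
                combined_z=z,
                p_perm=float(p_c),
                q=float(q_c),
                direction="hyper" if mdb > 0 else "hypo",
                genes=genes,
            )
        )
    dmrs.sort(key=lambda d: (-abs(d.combined_z), d.chrom, d.start))
    return dmrs


def compare_dmrs(dmrs_sat: list[DMR], dmrs_vat: list[DMR]) -> dict:
    """Match DMRs across tissues by >=1 bp overlap on the same chromosome.

    Overlapping DMRs are grouped by connected components of the overlap
    graph; components containing both tissues are "common" (counted once per
    component), the rest are tissue-specific.
    """
    items = [("SAT", d) for d in dmrs_sat] + [("VAT", d) for d in dmrs_vat]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1], items[j][1]
            if a.chrom == b.chrom and a.start <= b.end and b.start <= a.end:
                union(i, j)
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    common, sat_specific, vat_specific = [], [], []
    for members in comps.values():
        tissues = {t for t, _ in members}
        if tissues == {"SAT", "VAT"}:
            common.append([d for _, d in members])
        elif tissues == {"SAT"}:
            sat_specific.extend(d for _, d in members)
        else:
            vat_specific.extend(d for _, d in members)
    return {
        "common": common,
        "sat_specific": sat_specific,
        "vat_specific": vat_specific,
    }


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """Flatten DMRs into a BED-compatible statistics table."""
    rows = [
        {
            "chrom": d.chrom,
            "start": d.start,
            "end": d.end,
            "n_probes": d.n_probes,
            "mean_delta_beta": d.mean_delta_beta,
            "combined_z": d.combined_z,
            "p_perm": d.p_perm,
            "q": d.q,
            "direction": d.direction,
            "genes": ",".join(d.genes),
            "probes": ",".join(d.probe_ids),
        }
        for d in dmrs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_probes",
            "mean_delta_beta",
            "combined_z",
            "p_perm",
            "q",
            "direction",
            "genes",
            "probes",
        ],
    )
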