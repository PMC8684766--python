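"""Readers and writers for every external file the pipeline touches.

All tabular inputs are plain text (TSV matrices, CSV sample sheet and probe
annotation, BED3/BED4 intervals, GMT gene sets, TSV edge lists).  Readers
validate strictly and fail with coordinates (row, probe, sample, line number)
rather than silently coercing; write/read round trips are identity for valid
objects.

Coordinate conventions
----------------------
Methylation probes are annotated with 1-based positions (array-manifest
style); interval files are 0-based half-open (BED style).  The single
conversion rule lives in :func:`probe_overlaps_interval`: a probe at 1-based
position ``p`` overlaps interval ``(start, end)`` iff ``start <= p - 1 < end``,
i.e. interval ``(100, 200)`` contains 1-based positions 101..200.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SampleSheet",
    "BetaMatrix",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "IntervalSet",
    "GeneSetCollection",
    "GROUP_ALIASES",
    "TISSUES",
    "REGION_CLASSES",
    "CGI_RELATIONS",
    "GENESET_CATEGORIES",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix",
    "write_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "probe_overlaps_interval",
    "probes_by_label",
    "probes_in_intervals",
]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


#: Canonical group tokens.  Raw sample sheets may use study-specific labels
#: (e.g. the diabetic group written as "T2D"); the alias table is the single
#: place where they are normalized.
GROUP_ALIASES = {
    "case": "case",
    "t2d": "case",
    "control": "control",
    "ctrl": "control",
    "non-t2d": "control",
    "nont2d": "control",
    "non_t2d": "control",
}

TISSUES = ("SAT", "VAT")

REGION_CLASSES = ("TSS200", "TSS1500", "5UTR", "body", "3UTR", "intergenic")
CGI_RELATIONS = ("island", "shore", "shelf", "open_sea")

GENESET_CATEGORIES = (
    "comorbidity",
    "druggability",
    "eQTL",
    "GWAS",
    "TFBS",
    "TF",
    "T2Di",
    "other",
)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sample with group and tissue labels.

    ``frame`` has columns ``sample_id``, ``group`` (canonical ``case`` /
    ``control``) and ``tissue`` (``SAT`` / ``VAT``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "tissue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.frame["sample_id"]
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate sample ids: {dup}")
        bad_group = sorted(set(self.frame["group"]) - {"case", "control"})
        if bad_group:
            raise FormatError(f"non-canonical group tokens: {bad_group}")
        bad_tissue = sorted(set(self.frame["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise FormatError(f"unknown tissues: {bad_tissue}")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def for_tissue(self, tissue: str) -> "SampleSheet":
        if tissue not in TISSUES:
            raise FormatError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        sub = self.frame[self.frame["tissue"] == tissue].reset_index(drop=True)
        return SampleSheet(sub)

    def ids_for(self, group: str, tissue: str | None = None) -> list[str]:
        f = self.frame
        mask = f["group"] == group
        if tissue is not None:
            mask &= f["tissue"] == tissue
        return f.loc[mask, "sample_id"].tolist()


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet CSV with header ``sample_id,group,tissue``.

    Group tokens are normalized through :data:`GROUP_ALIASES`
    (case-insensitive); tissues are upper-cased.  Duplicate sample ids and
    unrecognized tokens are hard errors naming the offending row.
    """
    raw = pd.read_csv(path, dtype=str).fillna("")
    required = ["sample_id", "group", "tissue"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    groups, tissues = [], []
    for i, row in raw.iterrows():
        g = str(row["group"]).strip().lower()
        if g not in GROUP_ALIASES:
            raise FormatError(
                f"{path}: row {i + 2} (sample {row['sample_id']!r}): "
                f"unknown group token {row['group']!r}"
            )
        t = str(row["tissue"]).strip().upper()
        if t not in TISSUES:
            raise FormatError(
                f"{path}: row {i + 2} (sample {row['sample_id']!r}): "
                f"unknown tissue token {row['tissue']!r}"
            )
        groups.append(GROUP_ALIASES[g])
        tissues.append(t)
    frame = pd.DataFrame(
        {"sample_id": raw["sample_id"].astype(str), "group": groups, "tissue": tissues}
    )
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


class FeatureMatrix:
    """Dense feature-by-sample numeric matrix (features as rows)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dup}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        vals = values.astype(float)
        self.values = vals
        self._validate()

    def _validate(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            r, c = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise FormatError(
                f"non-finite value at (feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r})"
            )

    @property
    def features(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise FormatError(f"samples absent from matrix: {missing}")
        return type(self)(self.values[list(sample_ids)])

    def check_samples(self, sheet: SampleSheet) -> None:
        missing = sorted(set(self.samples) - set(sheet.sample_ids))
        if missing:
            raise FormatError(f"matrix samples absent from sample sheet: {missing}")


class BetaMatrix(FeatureMatrix):
    """Probe-by-sample methylation beta values, all in [0, 1]."""

    def _validate(self) -> None:
        super()._validate()
        arr = self.values.to_numpy()
        bad = np.argwhere((arr < 0.0) | (arr > 1.0))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"beta value {arr[r, c]!r} outside [0, 1] at "
                f"(probe {self.values.index[r]!r}, sample {self.values.columns[c]!r})"
            )


class ExpressionMatrix(FeatureMatrix):
    """Gene-by-sample log2-scale expression abundances (e.g. log2(FPKM+1))."""


def read_matrix(path, kind: str) -> FeatureMatrix:
    """Read a dense TSV matrix (first column feature id, remaining samples).

    ``kind`` is ``"beta"`` or ``"expression"``; beta matrices additionally
    enforce values in [0, 1].  Non-numeric cells are errors with coordinates.
    """
    if kind not in ("beta", "expression"):
        raise FormatError(f"unknown matrix kind {kind!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at "
            f"(feature {raw.index[r]!r}, sample {raw.columns[c]!r})"
        )
    # Python float parsing is correctly rounded (write/read is then identity)
    numeric = raw.apply(lambda col: col.map(float))
    cls = BetaMatrix if kind == "beta" else ExpressionMatrix
    return cls(numeric)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g")  # lossless round trip


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``frame`` is indexed by probe id with columns ``chrom``, ``pos`` (1-based),
    ``gene`` (empty string for intergenic probes), ``region_class`` and
    ``cgi_relation``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"chrom", "pos", "gene", "region_class", "cgi_relation"}
        missing = required - set(f.columns)
        if missing:
            raise FormatError(f"probe annotation missing columns: {sorted(missing)}")
        if f.index.duplicated().any():
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dup}")
        bad_rc = sorted(set(f["region_class"]) - set(REGION_CLASSES))
        if bad_rc:
            raise FormatError(f"unknown region classes: {bad_rc}")
        bad_cgi = sorted(set(f["cgi_relation"]) - set(CGI_RELATIONS))
        if bad_cgi:
            raise FormatError(f"unknown CpG-island relations: {bad_cgi}")
        if (f["pos"] < 1).any():
            bad = f.index[f["pos"] < 1].tolist()
            raise FormatError(f"probe positions must be 1-based positive: {bad}")
        inter = f["region_class"] == "intergenic"
        empty = f["gene"] == ""
        mismatch = f.index[inter != empty].tolist()
        if mismatch:
            raise FormatError(
                f"region_class must be 'intergenic' exactly when gene is empty; "
                f"violated by probes {mismatch}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def subset(self, probe_ids) -> "ProbeAnnotation":
        missing = sorted(set(probe_ids) - set(self.frame.index))
        if missing:
            raise FormatError(f"probes absent from annotation: {missing}")
        return ProbeAnnotation(self.frame.loc[list(probe_ids)])


def read_probe_annotation(path) -> ProbeAnnotation:
    raw = pd.read_csv(path, dtype={"probe_id": str, "chrom": str, "gene": str})
    if "probe_id" not in raw.columns:
        raise FormatError(f"{path}: probe annotation needs a probe_id column")
    raw["gene"] = raw["gene"].fillna("")
    raw["pos"] = raw["pos"].astype(int)
    return ProbeAnnotation(raw.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    out = annotation.frame.reset_index()
    out = out.rename(columns={out.columns[0]: "probe_id"})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# intervals (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalSet:
    """A named set of 0-based half-open genomic intervals, optionally labeled.

    Labels carry TF names when the set is a binding-site catalogue.
    Overlapping intervals are preserved as-is (no implicit merging).
    """

    name: str
    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label"])
    )

    def __post_init__(self) -> None:
        f = self.frame
        required = {"chrom", "start", "end"}
        missing = required - set(f.columns)
        if missing:
            raise FormatError(f"interval set missing columns: {sorted(missing)}")
        bad = f[f["start"] >= f["end"]]
        if len(bad):
            first = bad.iloc[0]
            raise FormatError(
                f"interval start >= end: {first['chrom']}:{first['start']}-{first['end']}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        if "label" not in self.frame.columns:
            return []
        vals = self.frame["label"].dropna()
        return sorted(set(vals) - {""})


def read_bed(path, name: str) -> IntervalSet:
    """Read BED3/BED4 (tab- or space-separated); 4th column is the label."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates {parts[1:3]}"
                ) from None
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, label))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(name=name, frame=frame)


def write_bed(intervals: IntervalSet, path) -> None:
    cols = ["chrom", "start", "end"]
    frame = intervals.frame
    if "label" in frame.columns and frame["label"].astype(str).str.len().gt(0).any():
        cols.append("label")
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets under one validation category (GMT semantics)."""

    sets: dict[str, frozenset]
    category: str = "other"

    def __post_init__(self) -> None:
        if self.category not in GENESET_CATEGORIES:
            raise FormatError(
                f"unknown category {self.category!r}; expected one of {GENESET_CATEGORIES}"
            )
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if any(not g for g in genes):
                raise FormatError(f"gene set {name!r} contains empty gene names")

    def all_genes(self) -> frozenset:
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path, category: str = "other") -> GeneSetCollection:
    """Read a standard GMT file (set name, description, member genes)."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description, >=1 gene"
                )
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets, category=category)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.category, *genes]) + "\n")


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------


def read_network(path) -> nx.Graph:
    """Read an undirected gene-level edge list (TSV, no header).

    Columns: gene1, gene2, optional provenance label.  Duplicate edges are
    collapsed; self-loops are dropped with a logged count.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs at least 2 columns")
    graph = nx.Graph()
    n_self = 0
    for row in raw.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            n_self += 1
            continue
        attrs = {}
        if len(row) > 2 and isinstance(row[2], str) and row[2]:
            attrs["provenance"] = row[2]
        graph.add_edge(a, b, **attrs)
    if n_self:
        logger.info("read_network: dropped %d self-loop(s) from %s", n_self, path)
    return graph


def write_network(graph: nx.Graph, path) -> None:
    rows = []
    for a, b, data in sorted(graph.edges(data=True)):
        prov = data.get("provenance", "")
        rows.append((a, b, prov) if prov else (a, b))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# coordinate conversion (single owner of the 1-based / 0-based mapping)
# ---------------------------------------------------------------------------


def probe_overlaps_interval(pos: int, start: int, end: int) -> bool:
    """True iff a probe at 1-based ``pos`` lies inside 0-based ``[start, end)``."""
    return start <= pos - 1 < end


def probes_in_intervals(
    annotation: ProbeAnnotation, intervals: IntervalSet, label: str | None = None
) -> np.ndarray:
    """Boolean mask over annotation probes overlapping any (matching) interval."""
    frame = intervals.frame
    if label is not None:
        frame = frame[frame["label"] == label]
    probes = annotation.frame
    mask = np.zeros(len(probes), dtype=bool)
    for chrom, sub in frame.groupby("chrom"):
        sel = probes["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = probes.loc[sel, "pos"].to_numpy() - 1  # 0-based probe points
        idx = np.flatnonzero(sel.to_numpy())
        order = np.argsort(pos0, kind="stable")
        sorted_pos = pos0[order]
        hit = np.zeros(len(sorted_pos), dtype=bool)
        for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            lo = np.searchsorted(sorted_pos, start, side="left")
            hi = np.searchsorted(sorted_pos, end, side="left")
            hit[lo:hi] = True
        mask[idx[order[hit]]] = True
    return mask


def probes_by_label(
    annotation: ProbeAnnotation, intervals: IntervalSet
) -> dict[str, set]:
    """Map each interval label (e.g. TF name) to its overlapping probe ids."""
    out: dict[str, set] = {}
    for label in intervals.labels:
        mask = probes_in_intervals(annotation, intervals, label=label)
        out[label] = set(np.asarray(annotation.probe_ids)[mask])
    return out
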