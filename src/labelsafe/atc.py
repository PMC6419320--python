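"""ATC therapeutic-class analysis: PT x ATC frequency matrix and two-way HCA.

Drugs are grouped by second-level Anatomical Therapeutic Chemical codes
(letter + two digits, e.g. ``L01``, ``N02``); a drug carrying several ATC
codes contributes to every one of its classes.  For Boxed-Warning pattern
discovery, cell (PT, ATC) counts the BW-bearing drugs of the class whose
Boxed Warning mentions the PT; sparse classes and rare PTs (fewer than 5
drugs by default) are filtered out, counts are log2(x+1) transformed, and
rows and columns are clustered independently by agglomerative hierarchical
clustering (Euclidean distance, complete linkage by default — the classic
heatmap defaults).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .meddra import Dictionary
from .occurrence import DrugPTMatrix

logger = logging.getLogger(__name__)

_ATC2_RE = re.compile(r"^[A-Z]\d{2}$")


class AtcError(Exception):
    pass


@dataclass
class ATCMap:
    """Drug set_id -> set of second-level ATC codes."""

    entries: Dict[str, Set[str]]

    def __post_init__(self) -> None:
        for set_id, codes in self.entries.items():
            bad = [c for c in codes if not _ATC2_RE.match(c)]
            if bad:
                raise AtcError(
                    f"invalid second-level ATC codes for {set_id}: {bad}"
                )


def read_atc_tsv(path: str) -> ATCMap:
    """Read a two-column TSV ``set_id <tab> atc_code`` (one pair per row)."""
    entries: Dict[str, Set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AtcError(f"{path}:{lineno}: expected 2 tab-separated fields")
            entries.setdefault(parts[0], set()).add(parts[1])
    return ATCMap(entries=entries)


def write_atc_tsv(atc: ATCMap, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(atc.entries):
            for code in sorted(atc.entries[set_id]):
                fh.write(f"{set_id}\t{code}\n")


@dataclass
class ClusterInput:
    """log2-transformed PT x ATC frequency grid with label metadata.

    ``matrix`` rows are PTs (index = PT name, one row per retained PT),
    columns are second-level ATC codes.  ``row_soc`` carries each PT's
    primary-SOC abbreviation for color-keyed display.
    """

    matrix: pd.DataFrame
    pt_codes: List[int]
    row_soc: Dict[int, str] = field(default_factory=dict)
    filters_applied: Dict[str, int] = field(default_factory=dict)

    @property
    def raw_counts(self) -> pd.DataFrame:
        return np.exp2(self.matrix) - 1


def build_atc_pt_matrix(
    m: DrugPTMatrix,
    atc: ATCMap,
    d: Optional[Dictionary] = None,
    min_drugs: int = 5,
) -> ClusterInput:
    """Build the filtered, log2(count+1)-transformed PT x ATC matrix.

    Cell (PT, ATC) = number of BW-bearing drugs in the ATC class whose
    Boxed Warning contains the PT.  ATC columns with fewer than
    ``min_drugs`` BW-bearing drugs and PT rows mentioned by fewer than
    ``min_drugs`` distinct BW drugs overall are dropped (filters operate on
    raw counts, before the transform).
    """
    if min_drugs < 1:
        raise ValueError(f"min_drugs must be >= 1, got {min_drugs}")
    bw = m.section_slice("BW")
    has_bw = m.section_presence[:, 0]

    atc_codes = sorted({c for codes in atc.entries.values() for c in codes})
    atc_ix = {c: i for i, c in enumerate(atc_codes)}
    # drug -> ATC membership incidence (BW-bearing drugs only)
    member = np.zeros((len(m.set_ids), len(atc_codes)), dtype=bool)
    for i, set_id in enumerate(m.set_ids):
        if not has_bw[i]:
            continue
        for code in atc.entries.get(set_id, ()):
            member[i, atc_ix[code]] = True

    counts = (bw.astype(np.int64).T @ member.astype(np.int64))  # PT x ATC

    col_bw_drugs = member.sum(axis=0)
    keep_cols = col_bw_drugs >= min_drugs
    pt_total_drugs = bw.sum(axis=0)
    keep_rows = pt_total_drugs >= min_drugs

    filters = {
        "min_drugs_per_atc": min_drugs,
        "min_drugs_per_pt": min_drugs,
        "atc_columns_dropped": int((~keep_cols).sum()),
        "pt_rows_dropped": int((~keep_rows).sum()),
    }
    counts = counts[np.ix_(keep_rows, keep_cols)]
    kept_pts = [p for p, k in zip(m.pt_codes, keep_rows) if k]
    kept_atcs = [c for c, k in zip(atc_codes, keep_cols) if k]

    # residual all-zero rows/columns carry no pattern information
    nz_rows = counts.any(axis=1)
    nz_cols = counts.any(axis=0)
    filters["zero_rows_dropped"] = int((~nz_rows).sum())
    filters["zero_cols_dropped"] = int((~nz_cols).sum())
    counts = counts[np.ix_(nz_rows, nz_cols)]
    kept_pts = [p for p, k in zip(kept_pts, nz_rows) if k]
    kept_atcs = [c for c, k in zip(kept_atcs, nz_cols) if k]

    if counts.size == 0:
        raise AtcError(
            f"empty matrix after filtering (filters: {filters}); "
            "lower min_drugs or check the ATC map"
        )

    row_soc: Dict[int, str] = {}
    if d is not None:
        for p in kept_pts:
            soc = d.pt_primary_soc(p)
            row_soc[p] = d.socs[soc].soc_abbrev or str(soc)

    mat = pd.DataFrame(
        np.log2(counts + 1.0),
        index=[m.pt_label(p) for p in kept_pts],
        columns=kept_atcs,
    )
    logger.info(
        "ATC/PT cluster matrix: %d PTs x %d ATC classes (filters %s)",
        mat.shape[0], mat.shape[1], filters,
    )
    return ClusterInput(
        matrix=mat, pt_codes=kept_pts, row_soc=row_soc, filters_applied=filters
    )


@dataclass
class HCAResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: List[str]
    col_order: List[str]
    row_newick: str
    col_newick: str


def _to_newick(linkage: np.ndarray, labels: List[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def two_way_hca(
    ci: ClusterInput,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> HCAResult:
    """Cluster rows (PTs) and columns (ATC classes) independently.

    Deterministic given the matrix: SciPy's agglomerative merge order is
    reproducible and ties resolve to the lowest-index pair.  Dendrograms
    are also rendered as Newick text with branch lengths derived from merge
    heights.
    """
    mat = ci.matrix.to_numpy()
    if not np.isfinite(mat).all():
        raise AtcError("non-finite cell in cluster input")
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise AtcError(f"need >= 2 rows and >= 2 columns, got {mat.shape}")
    row_Z = hierarchy.linkage(pdist(mat, metric=distance), method=linkage)
    col_Z = hierarchy.linkage(pdist(mat.T, metric=distance), method=linkage)
    row_leaves = hierarchy.leaves_list(row_Z)
    col_leaves = hierarchy.leaves_list(col_Z)
    row_labels = list(ci.matrix.index)
    col_labels = list(ci.matrix.columns)
    return HCAResult(
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=[row_labels[i] for i in row_leaves],
        col_order=[col_labels[i] for i in col_leaves],
        row_newick=_to_newick(row_Z, row_labels),
        col_newick=_to_newick(col_Z, col_labels),
    )


def cut_columns(hca: HCAResult, n_clusters: int) -> Dict[str, int]:
    """Column-cluster assignment at an ``n_clusters`` cut."""
    flat = hierarchy.fcluster(hca.col_linkage, t=n_clusters, criterion="maxclust")
    labels = hca.col_order  # leaves order irrelevant; map by original order
    cols = _linkage_labels(hca)
    return {c: int(k) for c, k in zip(cols, flat)}


def _linkage_labels(hca: HCAResult) -> List[str]:
    # original column order = leaves re-sorted by leaf id
    order = hierarchy.leaves_list(hca.col_linkage)
    pairs = sorted(zip(order, hca.col_order))
    return [lbl for _, lbl in pairs]


def cluster_report(
    ci: ClusterInput,
    hca: HCAResult,
    cut_height: Optional[float] = None,
    n_clusters: Optional[int] = None,
    margin: float = 0.5,
) -> List[dict]:
    """Membership and enriched PTs per column cluster at a requested cut.

    A PT is reported as enriched in a cluster when its within-cluster mean
    (of the log2 matrix) exceeds its global mean by more than ``margin``.
    Exactly one of ``cut_height`` / ``n_clusters`` must be given.
    """
    if (cut_height is None) == (n_clusters is None):
        raise ValueError("give exactly one of cut_height or n_clusters")
    max_h = float(hca.col_linkage[:, 2].max()) if len(hca.col_linkage) else 0.0
    if cut_height is not None:
        if not 0.0 <= cut_height <= max_h:
            raise ValueError(
                f"cut height {cut_height} outside dendrogram range [0, {max_h}]"
            )
        flat = hierarchy.fcluster(hca.col_linkage, t=cut_height, criterion="distance")
    else:
        flat = hierarchy.fcluster(hca.col_linkage, t=n_clusters, criterion="maxclust")

    cols = _linkage_labels(hca)
    mat = ci.matrix
    global_mean = mat.mean(axis=1)
    report = []
    for k in sorted(set(flat)):
        members = [c for c, kk in zip(cols, flat) if kk == k]
        sub_mean = mat[members].mean(axis=1)
        enriched = [
            pt for pt in mat.index
            if sub_mean.loc[pt] > global_mean.loc[pt] + margin
        ]
        report.append({
            "cluster": int(k),
            "atc_members": members,
            "enriched_pts": enriched,
        })
    return report
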