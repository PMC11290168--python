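"""Two-level network construction and comparison.

Nodes are the variables passing each level's significance cutoff.
Cross-level edges are directed (level 1 -> level 2) and exist exactly where
the annotation mask links two significant endpoints. Within-level edges
follow one of three connectivity classes: none, sparse (absolute Pearson
correlation of the level's data columns at or above an edge threshold), or
complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import UsageError, ValidationError
from .io import GRN, AnnotationMask, GRNEdge, GRNNode, ScoreTable, SelectionResult
from .select import threshold_scores

CONNECTIVITY_MODES = ("none", "sparse", "complete")
LAYOUTS = ("layout_with_kk", "layout_bipartite", "layout_circle")


@dataclass(frozen=True)
class ConnectivityMode:
    """Within-level connectivity class; ``edge_threshold`` only for sparse."""

    mode: str = "none"
    edge_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in CONNECTIVITY_MODES:
            raise UsageError(
                f"connectivity mode must be one of {CONNECTIVITY_MODES}, "
                f"got {self.mode!r}"
            )
        if self.mode == "sparse":
            if self.edge_threshold is None:
                raise UsageError("sparse connectivity requires edge_threshold")
            if not 0.0 <= self.edge_threshold <= 1.0:
                raise UsageError(
                    f"edge_threshold must lie in [0, 1], got {self.edge_threshold}"
                )
        elif self.edge_threshold is not None:
            raise UsageError(f"edge_threshold only applies to sparse mode")

    def describe(self) -> dict:
        return {"mode": self.mode, "edge_threshold": self.edge_threshold}


@dataclass
class GRNDiff:
    """Set-algebra comparison of two networks sharing a score kind."""

    nodes_added: list[str] = field(default_factory=list)
    nodes_removed: list[str] = field(default_factory=list)
    nodes_persisting: list[dict] = field(default_factory=list)
    edges_added: list[tuple] = field(default_factory=list)
    edges_removed: list[tuple] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.nodes_added
            or self.nodes_removed
            or self.edges_added
            or self.edges_removed
            or any(d["delta"] != 0.0 for d in self.nodes_persisting)
        )

    def to_dict(self) -> dict:
        return {
            "nodes_added": self.nodes_added,
            "nodes_removed": self.nodes_removed,
            "nodes_persisting": self.nodes_persisting,
            "edges_added": [list(e) for e in self.edges_added],
            "edges_removed": [list(e) for e in self.edges_removed],
        }


def sparse_within_edges(
    level_data: np.ndarray,
    node_ids: list[str],
    tau: float,
) -> list[tuple[str, str, float]]:
    """Undirected edges (a, b, |r|) for column pairs with |corr| >= tau.

    Constant columns have all their correlations treated as zero (no edges).
    """
    level_data = np.asarray(level_data, dtype=float)
    if level_data.ndim != 2 or level_data.shape[1] != len(node_ids):
        raise ValidationError(
            f"level_data has {level_data.shape[1] if level_data.ndim == 2 else '?'} "
            f"columns for {len(node_ids)} node ids"
        )
    if level_data.shape[0] < 3:
        raise UsageError("need n >= 3 samples to estimate correlations")
    if len(node_ids) < 2:
        return []
    sd = level_data.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(level_data, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[sd == 0.0, :] = 0.0
    r[:, sd == 0.0] = 0.0
    edges = []
    K = len(node_ids)
    const = sd == 0.0
    for a in range(K):
        for b in range(a + 1, K):
            if const[a] or const[b]:  # no correlation defined: never an edge
                continue
            w = abs(float(r[a, b]))
            if w >= tau:
                edges.append((node_ids[a], node_ids[b], min(w, 1.0)))
    return edges


def build_grn(
    result: SelectionResult,
    mask: AnnotationMask,
    l1_cutoff: float,
    l2_cutoff: float,
    l1_mode: ConnectivityMode = ConnectivityMode("none"),
    l2_mode: ConnectivityMode = ConnectivityMode("none"),
    level_data: Optional[dict[int, tuple[np.ndarray, list[str]]]] = None,
) -> GRN:
    """Assemble the two-level GRN from a selection result and a mask.

    ``level_data`` maps level -> (data matrix, column ids) and is required
    for any level using sparse connectivity. Nodes failing the cutoff are
    removed entirely; a significant level-1 node with no significant
    annotated group is kept and flagged as an orphan.
    """
    for tbl, name in ((result.level1, "level-1"), (result.level2, "level-2")):
        known = set(mask.row_ids if tbl.level == 1 else mask.col_ids)
        missing = [i for i in tbl.ids if i not in known]
        if missing:
            raise ValidationError(
                f"{name} score ids not covered by the mask: {missing[:5]}"
            )

    sig1 = threshold_scores(result.level1, l1_cutoff)
    sig2 = threshold_scores(result.level2, l2_cutoff)
    sig2_set = set(sig2)
    scores1 = result.level1.as_dict()
    scores2 = result.level2.as_dict()
    kind = result.level1.score_kind

    row_index = {r: j for j, r in enumerate(mask.row_ids)}
    col_index = {c: g for g, c in enumerate(mask.col_ids)}

    edges: list[GRNEdge] = []
    orphan: dict[str, bool] = {}
    for sid in sig1:
        j = row_index[sid]
        targets = [
            g for g in mask.col_ids
            if mask.values[j, col_index[g]] == 1 and g in sig2_set
        ]
        orphan[sid] = not targets
        for g in targets:
            edges.append(
                GRNEdge(source=sid, target=g, directed=True, kind="cross_level")
            )

    nodes: list[GRNNode] = []
    for sid in sig1:
        j = row_index[sid]
        memberships = tuple(
            c for c in mask.col_ids if mask.values[j, col_index[c]] == 1
        )
        nodes.append(
            GRNNode(
                id=sid, level=1, score=float(scores1[sid]), score_kind=kind,
                significant=True, group_memberships=memberships,
                orphan=orphan[sid],
            )
        )
    for gid in sig2:
        nodes.append(
            GRNNode(
                id=gid, level=2, score=float(scores2[gid]), score_kind=kind,
                significant=True,
            )
        )

    for level, ids, mode in ((1, sig1, l1_mode), (2, sig2, l2_mode)):
        if mode.mode == "none" or len(ids) < 2:
            continue
        if mode.mode == "complete":
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    edges.append(
                        GRNEdge(
                            source=ids[a], target=ids[b],
                            directed=False, kind="within_level",
                        )
                    )
        else:  # sparse
            if level_data is None or level not in level_data:
                raise UsageError(
                    f"sparse connectivity on level {level} requires level_data"
                )
            mat, col_ids = level_data[level]
            col_of = {c: k for k, c in enumerate(col_ids)}
            missing = [i for i in ids if i not in col_of]
            if missing:
                raise ValidationError(
                    f"level_data for level {level} lacks columns: {missing[:5]}"
                )
            sub = np.asarray(mat, dtype=float)[:, [col_of[i] for i in ids]]
            for a, b, w in sparse_within_edges(sub, ids, mode.edge_threshold):
                edges.append(
                    GRNEdge(
                        source=a, target=b, directed=False,
                        kind="within_level", weight=w,
                    )
                )

    metadata = {
        "l1_cutoff": l1_cutoff,
        "l2_cutoff": l2_cutoff,
        "l1_connectivity": l1_mode.describe(),
        "l2_connectivity": l2_mode.describe(),
        "score_kind": kind,
        "backend": result.backend,
        "layout": None,
    }
    return GRN(nodes=nodes, edges=edges, metadata=metadata)


def diff_grn(before: GRN, after: GRN) -> GRNDiff:
    """What changed between two networks (node sets, edge sets, score deltas)."""
    kinds_b = {n.level: n.score_kind for n in before.nodes}
    kinds_a = {n.level: n.score_kind for n in after.nodes}
    for level in set(kinds_b) & set(kinds_a):
        if kinds_b[level] != kinds_a[level]:
            raise UsageError(
                f"score_kind mismatch on level {level}: "
                f"{kinds_b[level]!r} vs {kinds_a[level]!r}"
            )
    b_nodes = {n.id: n for n in before.nodes}
    a_nodes = {n.id: n for n in after.nodes}
    added = sorted(set(a_nodes) - set(b_nodes))
    removed = sorted(set(b_nodes) - set(a_nodes))
    persisting = [
        {
            "id": i,
            "score_before": b_nodes[i].score,
            "score_after": a_nodes[i].score,
            "delta": a_nodes[i].score - b_nodes[i].score,
        }
        for i in sorted(set(b_nodes) & set(a_nodes))
    ]
    b_edges = {e.canonical() for e in before.edges}
    a_edges = {e.canonical() for e in after.edges}
    return GRNDiff(
        nodes_added=added,
        nodes_removed=removed,
        nodes_persisting=persisting,
        edges_added=sorted(a_edges - b_edges),
        edges_removed=sorted(b_edges - a_edges),
    )


def layout_hint(grn: GRN, name: str) -> GRN:
    """Record a layout hint in metadata; no coordinates are computed."""
    if name not in LAYOUTS:
        raise UsageError(f"unknown layout {name!r}; options: {list(LAYOUTS)}")
    grn.metadata = dict(grn.metadata)
    grn.metadata["layout"] = name
    return grn
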