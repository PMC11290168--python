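"""Domain types and file input/output.

Score tables, annotation masks and genotype datasets are delimited text
(comma by default, tab auto-detected). Networks are serialized either as a
versioned JSON document or as GraphML. All writers emit UTF-8 with LF line
endings; all readers validate against the domain invariants and raise with
a location instead of silently coercing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, UsageError, ValidationError

GRN_SCHEMA_VERSION = 1

SCORE_KINDS = ("pip", "pvalue")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """Per-variable importance scores at one molecular level.

    ``score_kind`` is ``"pip"`` (posterior inclusion probabilities, in
    [0, 1], larger = more significant) or ``"pvalue"`` (in (0, 1], smaller =
    more significant).
    """

    ids: list[str]
    scores: list[float]
    level: int
    score_kind: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.level not in (1, 2):
            raise ValidationError(f"level must be 1 or 2, got {self.level}")
        if self.score_kind not in SCORE_KINDS:
            raise ValidationError(
                f"score_kind must be one of {SCORE_KINDS}, got {self.score_kind!r}"
            )
        if len(self.ids) != len(self.scores):
            raise DimensionError(
                f"{len(self.ids)} ids but {len(self.scores)} scores"
            )
        if any(not i for i in self.ids):
            raise ValidationError("empty id string")
        seen: set[str] = set()
        dups = sorted({i for i in self.ids if i in seen or seen.add(i)})
        if dups:
            raise ValidationError(f"duplicate ids: {dups}")
        for row, (i, s) in enumerate(zip(self.ids, self.scores), start=1):
            if not math.isfinite(s):
                raise ValidationError(f"non-finite score for {i!r} (row {row})")
            if self.score_kind == "pip" and not 0.0 <= s <= 1.0:
                raise ValidationError(
                    f"pip score {s} outside [0, 1] for {i!r} (row {row})"
                )
            if self.score_kind == "pvalue" and not 0.0 < s <= 1.0:
                raise ValidationError(
                    f"p-value {s} outside (0, 1] for {i!r} (row {row})"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.scores))


@dataclass
class AnnotationMask:
    """J x G binary matrix linking level-1 variables to level-2 groups."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # (J, G) of {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.validate()

    def validate(self) -> None:
        J, G = len(self.row_ids), len(self.col_ids)
        if J < 1 or G < 1:
            raise ValidationError(f"mask needs J >= 1 and G >= 1, got J={J}, G={G}")
        if self.values.shape != (J, G):
            raise DimensionError(
                f"mask values shape {self.values.shape} != ({J}, {G})"
            )
        if len(set(self.row_ids)) != J:
            raise ValidationError("duplicate mask row ids")
        if len(set(self.col_ids)) != G:
            raise ValidationError("duplicate mask column ids")
        bad = np.argwhere(~np.isin(self.values, (0, 1)))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"non-binary mask entry {self.values[r, c]!r} at "
                f"(row {self.row_ids[r]!r}, column {self.col_ids[c]!r})"
            )

    @property
    def J(self) -> int:
        return len(self.row_ids)

    @property
    def G(self) -> int:
        return len(self.col_ids)

    def groups_of(self, row_id: str) -> list[str]:
        """Level-2 ids annotated for one level-1 variable, in column order."""
        j = self.row_ids.index(row_id)
        return [g for g, v in zip(self.col_ids, self.values[j]) if v == 1]


@dataclass
class GenotypeDataset:
    """Aligned genotype matrix, phenotype and optional covariates/families.

    ``X`` is stored as float with NaN marking missing entries; imputation is
    an explicit :mod:`grnkit.preprocess` step, never implicit on read.
    """

    sample_ids: list[str]
    variable_ids: list[str]
    X: np.ndarray  # (N, J) float, NaN = missing
    y: Optional[np.ndarray] = None  # (N,)
    covariates: Optional[np.ndarray] = None  # (N, C)
    covariate_names: Optional[list[str]] = None
    family: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
        self.validate()

    def validate(self) -> None:
        N, J = self.X.shape if self.X.ndim == 2 else (len(self.X), 0)
        if self.X.ndim != 2:
            raise DimensionError("X must be 2-dimensional")
        if len(self.sample_ids) != N:
            raise DimensionError(f"{len(self.sample_ids)} sample ids for {N} X rows")
        if len(self.variable_ids) != J:
            raise DimensionError(
                f"{len(self.variable_ids)} variable ids for {J} X columns"
            )
        if self.y is not None:
            if self.y.shape != (N,):
                raise DimensionError(f"y shape {self.y.shape} != ({N},)")
            if np.isnan(self.y).any():
                raise ValidationError("y contains missing values")
        if self.covariates is not None:
            if self.covariates.shape[0] != N:
                raise DimensionError("covariates row count != N")
            if self.covariate_names is not None and len(self.covariate_names) != (
                self.covariates.shape[1]
            ):
                raise DimensionError("covariate_names length mismatch")
        if self.family is not None and len(self.family) != N:
            raise DimensionError("family labels length != N")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.X).sum())


@dataclass(frozen=True)
class GRNNode:
    id: str
    level: int
    score: float
    score_kind: str
    significant: bool
    group_memberships: tuple[str, ...] = ()
    orphan: bool = False


@dataclass(frozen=True)
class GRNEdge:
    source: str
    target: str
    directed: bool
    kind: str  # "cross_level" | "within_level"
    weight: Optional[float] = None

    def canonical(self) -> tuple:
        if self.directed:
            return (self.source, self.target, self.kind, True)
        a, b = sorted((self.source, self.target))
        return (a, b, self.kind, False)


@dataclass
class GRN:
    """Two-level network of typed nodes and typed edges.

    Cross-level edges are directed level-1 -> level-2; within-level edges are
    undirected. ``metadata`` records the thresholds, connectivity modes,
    backend and layout hint that produced the network.
    """

    nodes: list[GRNNode] = field(default_factory=list)
    edges: list[GRNEdge] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {n.id: n for n in self.nodes}
        if len(by_id) != len(self.nodes):
            raise ValidationError("duplicate node ids")
        for n in self.nodes:
            if n.level not in (1, 2):
                raise ValidationError(f"node {n.id!r}: level must be 1 or 2")
        seen: set[tuple] = set()
        for e in self.edges:
            if e.source not in by_id or e.target not in by_id:
                raise ValidationError(
                    f"edge ({e.source!r} -> {e.target!r}) references unknown node"
                )
            if e.source == e.target:
                raise ValidationError(f"self-edge on {e.source!r}")
            src, tgt = by_id[e.source], by_id[e.target]
            if e.kind == "cross_level":
                if not e.directed:
                    raise ValidationError("cross_level edges must be directed")
                if src.level != 1 or tgt.level != 2:
                    raise ValidationError(
                        f"cross_level edge must go level 1 -> 2, got "
                        f"{src.level} -> {tgt.level}"
                    )
            elif e.kind == "within_level":
                if e.directed:
                    raise ValidationError("within_level edges must be undirected")
                if src.level != tgt.level:
                    raise ValidationError(
                        "within_level edge endpoints on different levels"
                    )
            else:
                raise ValidationError(f"unknown edge kind {e.kind!r}")
            c = e.canonical()
            if c in seen:
                raise ValidationError(f"duplicate edge {c}")
            seen.add(c)

    def node_ids(self, level: Optional[int] = None) -> list[str]:
        return [n.id for n in self.nodes if level is None or n.level == level]

    def get_node(self, node_id: str) -> GRNNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented
        return (
            sorted(self.nodes, key=lambda n: n.id)
            == sorted(other.nodes, key=lambda n: n.id)
            and sorted(self.edges, key=lambda e: e.canonical())
            == sorted(other.edges, key=lambda e: e.canonical())
            and self.metadata == other.metadata
        )


@dataclass
class SelectionResult:
    """Backend output: one score table per molecular level plus fit metadata."""

    level1: ScoreTable
    level2: ScoreTable
    backend: str
    converged: bool = True
    n_iterations: int = 0
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level1.level != 1:
            raise ValidationError("level1 table must have level=1")
        if self.level2.level != 2:
            raise ValidationError("level2 table must have level=2")
        if self.level1.score_kind != self.level2.score_kind:
            raise ValidationError("both tables must share a score_kind")


# ---------------------------------------------------------------------------
# Delimited-text helpers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    sep = _sniff_sep(path)
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def read_score_table(path: str | Path, level: int, score_kind: str) -> ScoreTable:
    """Read a two-column ("id", "score") delimited file.

    Column order is free; extra columns are ignored. Scores are parsed as
    reals and validated against the declared ``score_kind`` range.
    """
    df = _read_table(path)
    for col in ("id", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ids = df["id"].tolist()
    scores: list[float] = []
    for row, raw in enumerate(df["score"].tolist(), start=2):  # 1-based + header
        try:
            scores.append(float(raw))
        except ValueError as exc:
            raise FormatError(
                f"{path}: unparseable score {raw!r} at line {row}"
            ) from exc
    return ScoreTable(ids=ids, scores=scores, level=level, score_kind=score_kind)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id,score\n")
        for i, s in zip(table.ids, table.scores):
            fh.write(f"{i},{float(s)!r}\n")


# ---------------------------------------------------------------------------
# Annotation masks
# ---------------------------------------------------------------------------


def read_mask(path: str | Path) -> AnnotationMask:
    """Read a mask file: header row = level-2 ids, first column = level-1 ids."""
    df = _read_table(path, index_col=0)
    row_ids = [str(i) for i in df.index.tolist()]
    col_ids = [str(c) for c in df.columns.tolist()]
    values = np.empty(df.shape, dtype=int)
    for j, row in enumerate(df.itertuples(index=False)):
        for g, raw in enumerate(row):
            if raw not in ("0", "1"):
                raise ValidationError(
                    f"{path}: non-binary entry {raw!r} at "
                    f"(row {row_ids[j]!r}, column {col_ids[g]!r})"
                )
            values[j, g] = int(raw)
    return AnnotationMask(row_ids=row_ids, col_ids=col_ids, values=values)


def write_mask(mask: AnnotationMask, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id," + ",".join(mask.col_ids) + "\n")
        for rid, row in zip(mask.row_ids, mask.values):
            fh.write(rid + "," + ",".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Genotype datasets
# ---------------------------------------------------------------------------

_MISSING_TOKENS = ("", "NA")


def read_genotype_dataset(
    x_path: str | Path,
    y_path: Optional[str | Path] = None,
    covar_path: Optional[str | Path] = None,
    family_path: Optional[str | Path] = None,
    coding: str = "genotype",
) -> GenotypeDataset:
    """Read X (and optionally y, covariates, family labels) from delimited text.

    X layout: header = variable ids, first column = sample ids. Missing
    genotypes are the empty field or "NA". With ``coding="genotype"`` entries
    must be in {0, 1, 2}; ``coding="dosage"`` accepts any real (for matrices
    already imputed to family means).
    """
    if coding not in ("genotype", "dosage"):
        raise UsageError(f"coding must be 'genotype' or 'dosage', got {coding!r}")
    xdf = _read_table(x_path, index_col=0)
    sample_ids = [str(i) for i in xdf.index.tolist()]
    variable_ids = [str(c) for c in xdf.columns.tolist()]
    X = np.empty(xdf.shape, dtype=float)
    for i, row in enumerate(xdf.itertuples(index=False)):
        for j, raw in enumerate(row):
            if raw in _MISSING_TOKENS:
                X[i, j] = np.nan
                continue
            try:
                v = float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{x_path}: unparseable genotype {raw!r} at "
                    f"(row {i + 1}, column {j + 1})"
                ) from exc
            if coding == "genotype" and v not in (0.0, 1.0, 2.0):
                raise ValidationError(
                    f"{x_path}: genotype {raw!r} not in {{0,1,2}} at "
                    f"(row {i + 1}, column {j + 1})"
                )
            X[i, j] = v

    y = None
    if y_path is not None:
        ydf = _read_table(y_path)
        col = "y" if "y" in ydf.columns else ydf.columns[-1]
        if len(ydf) != len(sample_ids):
            raise DimensionError(
                f"X has {len(sample_ids)} samples but y has {len(ydf)} rows"
            )
        try:
            y = np.array([float(v) for v in ydf[col]], dtype=float)
        except ValueError as exc:
            raise FormatError(f"{y_path}: unparseable phenotype value") from exc

    covariates = covariate_names = None
    if covar_path is not None:
        cdf = _read_table(covar_path, index_col=0)
        if len(cdf) != len(sample_ids):
            raise DimensionError("covariate row count != N")
        covariate_names = [str(c) for c in cdf.columns.tolist()]
        covariates = cdf.astype(float).to_numpy()

    family = None
    if family_path is not None:
        fdf = _read_table(family_path)
        col = "family" if "family" in fdf.columns else fdf.columns[-1]
        if len(fdf) != len(sample_ids):
            raise DimensionError("family label count != N")
        family = [str(v) for v in fdf[col]]

    return GenotypeDataset(
        sample_ids=sample_ids,
        variable_ids=variable_ids,
        X=X,
        y=y,
        covariates=covariates,
        covariate_names=covariate_names,
        family=family,
    )


def write_genotype_matrix(data: GenotypeDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id," + ",".join(data.variable_ids) + "\n")
        for sid, row in zip(data.sample_ids, data.X):
            cells = ["NA" if np.isnan(v) else _fmt_geno(v) for v in row]
            fh.write(sid + "," + ",".join(cells) + "\n")


def _fmt_geno(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_phenotype(data: GenotypeDataset, path: str | Path) -> None:
    if data.y is None:
        raise UsageError("dataset has no phenotype to write")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,y\n")
        for sid, v in zip(data.sample_ids, data.y):
            fh.write(f"{sid},{float(v)!r}\n")


def write_family(data: GenotypeDataset, path: str | Path) -> None:
    if data.family is None:
        raise UsageError("dataset has no family labels to write")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,family\n")
        for sid, fam in zip(data.sample_ids, data.family):
            fh.write(f"{sid},{fam}\n")


def write_covariates(data: GenotypeDataset, path: str | Path) -> None:
    if data.covariates is None:
        raise UsageError("dataset has no covariates to write")
    names = data.covariate_names or [
        f"c{k + 1}" for k in range(data.covariates.shape[1])
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id," + ",".join(names) + "\n")
        for sid, row in zip(data.sample_ids, data.covariates):
            fh.write(sid + "," + ",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GRN serialization
# ---------------------------------------------------------------------------


def _grn_to_dict(grn: GRN) -> dict:
    return {
        "schema_version": GRN_SCHEMA_VERSION,
        "nodes": [
            {
                "id": n.id,
                "level": n.level,
                "score": n.score,
                "score_kind": n.score_kind,
                "significant": n.significant,
                "group_memberships": list(n.group_memberships),
                "orphan": n.orphan,
            }
            for n in grn.nodes
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "directed": e.directed,
                "kind": e.kind,
                "weight": e.weight,
            }
            for e in grn.edges
        ],
        "metadata": grn.metadata,
    }


def _grn_from_dict(doc: dict) -> GRN:
    if doc.get("schema_version") != GRN_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported GRN schema_version {doc.get('schema_version')!r}"
        )
    nodes = [
        GRNNode(
            id=n["id"],
            level=int(n["level"]),
            score=float(n["score"]),
            score_kind=n["score_kind"],
            significant=bool(n["significant"]),
            group_memberships=tuple(n.get("group_memberships", ())),
            orphan=bool(n.get("orphan", False)),
        )
        for n in doc["nodes"]
    ]
    edges = [
        GRNEdge(
            source=e["source"],
            target=e["target"],
            directed=bool(e["directed"]),
            kind=e["kind"],
            weight=None if e.get("weight") is None else float(e["weight"]),
        )
        for e in doc["edges"]
    ]
    return GRN(nodes=nodes, edges=edges, metadata=doc.get("metadata", {}))


_GROUP_SEP = "|"


def write_grn(grn: GRN, path: str | Path, format: str = "json") -> None:
    """Serialize a GRN to ``json`` (versioned schema) or ``graphml``."""
    grn.validate()
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(_grn_to_dict(grn), fh, indent=2)
            fh.write("\n")
    elif format == "graphml":
        g = nx.DiGraph()
        g.graph["schema_version"] = GRN_SCHEMA_VERSION
        g.graph["metadata_json"] = json.dumps(grn.metadata, sort_keys=True)
        for n in grn.nodes:
            g.add_node(
                n.id,
                level=n.level,
                score=n.score,
                score_kind=n.score_kind,
                significant=n.significant,
                group_memberships=_GROUP_SEP.join(n.group_memberships),
                orphan=n.orphan,
            )
        for e in grn.edges:
            attrs = {"directed": e.directed, "kind": e.kind}
            if e.weight is not None:
                attrs["weight"] = e.weight
            g.add_edge(e.source, e.target, **attrs)
        nx.write_graphml(g, path)
    else:
        raise UsageError(f"unknown GRN format {format!r} (use 'json' or 'graphml')")


def read_grn(path: str | Path, format: str = "json") -> GRN:
    path = Path(path)
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: not valid JSON: {exc}") from exc
        return _grn_from_dict(doc)
    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:  # networkx raises several parse error types
            raise FormatError(f"{path}: not valid GraphML: {exc}") from exc
        nodes = []
        for nid, a in g.nodes(data=True):
            if "level" not in a or "score" not in a:
                raise ValidationError(
                    f"{path}: node {nid!r} lacks required attributes "
                    "(undeclared node referenced by an edge?)"
                )
            memberships = tuple(
                m for m in str(a.get("group_memberships", "")).split(_GROUP_SEP) if m
            )
            nodes.append(
                GRNNode(
                    id=str(nid),
                    level=int(a["level"]),
                    score=float(a["score"]),
                    score_kind=str(a["score_kind"]),
                    significant=bool(a["significant"]),
                    group_memberships=memberships,
                    orphan=bool(a.get("orphan", False)),
                )
            )
        edges = []
        for u, v, a in g.edges(data=True):
            edges.append(
                GRNEdge(
                    source=str(u),
                    target=str(v),
                    directed=bool(a["directed"]),
                    kind=str(a["kind"]),
                    weight=float(a["weight"]) if "weight" in a else None,
                )
            )
        metadata = json.loads(g.graph.get("metadata_json", "{}"))
        return GRN(nodes=nodes, edges=edges, metadata=metadata)
    raise UsageError(f"unknown GRN format {format!r} (use 'json' or 'graphml')")
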