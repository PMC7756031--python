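"""Readers and writers for the pipeline's on-disk artifacts.

All tabular files are tab-delimited UTF-8 with ``#`` comment lines; graphs
are GraphML.  Writers sort rows lexicographically by primary id so output is
bit-stable across runs.  Domain containers validate their invariants on
construction and raise :class:`ValueError` with the offending identifier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE = "gene"
MIRNA = "mirna"
KINDS = (GENE, MIRNA)

#: id prefixes conventionally used for mature miRNA names
_MIRNA_ID = re.compile(r"^(hsa-)?(mir|let)-", re.IGNORECASE)


def infer_kind(molecule_id: str) -> str:
    """Classify a molecule id as ``gene`` or ``mirna`` by prefix convention.

    Ids starting with ``miR-``/``let-`` (optionally ``hsa-``-prefixed, any
    case) are miRNAs; everything else is a coding gene.
    """
    return MIRNA if _MIRNA_ID.match(str(molecule_id)) else GENE


def normalize_mirna_id(mirna_id: str) -> str:
    """Case-insensitive canonical miRNA id; mature-arm suffixes preserved.

    ``miR-320a`` and ``MIR-320A`` collapse to the same key while ``miR-320a``
    and ``miR-320b`` remain distinct.
    """
    return str(mirna_id).strip().lower()


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Molecules x samples expression values with a per-molecule kind tag.

    ``values`` is a molecules-by-samples DataFrame (log-scale assumed but
    unit-agnostic); ``kinds`` maps every molecule id to ``gene`` or ``mirna``.
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate molecule id: {dup!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at molecule {idx[i]!r}, sample {cols[j]!r}"
            )
        self.kinds = self.kinds.reindex(idx)
        if self.kinds.isna().any():
            missing = self.kinds.index[self.kinds.isna()][0]
            raise ValueError(f"no kind assigned for molecule {missing!r}")
        bad = ~self.kinds.isin(KINDS)
        if bad.any():
            raise ValueError(
                f"invalid kind {self.kinds[bad].iloc[0]!r} for molecule "
                f"{self.kinds.index[bad][0]!r}"
            )

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, molecule_id: str) -> pd.Series:
        return self.values.loc[molecule_id]

    def subset(self, molecules: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        values = self.values
        if molecules is not None:
            values = values.loc[list(molecules)]
        if samples is not None:
            values = values[list(samples)]
        return ExpressionMatrix(values, self.kinds.loc[values.index])


def concat_expression(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Stack matrices over the intersection of their samples (row-wise)."""
    shared: list[str] | None = None
    for m in matrices:
        shared = m.sample_ids if shared is None else [s for s in shared if s in set(m.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between expression matrices")
    values = pd.concat([m.values[shared] for m in matrices])
    kinds = pd.concat([m.kinds for m in matrices])
    return ExpressionMatrix(values, kinds)


def read_expression(path: str | Path,
                    kind_map: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read an expression TSV: header row of sample ids, first column molecule ids.

    Kinds come from ``kind_map`` when given, otherwise from the id prefix
    convention (logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate molecule id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna())][0]
            raise ValueError(f"{path}: non-numeric cell at molecule {row!r}, sample {col!r}")
        df[col] = coerced
    if kind_map is not None:
        kinds = pd.Series({m: kind_map[m] for m in df.index})
    else:
        logger.info("inferring molecule kinds from id prefixes for %s", path)
        kinds = pd.Series({m: infer_kind(m) for m in df.index})
    return ExpressionMatrix(df, kinds)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.sort_index()
    out.index.name = "molecule_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# condition labels

CASE = "case"
CONTROL = "control"


@dataclass
class ConditionLabels:
    """Two-group sample labels: sample id -> ``case`` | ``control``."""

    assignments: pd.Series

    def __post_init__(self) -> None:
        s = self.assignments
        if s.index.duplicated().any():
            raise ValueError(f"duplicate sample id: {s.index[s.index.duplicated()][0]!r}")
        bad = ~s.isin([CASE, CONTROL])
        if bad.any():
            raise ValueError(f"invalid condition {s[bad].iloc[0]!r} for sample {s.index[bad][0]!r}")
        for cond in (CASE, CONTROL):
            if int((s == cond).sum()) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    @property
    def case_samples(self) -> list[str]:
        return list(self.assignments.index[self.assignments == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.assignments.index[self.assignments == CONTROL])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.assignments.index) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"labeled sample absent from matrix: {sorted(missing)[0]!r}")


def read_labels(path: str | Path) -> ConditionLabels:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, condition")
    return ConditionLabels(pd.Series(df["condition"].values, index=df["sample_id"].values))


def write_labels(labels: ConditionLabels, path: str | Path) -> None:
    df = labels.assignments.rename("condition").sort_index()
    df.index.name = "sample_id"
    df.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# miRNA-target table

EVIDENCE_LEVELS = ("low_throughput", "high_throughput", "")


@dataclass
class MiRTargetTable:
    """Experimentally validated (miRNA, target gene) pairs, deduplicated."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id, evidence

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        if "evidence" not in df.columns:
            df["evidence"] = ""
        df = df[["mirna_id", "gene_id", "evidence"]].astype(str)
        df["evidence"] = df["evidence"].replace({"nan": ""})
        if (df["mirna_id"].str.len() == 0).any() or (df["gene_id"].str.len() == 0).any():
            raise ValueError("empty miRNA or gene id in target table")
        bad = ~df["evidence"].isin(EVIDENCE_LEVELS)
        if bad.any():
            raise ValueError(f"invalid evidence tag {df.loc[bad, 'evidence'].iloc[0]!r}")
        before = len(df)
        df = df.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
        if len(df) < before:
            logger.info("dropped %d duplicate target pairs", before - len(df))
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def filter_evidence(self, level: str = "all") -> "MiRTargetTable":
        if level == "all":
            return self
        return MiRTargetTable(self.pairs[self.pairs["evidence"] == level])

    def targets_by_mirna(self) -> dict[str, set[str]]:
        """Map normalized miRNA id -> set of target gene ids."""
        out: dict[str, set[str]] = {}
        for mid, gid in zip(self.pairs["mirna_id"], self.pairs["gene_id"]):
            out.setdefault(normalize_mirna_id(mid), set()).add(gid)
        return out

    def display_ids(self) -> dict[str, str]:
        """Normalized miRNA id -> first-seen display form."""
        out: dict[str, str] = {}
        for mid in self.pairs["mirna_id"]:
            out.setdefault(normalize_mirna_id(mid), mid)
        return out

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["mirna_id"], self.pairs["gene_id"]))


def read_targets(path: str | Path) -> MiRTargetTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mirna_id, gene_id")
    return MiRTargetTable(df)


def write_targets(table: MiRTargetTable, path: str | Path) -> None:
    table.pairs.sort_values(["mirna_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time in months and event indicator (1=death, 0=censored)."""

    data: pd.DataFrame  # index sample_id; columns time_months, event

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError(f"duplicate sample id: {df.index[df.index.duplicated()][0]!r}")
        if not {"time_months", "event"} <= set(df.columns):
            raise ValueError("survival table needs columns time_months, event")
        times = pd.to_numeric(df["time_months"], errors="coerce")
        if times.isna().any():
            raise ValueError(f"non-numeric time for sample {df.index[times.isna()][0]!r}")
        if (times < 0).any():
            raise ValueError(f"negative time for sample {df.index[times < 0][0]!r}")
        events = pd.to_numeric(df["event"], errors="coerce")
        if events.isna().any() or not events.isin([0, 1]).all():
            bad = df.index[~events.isin([0, 1]) | events.isna()][0]
            raise ValueError(f"non-binary event for sample {bad!r}")
        self.data = pd.DataFrame(
            {"time_months": times.astype(float), "event": events.astype(int)},
            index=df.index,
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    out = table.data.sort_index()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pathway graphs


@dataclass
class PathwayGraph:
    """An undirected simple graph over gene nodes representing one pathway."""

    pathway_id: str
    name: str
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        g = self.graph
        if g.is_directed():
            logger.info("pathway %s: symmetrizing directed edges", self.pathway_id)
            g = g.to_undirected()
        loops = list(nx.selfloop_edges(g))
        if loops:
            logger.info("pathway %s: dropping %d self-loops", self.pathway_id, len(loops))
            g = g.copy()
            g.remove_edges_from(loops)
        if g.is_multigraph():
            g = nx.Graph(g)
        self.graph = g

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_pathways(path: str | Path) -> list[PathwayGraph]:
    """Read pathways from an edge-list TSV or a directory of GraphML files.

    The TSV needs columns ``pathway_id``, ``node_a``, ``node_b``; a directory
    is read as one GraphML graph per pathway.  Directed declarations are
    symmetrized and self-loops/parallel edges dropped (logged).
    """
    p = Path(path)
    out: list[PathwayGraph] = []
    if p.is_dir():
        for f in sorted(p.glob("*.graphml")):
            g = nx.read_graphml(f)
            pid = g.graph.get("pathway_id", f.stem)
            out.append(PathwayGraph(pid, g.graph.get("name", pid), g))
        return out
    df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    if not {"pathway_id", "node_a", "node_b"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns pathway_id, node_a, node_b")
    for pid, grp in df.groupby("pathway_id", sort=True):
        g = nx.Graph()
        for a, b in zip(grp["node_a"], grp["node_b"]):
            g.add_edge(a, b)
        name = grp["name"].iloc[0] if "name" in grp.columns else str(pid)
        out.append(PathwayGraph(str(pid), str(name), g))
    return out


def write_pathways(pathways: Iterable[PathwayGraph], path: str | Path) -> None:
    """Write pathways as an edge-list TSV (sorted, bit-stable)."""
    rows = []
    for pw in pathways:
        for a, b in pw.graph.edges():
            a, b = sorted((str(a), str(b)))
            rows.append((pw.pathway_id, a, b, pw.name))
        for node in nx.isolates(pw.graph):
            rows.append((pw.pathway_id, str(node), str(node), pw.name))
    df = pd.DataFrame(rows, columns=["pathway_id", "node_a", "node_b", "name"])
    df.sort_values(["pathway_id", "node_a", "node_b"]).to_csv(path, sep="\t", index=False)


def _sanitize_attrs(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.graph.update(graph.graph)
    for node in sorted(graph.nodes, key=str):
        attrs = {
            k: ("|".join(map(str, v)) if isinstance(v, (list, tuple, set, frozenset)) else v)
            for k, v in graph.nodes[node].items()
        }
        g.add_node(node, **attrs)
    for a, b in sorted((tuple(sorted((str(a), str(b)))) for a, b in graph.edges)):
        attrs = {
            k: ("|".join(map(str, sorted(map(str, v)))) if isinstance(v, (list, tuple, set, frozenset)) else v)
            for k, v in graph.edges[a, b].items()
        }
        attrs = {k: v for k, v in attrs.items() if v is not None and not (
            isinstance(v, float) and np.isnan(v))}
        g.add_edge(a, b, **attrs)
    return g


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as GraphML; list-valued attributes become '|'-joined strings."""
    nx.write_graphml(_sanitize_attrs(graph), path)


def read_network(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(path)
    for a, b, attrs in g.edges(data=True):
        if "origins" in attrs and isinstance(attrs["origins"], str):
            attrs["origins"] = attrs["origins"].split("|")
    return nx.Graph(g)


def read_id_list(path: str | Path) -> list[str]:
    """One id per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def write_table(df: pd.DataFrame, path: str | Path, sort_by: str | None = None) -> None:
    """Generic TSV writer with deterministic row order."""
    if sort_by is None and len(df.columns):
        sort_by = df.columns[0]
    out = df.sort_values(sort_by) if sort_by else df
    out.to_csv(path, sep="\t", index=False)
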