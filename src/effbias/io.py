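"""Readers and writers for the pipeline's on-disk formats.

Formats handled:

* feature table — delimited text, one row per sample; first column the
  sample id, a designated column the group label, remaining columns
  metabolite abundances (non-negative, missing allowed);
* GMT — one named set per line: ``id<TAB>description<TAB>member...``;
* mapping TSV — two columns, metabolite id and gene id;
* SIF-style edge list — ``source<TAB>relation<TAB>target`` per line,
  read as an undirected simple graph (the relation is recorded but plays
  no role in centrality).

Reading and then writing any of these reproduces the file's content
(row and column order preserved; duplicate set members and duplicate
edges are collapsed on read, which is the one deliberate asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Canonical group labels of the four-arm design.
CANONICAL_GROUPS = ("control", "challenge", "treated", "drug_alone")

#: Cell contents treated as missing on read, unless overridden.
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples × metabolites abundance matrix with group labels.

    ``values`` is a float DataFrame indexed by sample id with metabolite
    ids as columns; NaN marks missing cells.  ``groups`` is a Series on
    the same index with values in :data:`CANONICAL_GROUPS`.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        dup_s = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_s:
            raise FormatError(f"duplicate sample ids: {dup_s}")
        dup_m = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_m:
            raise FormatError(f"duplicate metabolite ids: {dup_m}")
        if not self.groups.index.equals(self.values.index):
            raise ValidationError("group labels and value matrix have different sample ids")
        bad = sorted(set(self.groups) - set(CANONICAL_GROUPS))
        if bad:
            raise FormatError(
                f"unrecognized group labels {bad}; expected one of {list(CANONICAL_GROUPS)}"
            )
        self.values = self.values.astype(float)

    # -- conveniences -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def group_means(self) -> pd.DataFrame:
        """Per-metabolite mean of each group on the current scale (NaN-aware).

        Returns a metabolites × groups frame with columns ordered as
        :data:`CANONICAL_GROUPS` (only groups present appear).
        """
        means = self.values.groupby(self.groups, observed=True).mean().T
        order = [g for g in CANONICAL_GROUPS if g in means.columns]
        return means[order]

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and self.groups.tolist() == other.groups.tolist()
            and np.array_equal(self.values.to_numpy(), other.values.to_numpy(), equal_nan=True)
        )


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(
    path: str | Path,
    group_column: str = "group",
    sep: str | None = None,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    group_map: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Read and validate a feature table from delimited text.

    ``group_map`` canonicalizes real-world labels (e.g. ``{"APAP":
    "challenge"}``) before validation.  Cells equal to one of
    ``missing_tokens`` become missing; any other non-numeric cell is a
    :class:`FormatError`, as are negative abundances, duplicate ids and
    unknown group labels.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"feature table not found: {path}")
    sep = sep or _infer_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    if group_column not in raw.columns:
        raise FormatError(f"group column {group_column!r} not found in {path}")
    labels = raw[group_column]
    if group_map:
        labels = labels.map(lambda g: group_map.get(g, g))
    for row_pos, (sid, g) in enumerate(labels.items(), start=2):  # +1 header, +1 one-based
        if g not in CANONICAL_GROUPS:
            raise FormatError(
                f"unknown group label {g!r} for sample {sid!r} (row {row_pos} of {path.name})"
            )
    data = raw.drop(columns=[group_column])
    masked = data.where(~data.isin(list(missing_tokens)))
    numeric = masked.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & masked.notna()
    if bad_cells.to_numpy().any():
        r, c = np.argwhere(bad_cells.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {data.iat[r, c]!r} at sample {data.index[r]!r}, "
            f"metabolite {data.columns[c]!r}"
        )
    # re-parse through numpy for correctly-rounded floats (exact round trip)
    exact = masked.fillna("nan").to_numpy(dtype=str).astype(float)
    numeric = pd.DataFrame(exact, index=numeric.index, columns=numeric.columns)
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise FormatError(
            f"negative abundance at sample {numeric.index[r]!r}, metabolite {numeric.columns[c]!r}"
        )
    return FeatureTable(values=numeric, groups=labels.rename("group"))


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    sep: str | None = None,
    missing_token: str = "NA",
) -> None:
    path = Path(path)
    sep = sep or _infer_sep(path)
    out = table.values.copy()
    out.insert(0, "group", table.groups)
    out.index.name = "sample"
    # default float formatting is the shortest exact repr: read∘write == identity
    out.to_csv(path, sep=sep, na_rep=missing_token)


# ---------------------------------------------------------------------------
# GMT sets
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteSetCollection:
    """Named sets (metabolite sets for MSEA, or gene memberships).

    ``sets`` maps set id → (description, ordered member tuple); member
    lists are deduplicated preserving first occurrence.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, tuple[str, ...]]] = {}
        for sid, (desc, members) in self.sets.items():
            members = tuple(dict.fromkeys(members))
            if not members:
                raise ValidationError(f"set {sid!r} has no members")
            clean[sid] = (desc, members)
        self.sets = clean

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> MetaboliteSetCollection:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GMT file not found: {path}")
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: expected >= 3 tab-separated fields")
            sid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {sid!r} has no members")
            if sid in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set id {sid!r}")
            sets[sid] = (desc, tuple(dict.fromkeys(members)))
    return MetaboliteSetCollection(sets=sets)


def write_gmt(collection: MetaboliteSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# metabolite → gene mapping
# ---------------------------------------------------------------------------


@dataclass
class MappingTable:
    """Metabolite id → set of interacting gene/protein ids."""

    pairs: dict[str, set[str]] = field(default_factory=dict)

    def genes_for(self, metabolites: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for m in metabolites:
            out |= self.pairs.get(m, set())
        return out

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.pairs.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def read_mapping(path: str | Path) -> MappingTable:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"mapping file not found: {path}")
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise FormatError(f"{path.name}:{lineno}: expected 2 tab-separated fields")
            met, gene = fields
            pairs.setdefault(met, set()).add(gene)
    return MappingTable(pairs=pairs)


def write_mapping(mapping: MappingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for met in sorted(mapping.pairs):
            for gene in sorted(mapping.pairs[met]):
                fh.write(f"{met}\t{gene}\n")


# ---------------------------------------------------------------------------
# SIF edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, pathway_id: str | None = None):
    """Read a SIF-style edge list as an undirected simple :class:`PathwayGraph`.

    A one-field line declares an isolated node; a three-or-more-field
    line ``source relation target [target ...]`` declares one edge per
    target.  Two-field lines are malformed.  Duplicate edges collapse.
    """
    from .enrichment import PathwayGraph  # local import avoids a cycle at module load

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"edge list not found: {path}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                g.add_node(fields[0])
            elif len(fields) >= 3:
                src, _relation, *targets = fields
                for tgt in targets:
                    if src == tgt:
                        g.add_node(src)  # self-loops carry no centrality information
                    else:
                        g.add_edge(src, tgt)
            else:
                raise FormatError(f"{path.name}:{lineno}: expected 1 or >= 3 fields, got 2")
    return PathwayGraph(pathway_id=pathway_id or path.stem, graph=g)


def write_edge_list(pathway_graph, path: str | Path, relation: str = "interacts-with") -> None:
    g = pathway_graph.graph
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in g.nodes():
            if g.degree(node) == 0:
                fh.write(f"{node}\n")
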