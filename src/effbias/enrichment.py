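"""Over-representation and centrality-weighted pathway enrichment.

Two flavors are provided:

* :func:`ora_hypergeometric` — the classical upper-tail hypergeometric
  test of overlap between a selection and a named set within a finite
  universe (the operational core of metabolite-set enrichment
  analysis);
* :func:`cepa_ora` — a centrality-weighted variant for gene-level
  pathway graphs: the observed score is the summed node-centrality
  weight of differential genes in the pathway, and its null
  distribution comes from redrawing equally many genes uniformly
  without replacement from the universe.  The permutation p-value uses
  the plus-one correction ``(1 + #{null >= observed}) / (1 + n_perm)``,
  so it is never exactly zero.  With equal node weights the score is
  the overlap count and the permutation p converges to the
  hypergeometric tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .classify import bh_adjust
from .errors import ValidationError
from .io import MappingTable

CENTRALITY_KINDS = ("equal", "degree", "betweenness")


@dataclass
class PathwayGraph:
    """A pathway's undirected gene graph plus optional node weights."""

    pathway_id: str
    graph: nx.Graph
    weights: dict[str, float] | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class EnrichmentRecord:
    """One set/pathway enrichment outcome.

    ``universe_size`` N, ``set_size`` K, ``selection_size`` n and
    ``overlap`` k follow the usual ORA bookkeeping; ``score`` is the
    centrality-weighted observed score (equal to k for equal weights,
    None for plain ORA).
    """

    set_id: str
    universe_size: int
    set_size: int
    selection_size: int
    overlap: int
    p: float
    score: float | None = None
    p_adj: float | None = None
    meta: dict = field(default_factory=dict)


def ora_hypergeometric(selected: set, members: set, universe: set, set_id: str = "set"):
    """Upper-tail hypergeometric ORA (overlap >= k included in the tail)."""
    selected, members, universe = set(selected), set(members), set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not selected:
        raise ValidationError("empty selection")
    if not members <= universe:
        raise ValidationError(f"set {set_id!r} is not contained in the universe")
    if not selected <= universe:
        raise ValidationError("selection is not contained in the universe")
    N, K, n = len(universe), len(members), len(selected)
    k = len(selected & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentRecord(
        set_id=set_id, universe_size=N, set_size=K, selection_size=n, overlap=k,
        p=min(p, 1.0),
    )


def compute_centrality(pathway_graph: PathwayGraph, kind: str = "equal") -> dict[str, float]:
    """Node weights: all-ones, degree, or unnormalized shortest-path betweenness."""
    g = pathway_graph.graph
    if g.number_of_nodes() == 0:
        raise ValidationError(f"pathway {pathway_graph.pathway_id!r} has no nodes")
    if kind == "equal":
        return {v: 1.0 for v in g.nodes}
    if kind == "degree":
        return {v: float(d) for v, d in g.degree()}
    if kind == "betweenness":
        return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=False).items()}
    raise ValidationError(f"unknown centrality kind {kind!r}")


def cepa_ora(
    pathway_graph: PathwayGraph,
    diff_genes: set,
    universe_genes: set,
    n_perm: int = 10_000,
    seed: int = 0,
    centrality: str = "equal",
) -> EnrichmentRecord:
    """Centrality-weighted pathway enrichment with a gene-sampling null.

    Observed score = sum of pathway-node weights over ``diff_genes``;
    null draws ``|diff_genes|`` genes uniformly without replacement from
    ``universe_genes``.  Deterministic under ``seed``.
    """
    nodes = pathway_graph.nodes
    diff_genes, universe_genes = set(diff_genes), set(universe_genes)
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not nodes <= universe_genes:
        raise ValidationError(
            f"pathway {pathway_graph.pathway_id!r} has nodes outside the universe"
        )
    if len(diff_genes) > len(universe_genes):
        raise ValidationError("selection larger than the universe")
    if not diff_genes <= universe_genes:
        raise ValidationError("selection is not contained in the universe")

    weights = pathway_graph.weights or compute_centrality(pathway_graph, centrality)
    universe = sorted(universe_genes)
    w_vec = np.array([weights.get(g, 0.0) for g in universe])
    observed = float(sum(weights[g] for g in nodes & diff_genes))

    n_draw = len(diff_genes)
    rng = np.random.default_rng(seed)
    exceed = 0
    if n_draw == len(universe):  # single possible draw
        null = np.full(n_perm, w_vec.sum())
        exceed = int(np.sum(null >= observed - 1e-12))
    else:
        chunk = max(1, min(n_perm, int(5e6 // max(len(universe), 1))))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            # indices of the n_draw smallest uniforms = uniform draw w/o replacement
            u = rng.random((m, len(universe)))
            idx = np.argpartition(u, n_draw - 1, axis=1)[:, :n_draw]
            null_scores = w_vec[idx].sum(axis=1)
            exceed += int(np.sum(null_scores >= observed - 1e-12))
            done += m
    p = (1 + exceed) / (1 + n_perm)

    return EnrichmentRecord(
        set_id=pathway_graph.pathway_id,
        universe_size=len(universe),
        set_size=len(nodes),
        selection_size=n_draw,
        overlap=len(nodes & diff_genes),
        p=float(p),
        score=observed,
        meta={"n_perm": n_perm, "seed": seed, "centrality": centrality},
    )


def map_selection(
    verdicts: pd.DataFrame,
    mapping: MappingTable,
    class_filter: str,
) -> tuple[set[str], list[str]]:
    """Union of gene sets of verdict metabolites in a class.

    ``class_filter`` is ``"efficacy"``, ``"bias"`` (= bias_up ∪
    bias_down), ``"bias_up"`` or ``"bias_down"``.  Returns the gene set
    and the list of selected metabolites with no mapping entry (also
    warned about).
    """
    if class_filter == "bias":
        wanted = {"bias_up", "bias_down"}
    elif class_filter in ("efficacy", "bias_up", "bias_down"):
        wanted = {class_filter}
    else:
        raise ValidationError(f"unknown class filter {class_filter!r}")
    selected = verdicts.index[verdicts["class"].isin(wanted)].tolist()
    if not selected:
        warnings.warn(f"no metabolites in class {class_filter!r}", stacklevel=2)
        return set(), []
    unmapped = [m for m in selected if not mapping.pairs.get(m)]
    if len(unmapped) == len(selected):
        warnings.warn(
            f"mapping covers none of the {len(selected)} selected metabolites", stacklevel=2
        )
    genes: set[str] = set()
    for m in selected:
        genes |= mapping.pairs.get(m, set())
    return genes, unmapped


def records_to_frame(records: list[EnrichmentRecord], adjust: bool = True) -> pd.DataFrame:
    """Tabulate records; optionally BH-adjust p across them."""
    df = pd.DataFrame(
        {
            "pathway": [r.set_id for r in records],
            "N": [r.universe_size for r in records],
            "K": [r.set_size for r in records],
            "n": [r.selection_size for r in records],
            "k": [r.overlap for r in records],
            "score": [r.score if r.score is not None else np.nan for r in records],
            "p": [r.p for r in records],
        }
    ).set_index("pathway")
    if adjust and len(df):
        df["p_adj"] = bh_adjust(df["p"])
        for r, adj in zip(records, df["p_adj"]):
            r.p_adj = float(adj)
    return df
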