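"""Synthetic four-group metabolomics cohorts with planted ground truth.

The generator emulates the analyzed arm structure of a pharmacology
study: *control*, *challenge* (toxic insult), *treated*
(challenge + drug) and *drug_alone*.  Metabolite abundances are
log-normal — ``exp(Normal(mu_gj, sigma))`` for metabolite ``j`` in group
``g`` with a shared log-scale standard deviation — matching the
multiplicative-noise convention of LC-MS intensity data.

Two kinds of signal are planted on the log scale:

* **efficacy** metabolites are perturbed by the challenge
  (``mu_challenge = mu_control ± d·sigma``) and partially restored by
  the drug: ``mu_treated = mu_challenge +
  restoration_fraction · (mu_control − mu_challenge)``; the drug alone
  leaves them at baseline;
* **bias** metabolites are untouched by the challenge but shifted by
  the drug — in both treated and drug-alone arms — to the *same* side
  of the control/challenge interval, by ``bias_effect · sigma``.

All remaining metabolites are pure noise.  :func:`generate_knowledge`
derives a matching knowledge base (metabolite→gene mapping, metabolite
sets, pathway graphs) in which one pathway is enriched for
efficacy-derived genes, one for bias-derived genes and one — the
planted "double" pathway — for both, alongside size-matched decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CANONICAL_GROUPS, FeatureTable, MappingTable, MetaboliteSetCollection


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    Effect sizes are standardized (Cohen's d) on the log scale;
    ``restoration_fraction`` is how far the treated mean moves back from
    the challenge mean toward control (1 = full restoration).  Defaults
    are the reference study conditions used throughout the test suite:
    7 samples per group, 400 metabolites of which 40 efficacy and 40
    bias, challenge d = 3, half restoration, bias d = 3, sigma = 0.3.
    """

    n_per_group: int = 7
    n_metabolites: int = 400
    n_efficacy: int = 40
    n_bias: int = 40
    challenge_effect: float = 3.0
    restoration_fraction: float = 0.5
    bias_effect: float = 3.0
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_metabolites < 1:
            raise ValidationError("n_metabolites must be >= 1")
        if self.n_efficacy < 0:
            raise ValidationError("n_efficacy must be >= 0")
        if self.n_bias < 0:
            raise ValidationError("n_bias must be >= 0")
        if self.n_efficacy + self.n_bias > self.n_metabolites:
            raise ValidationError("n_efficacy + n_bias must not exceed n_metabolites")
        if self.challenge_effect < 0:
            raise ValidationError("challenge_effect must be >= 0")
        if not 0.0 <= self.restoration_fraction <= 1.0:
            raise ValidationError("restoration_fraction must lie in [0, 1]")
        if self.bias_effect < 0:
            raise ValidationError("bias_effect must be >= 0")
        if self.baseline_log_sd <= 0:
            raise ValidationError("baseline_log_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated cohort.

    ``group_means`` holds the log-scale expected value for every
    metabolite × group; the id sets are pairwise disjoint.
    """

    efficacy_ids: frozenset[str]
    bias_up_ids: frozenset[str]
    bias_down_ids: frozenset[str]
    group_means: pd.DataFrame

    @property
    def bias_ids(self) -> frozenset[str]:
        return self.bias_up_ids | self.bias_down_ids

    @property
    def planted_ids(self) -> frozenset[str]:
        return self.efficacy_ids | self.bias_ids


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one cohort under ``spec``; identical spec ⇒ identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sigma = spec.baseline_log_sd

    met_ids = [f"M{j + 1:04d}" for j in range(spec.n_metabolites)]
    perm = rng.permutation(spec.n_metabolites)
    eff_idx = perm[: spec.n_efficacy]
    bias_idx = perm[spec.n_efficacy : spec.n_efficacy + spec.n_bias]

    # log-scale group means, columns ordered control/challenge/treated/drug_alone
    mu = np.full((spec.n_metabolites, 4), spec.baseline_log_mean)
    chal_dir = rng.choice([-1.0, 1.0], size=spec.n_efficacy)
    bias_dir = rng.choice([-1.0, 1.0], size=spec.n_bias)

    mu[eff_idx, 1] += chal_dir * spec.challenge_effect * sigma
    mu[eff_idx, 2] = mu[eff_idx, 1] + spec.restoration_fraction * (mu[eff_idx, 0] - mu[eff_idx, 1])
    # drug alone leaves efficacy metabolites at baseline (no effect absent challenge)
    mu[bias_idx, 2] += bias_dir * spec.bias_effect * sigma
    mu[bias_idx, 3] += bias_dir * spec.bias_effect * sigma

    n = spec.n_per_group
    sample_ids = [f"{g}_{i + 1:02d}" for g in CANONICAL_GROUPS for i in range(n)]
    groups = pd.Series(
        np.repeat(list(CANONICAL_GROUPS), n), index=sample_ids, name="group"
    )

    log_vals = np.empty((4 * n, spec.n_metabolites))
    for gi in range(4):
        log_vals[gi * n : (gi + 1) * n, :] = rng.normal(
            loc=mu[:, gi][None, :], scale=sigma, size=(n, spec.n_metabolites)
        )
    values = np.exp(log_vals)

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    table = FeatureTable(
        values=pd.DataFrame(values, index=sample_ids, columns=met_ids), groups=groups
    )
    ids = np.asarray(met_ids)
    truth = GroundTruth(
        efficacy_ids=frozenset(ids[eff_idx]),
        bias_up_ids=frozenset(ids[bias_idx[bias_dir > 0]]),
        bias_down_ids=frozenset(ids[bias_idx[bias_dir < 0]]),
        group_means=pd.DataFrame(mu, index=met_ids, columns=list(CANONICAL_GROUPS)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# knowledge base
# ---------------------------------------------------------------------------

PathwayRole = Literal["efficacy", "bias", "double", "decoy"]


@dataclass
class KnowledgeBundle:
    """Knowledge base matched to one cohort's ground truth.

    Carries the metabolite sets used by MSEA, the metabolite→gene
    mapping, one graph per pathway plus the pathway→gene membership
    sets, and the role each pathway/metabolite set plays in the plant.
    """

    metabolite_sets: MetaboliteSetCollection
    mapping: MappingTable
    graphs: list  # list[PathwayGraph]
    pathway_sets: MetaboliteSetCollection
    pathway_roles: dict[str, PathwayRole] = field(default_factory=dict)
    set_roles: dict[str, PathwayRole] = field(default_factory=dict)

    @property
    def double_pathway_id(self) -> str | None:
        for pid, role in self.pathway_roles.items():
            if role == "double":
                return pid
        return None


def _connected_graph(nodes: list[str], rng: np.random.Generator, extra_edge_factor: float = 0.5):
    """Random connected simple graph: spanning tree + extra edges."""
    from .enrichment import PathwayGraph

    g = nx.Graph()
    g.add_nodes_from(nodes)
    order = list(rng.permutation(nodes))
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        g.add_edge(order[i], order[j])
    n_extra = int(extra_edge_factor * len(nodes))
    for _ in range(n_extra):
        u, v = rng.choice(nodes, size=2, replace=False)
        if u != v:
            g.add_edge(u, v)
    return g


def _sample(pool: list[str], k: int, rng: np.random.Generator) -> list[str]:
    k = min(k, len(pool))
    return list(rng.choice(pool, size=k, replace=False)) if k else []


def generate_knowledge(
    truth: GroundTruth,
    n_pathways: int = 8,
    seed: int = 0,
    genes_per_metabolite: int = 2,
    pathway_size: int = 40,
    metabolite_set_size: int = 25,
) -> KnowledgeBundle:
    """Build a knowledge base whose pathways can recover the plant.

    Every metabolite maps to ``genes_per_metabolite`` private genes.
    With planted metabolites present, three pathways are constructed
    from planted-metabolite genes (one efficacy, one bias, one "double"
    drawing ~80% of its genes from both plants) and the remaining
    ``n_pathways − 3`` are size-matched decoys from unplanted genes;
    with an empty plant, all pathways are decoys.  Per-pathway graphs
    are connected.  Deterministic under ``seed``.
    """
    from .enrichment import PathwayGraph

    if n_pathways < 2:
        raise ValidationError("n_pathways must be >= 2")
    rng = np.random.default_rng(seed)

    met_ids = list(truth.group_means.index)
    mapping = MappingTable(
        pairs={
            m: {f"{m}.g{i + 1}" for i in range(genes_per_metabolite)} for m in met_ids
        }
    )

    eff_mets = sorted(truth.efficacy_ids)
    bias_mets = sorted(truth.bias_ids)
    null_mets = sorted(set(met_ids) - truth.planted_ids)
    eff_pool = sorted(mapping.genes_for(eff_mets))
    bias_pool = sorted(mapping.genes_for(bias_mets))
    null_pool = sorted(mapping.genes_for(null_mets))

    planted = bool(eff_mets) and bool(bias_mets)
    pathway_members: dict[str, list[str]] = {}
    roles: dict[str, PathwayRole] = {}

    if planted:
        half = pathway_size // 2
        dbl_planted = int(0.8 * pathway_size)  # 80% of the double pathway is planted
        eff_take = _sample(eff_pool, pathway_size + dbl_planted // 2, rng)
        bias_take = _sample(bias_pool, pathway_size + dbl_planted // 2, rng)
        pathway_members["PW_EFFICACY"] = sorted(eff_take[:pathway_size])
        pathway_members["PW_BIAS"] = sorted(bias_take[:pathway_size])
        dbl = (
            eff_take[pathway_size:]
            + bias_take[pathway_size:]
            + _sample(null_pool, pathway_size - dbl_planted, rng)
        )
        pathway_members["PW_DOUBLE"] = sorted(dbl)
        roles.update(PW_EFFICACY="efficacy", PW_BIAS="bias", PW_DOUBLE="double")
        n_decoys = n_pathways - 3
    else:
        n_decoys = n_pathways

    decoy_genes = list(null_pool)
    rng.shuffle(decoy_genes)
    for d in range(n_decoys):
        pid = f"PW_DECOY{d + 1:02d}"
        chunk = decoy_genes[d * pathway_size : (d + 1) * pathway_size]
        if len(chunk) < min(pathway_size, 3):  # pool exhausted: resample with reuse
            chunk = _sample(null_pool, pathway_size, rng)
        pathway_members[pid] = sorted(chunk)
        roles[pid] = "decoy"

    graphs = [
        PathwayGraph(pathway_id=pid, graph=_connected_graph(members, rng))
        for pid, members in pathway_members.items()
    ]
    pathway_sets = MetaboliteSetCollection(
        sets={pid: (f"{roles[pid]} pathway", tuple(m)) for pid, m in pathway_members.items()}
    )

    # metabolite sets for MSEA, mirroring the pathway plant at metabolite level
    met_sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    set_roles: dict[str, PathwayRole] = {}
    k = metabolite_set_size
    if planted:
        spike = max(1, int(0.8 * k))
        met_sets["MS_EFFICACY"] = (
            "efficacy metabolite set",
            tuple(sorted(_sample(eff_mets, spike, rng) + _sample(null_mets, k - spike, rng))),
        )
        met_sets["MS_BIAS"] = (
            "bias metabolite set",
            tuple(sorted(_sample(bias_mets, spike, rng) + _sample(null_mets, k - spike, rng))),
        )
        met_sets["MS_DOUBLE"] = (
            "double metabolite set",
            tuple(
                sorted(
                    _sample(eff_mets, spike // 2, rng)
                    + _sample(bias_mets, spike - spike // 2, rng)
                    + _sample(null_mets, k - spike, rng)
                )
            ),
        )
        set_roles.update(MS_EFFICACY="efficacy", MS_BIAS="bias", MS_DOUBLE="double")
        n_set_decoys = max(0, n_pathways - 3)
    else:
        n_set_decoys = n_pathways
    for d in range(n_set_decoys):
        sid = f"MS_DECOY{d + 1:02d}"
        met_sets[sid] = ("decoy metabolite set", tuple(sorted(_sample(null_mets, k, rng))))
        set_roles[sid] = "decoy"

    return KnowledgeBundle(
        metabolite_sets=MetaboliteSetCollection(sets=met_sets),
        mapping=mapping,
        graphs=graphs,
        pathway_sets=pathway_sets,
        pathway_roles=roles,
        set_roles=set_roles,
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
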