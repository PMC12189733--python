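"""End-to-end orchestration: preprocess → PLS-DA/VIP → tests → classes →
gene mapping → dual enrichment, with a serializable run configuration,
deterministic seeding and a machine-readable manifest.

All randomness descends from one root seed through
``numpy.random.SeedSequence`` spawning, so identical configuration ⇒
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_all, differential_test
from .dual_axis import dual_axis, rank_jointly
from .enrichment import (
    EnrichmentRecord,
    PathwayGraph,
    cepa_ora,
    map_selection,
    ora_hypergeometric,
    records_to_frame,
)
from .errors import EffbiasError, ValidationError
from .io import (
    FeatureTable,
    MappingTable,
    MetaboliteSetCollection,
    read_edge_list,
    read_feature_table,
    read_gmt,
    read_mapping,
    write_edge_list,
    write_feature_table,
    write_gmt,
    write_mapping,
)
from .preprocess import PreprocessConfig, preprocess
from .plsda import compute_vip, fit_plsda
from .schema import TABLE_SCHEMAS
from .synthetic import CohortSpec, KnowledgeBundle, generate_cohort, generate_knowledge

logger = logging.getLogger("effbias")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to YAML."""

    feature_table: str = ""
    metabolite_gmt: str = ""
    mapping: str = ""
    graph_dir: str = ""
    out_dir: str = "effbias_run"
    group_column: str = "group"
    group_map: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_components: int = 2
    vip_threshold: float = 1.0
    test_method: str = "auto"
    epsilon: float = 0.0
    alpha: float = 0.05
    centrality: str = "equal"
    n_perm: int = 10_000
    use_adjusted: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"] = asdict(self.preprocess)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("preprocess"), dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def validate_paths(self) -> None:
        for name in ("feature_table", "metabolite_gmt", "mapping", "graph_dir"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ValidationError(f"{name} path does not exist: {p!r}")
        if not list(Path(self.graph_dir).glob("*.sif")):
            raise ValidationError(f"no .sif graphs found in {self.graph_dir!r}")


@dataclass
class AnalysisResult:
    """In-memory outputs of every stage of one run."""

    preprocessed: object  # PreprocessResult
    model: object  # PlsdaModel
    vip: pd.DataFrame
    diff_challenge: pd.DataFrame
    diff_treated: pd.DataFrame
    verdicts: pd.DataFrame
    selections: dict[str, set[str]]
    msea: pd.DataFrame
    cepa: pd.DataFrame
    dual: pd.DataFrame


def _stage_seed(root_seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_analysis(
    table: FeatureTable,
    metabolite_sets: MetaboliteSetCollection,
    mapping: MappingTable,
    graphs: list[PathwayGraph],
    cfg: RunConfig,
) -> AnalysisResult:
    """Run the full inference chain in memory."""
    pre = preprocess(table, cfg.preprocess)
    model = fit_plsda(pre.X, pre.groups, n_components=cfg.n_components)
    vip = compute_vip(model, pre.metabolite_ids)

    analysis_table = pre.analysis_table
    diff_challenge = differential_test(analysis_table, "control", "challenge", cfg.test_method)
    diff_treated = differential_test(analysis_table, "control", "treated", cfg.test_method)
    verdicts = classify_all(
        analysis_table, vip, diff_challenge, diff_treated,
        vip_threshold=cfg.vip_threshold, epsilon=cfg.epsilon, alpha=cfg.alpha,
    )

    # MSEA: metabolite-level ORA per selection class, universe = analyzed metabolites
    met_universe = set(analysis_table.metabolite_ids)
    msea_frames = []
    met_selections = {
        "differential": set(diff_challenge.index[diff_challenge["p_adj"] < cfg.alpha]),
        "efficacy": set(verdicts.index[verdicts["class"] == "efficacy"]),
        "bias": set(verdicts.index[verdicts["class"].isin(["bias_up", "bias_down"])]),
    }
    for cls, sel in met_selections.items():
        if not sel:
            continue
        recs = []
        for sid in metabolite_sets:
            members = set(metabolite_sets.members(sid)) & met_universe
            if not members:
                continue
            recs.append(ora_hypergeometric(sel, members, met_universe, set_id=sid))
        frame = records_to_frame(recs)
        frame.insert(0, "selection", cls)
        msea_frames.append(frame.reset_index())
    msea = (
        pd.concat(msea_frames, ignore_index=True)
        if msea_frames
        else pd.DataFrame(
            columns=["pathway", "selection", "N", "K", "n", "k", "score", "p", "p_adj"]
        )
    )

    # gene-level CePa-style enrichment per class
    gene_universe = mapping.all_genes
    selections = {
        "efficacy": map_selection(verdicts, mapping, "efficacy")[0],
        "bias": map_selection(verdicts, mapping, "bias")[0],
    }
    cepa_frames: dict[str, pd.DataFrame] = {}
    for cls, genes in selections.items():
        recs: list[EnrichmentRecord] = []
        for pg in graphs:
            if not genes:
                recs.append(
                    EnrichmentRecord(
                        set_id=pg.pathway_id, universe_size=len(gene_universe),
                        set_size=len(pg.nodes), selection_size=0, overlap=0,
                        p=1.0, score=0.0,
                    )
                )
                continue
            recs.append(
                cepa_ora(
                    pg, genes, gene_universe,
                    n_perm=cfg.n_perm,
                    seed=_stage_seed(cfg.seed, f"cepa:{cls}:{pg.pathway_id}"),
                    centrality=cfg.centrality,
                )
            )
        cepa_frames[cls] = records_to_frame(recs)
    cepa = pd.concat(
        [f.reset_index().assign(selection=cls).set_index("pathway")
         for cls, f in cepa_frames.items()]
    ).reset_index()

    dual = dual_axis(
        cepa_frames["bias"], cepa_frames["efficacy"],
        alpha=cfg.alpha, use_adjusted=cfg.use_adjusted,
    )

    return AnalysisResult(
        preprocessed=pre, model=model, vip=vip,
        diff_challenge=diff_challenge, diff_treated=diff_treated,
        verdicts=verdicts, selections=selections,
        msea=msea, cepa=cepa, dual=dual,
    )


# ---------------------------------------------------------------------------
# disk-level run
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(cfg: RunConfig) -> Path:
    """Load inputs, run the chain, write every stage's table plus a manifest.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker
    naming the stage is written, and the exception propagates.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "load_inputs"
    try:
        logger.info("loading inputs")
        table = read_feature_table(
            cfg.feature_table, group_column=cfg.group_column, group_map=cfg.group_map or None
        )
        met_sets = read_gmt(cfg.metabolite_gmt)
        mapping = read_mapping(cfg.mapping)
        graphs = [read_edge_list(p) for p in sorted(Path(cfg.graph_dir).glob("*.sif"))]

        stage = "analysis"
        res = run_analysis(table, met_sets, mapping, graphs, cfg)

        stage = "write_outputs"
        pre = res.preprocessed
        _write_tsv(
            pd.DataFrame(pre.X, index=pre.sample_ids, columns=pre.metabolite_ids)
            .rename_axis("sample"),
            out / "preprocessed_matrix.tsv",
        )
        res.model.save(out / "plsda_model.json")
        _write_tsv(res.vip, out / "vip.tsv")
        _write_tsv(res.diff_challenge, out / "differential_challenge.tsv")
        _write_tsv(res.diff_treated, out / "differential_treated.tsv")
        _write_tsv(res.verdicts, out / "verdicts.tsv")
        for cls, genes in res.selections.items():
            (out / f"selection_{cls}.txt").write_text(
                "\n".join(sorted(genes)) + ("\n" if genes else "")
            )
        _write_tsv(res.msea, out / "msea.tsv", index=False)
        _write_tsv(res.cepa, out / "cepa.tsv", index=False)
        _write_tsv(res.dual, out / "dual_axis.tsv")
        _write_tsv(rank_jointly(res.dual), out / "dual_axis_ranked.tsv")

        (out / "schema.json").write_text(json.dumps(TABLE_SCHEMAS, indent=2))
        manifest = {
            "package": "effbias",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(cfg.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": cfg.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "n_samples": table.n_samples,
            "n_metabolites": table.n_metabolites,
            "n_pathways": len(graphs),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("run complete: %s", out)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def simulate_command(
    spec: CohortSpec,
    out_dir: str | Path,
    n_pathways: int = 8,
) -> tuple[Path, KnowledgeBundle]:
    """Emit a ready-to-run input bundle (plus ground truth) for one cohort.

    Writes ``feature_table.csv``, ``metabolite_sets.gmt``,
    ``mapping.tsv``, ``pathway_sets.gmt``, per-pathway ``graphs/*.sif``
    and ``ground_truth.json``.
    """
    out = Path(out_dir)
    (out / "graphs").mkdir(parents=True, exist_ok=True)
    table, truth = generate_cohort(spec)
    bundle = generate_knowledge(
        truth, n_pathways=n_pathways, seed=_stage_seed(spec.seed, "knowledge")
    )
    write_feature_table(table, out / "feature_table.csv")
    write_gmt(bundle.metabolite_sets, out / "metabolite_sets.gmt")
    write_mapping(bundle.mapping, out / "mapping.tsv")
    write_gmt(bundle.pathway_sets, out / "pathway_sets.gmt")
    for pg in bundle.graphs:
        write_edge_list(pg, out / "graphs" / f"{pg.pathway_id}.sif")
    truth_doc = {
        "spec": asdict(spec),
        "efficacy_ids": sorted(truth.efficacy_ids),
        "bias_up_ids": sorted(truth.bias_up_ids),
        "bias_down_ids": sorted(truth.bias_down_ids),
        "pathway_roles": bundle.pathway_roles,
        "set_roles": bundle.set_roles,
        "group_means": {
            m: {g: float(truth.group_means.at[m, g]) for g in truth.group_means.columns}
            for m in truth.group_means.index
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    return out, bundle


def default_config_for_bundle(bundle_dir: str | Path, out_dir: str | Path, seed: int = 0) -> RunConfig:
    """Config pointing at a simulate_command bundle."""
    b = Path(bundle_dir)
    return RunConfig(
        feature_table=str(b / "feature_table.csv"),
        metabolite_gmt=str(b / "metabolite_sets.gmt"),
        mapping=str(b / "mapping.tsv"),
        graph_dir=str(b / "graphs"),
        out_dir=str(out_dir),
        seed=seed,
    )
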