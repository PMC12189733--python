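"""Presence filtering, imputation, log transform and column scaling.

The default chain — half-minimum imputation, natural log, autoscaling —
is the common convention for untargeted LC-MS feature tables.  Fitted
parameters (kept metabolites, per-metabolite half-minimum, centers,
scales) are stored so held-out samples can be projected through the
identical transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FeatureTable


@dataclass(frozen=True)
class PreprocessConfig:
    """What to do, in fixed order: filter → impute → transform → scale.

    ``min_presence`` keeps a metabolite only if observed (non-missing)
    in at least that fraction of samples.  ``pareto`` divides the
    centered column by the square root of its sample standard deviation
    (n−1 denominator); ``autoscale`` standardizes to unit sd.
    """

    impute: Literal["half_min", "none"] = "half_min"
    transform: Literal["log", "none"] = "log"
    scale: Literal["autoscale", "pareto", "none"] = "autoscale"
    min_presence: float = 0.5

    def validate(self) -> None:
        if self.impute not in ("half_min", "none"):
            raise ValidationError(f"unknown impute mode {self.impute!r}")
        if self.transform not in ("log", "none"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.scale not in ("autoscale", "pareto", "none"):
            raise ValidationError(f"unknown scale mode {self.scale!r}")
        if not 0.0 <= self.min_presence <= 1.0:
            raise ValidationError("min_presence must lie in [0, 1]")


@dataclass
class PreprocessParams:
    """Everything needed to replay the transform on new samples."""

    config: PreprocessConfig
    kept_ids: list[str]
    half_min: pd.Series  # imputation value per kept metabolite (pre-transform scale)
    center: pd.Series
    scale: pd.Series  # divisor per column; all-ones when scale == "none"


@dataclass
class PreprocessResult:
    X: np.ndarray  # samples × kept metabolites, fully scaled
    metabolite_ids: list[str]
    sample_ids: list[str]
    groups: pd.Series
    analysis_values: pd.DataFrame  # imputed + transformed, before centering/scaling
    params: PreprocessParams = field(repr=False)

    @property
    def analysis_table(self) -> FeatureTable:
        """The imputed/transformed values as a FeatureTable (analysis scale)."""
        return FeatureTable(values=self.analysis_values.copy(), groups=self.groups.copy())


def _impute_transform(
    values: pd.DataFrame, cfg: PreprocessConfig, half_min: pd.Series
) -> pd.DataFrame:
    out = values.copy()
    if cfg.impute == "half_min":
        out = out.fillna(half_min)
    if cfg.transform == "log":
        if (out.to_numpy() <= 0).any():
            bad = out.columns[(out <= 0).any(axis=0)].tolist()
            raise ValidationError(f"log transform requires positive values; offending: {bad[:5]}")
        out = np.log(out)
    return out


def preprocess(table: FeatureTable, cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Fit the preprocessing chain on ``table`` and return the scaled matrix.

    Raises :class:`ValidationError` if every metabolite is filtered out,
    or if a kept column has zero variance under autoscale/pareto (the
    offending metabolite is named).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if table.n_samples == 0 or table.n_metabolites == 0:
        raise ValidationError("empty feature table")

    presence = table.values.notna().mean(axis=0)
    kept = presence[presence >= cfg.min_presence].index.tolist()
    if not kept:
        raise ValidationError("all metabolites removed by the min_presence filter")
    values = table.values[kept]

    if cfg.impute == "half_min":
        obs_min = values.min(axis=0, skipna=True)
        half_min = obs_min / 2.0
        if values.isna().any().any() and half_min.isna().any():
            bad = half_min.index[half_min.isna()].tolist()
            raise ValidationError(f"cannot impute fully-missing metabolites: {bad[:5]}")
    else:
        half_min = pd.Series(np.nan, index=kept)
        if values.isna().any().any():
            raise ValidationError("missing values present but imputation disabled")

    analysis = _impute_transform(values, cfg, half_min)

    center = analysis.mean(axis=0)
    sd = analysis.std(axis=0, ddof=1)
    if cfg.scale == "autoscale":
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValidationError(f"zero-variance metabolite under autoscale: {bad}")
        scale = sd
    elif cfg.scale == "pareto":
        if (sd == 0).any():
            bad = sd.index[sd == 0].tolist()
            raise ValidationError(f"zero-variance metabolite under pareto scaling: {bad}")
        scale = np.sqrt(sd)
    else:
        center = pd.Series(0.0, index=kept)
        scale = pd.Series(1.0, index=kept)

    X = ((analysis - center) / scale).to_numpy()
    params = PreprocessParams(
        config=cfg, kept_ids=kept, half_min=half_min, center=center, scale=scale
    )
    return PreprocessResult(
        X=X,
        metabolite_ids=kept,
        sample_ids=table.sample_ids,
        groups=table.groups.copy(),
        analysis_values=analysis,
        params=params,
    )


def apply_params(params: PreprocessParams, table: FeatureTable) -> np.ndarray:
    """Project new samples through a fitted preprocessing chain.

    Applies the stored imputation values, transform, centers and scales;
    applying to the training table reproduces its matrix exactly.
    """
    missing = [m for m in params.kept_ids if m not in table.values.columns]
    if missing:
        raise ValidationError(f"table lacks metabolites required by the fit: {missing[:5]}")
    values = table.values[params.kept_ids]
    if params.config.impute != "half_min" and values.isna().any().any():
        raise ValidationError("missing values present but imputation disabled")
    analysis = _impute_transform(values, params.config, params.half_min)
    return ((analysis - params.center) / params.scale).to_numpy()
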