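"""Dual-axis pathway ranking: logP (bias axis) and foldP (efficacy/bias ratio).

Each pathway is tested twice — once against the bias-related gene
selection and once against the efficacy-related one — and the two
p-values are folded into plot-ready coordinates:

* ``logP = −log10(p_bias)`` — strength of the drug-intrinsic (bias)
  enrichment;
* ``foldP = p_efficacy / p_bias`` — how the efficacy-side enrichment
  compares to the bias side (1 = equally enriched, < 1 = efficacy side
  stronger);
* ``joint_flag`` — enriched on *both* axes at level alpha, the mark of
  a pathway the drug touches through restorative and intrinsic routes
  alike.

Permutation p-values carry a plus-one correction and hypergeometric
tails are strictly positive, so both coordinates are always finite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError


def _p_column(df: pd.DataFrame, use_adjusted: bool) -> pd.Series:
    col = "p_adj" if use_adjusted and "p_adj" in df.columns else "p"
    return df[col].astype(float)


def dual_axis(
    records_bias: pd.DataFrame,
    records_efficacy: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Combine per-pathway bias and efficacy enrichments into dual-axis rows.

    Inputs are frames indexed by pathway with ``p`` (and optionally
    ``p_adj``) columns; pathways present on only one side are dropped
    with a warning.  Output columns: ``p_bias``, ``p_efficacy``,
    ``logP``, ``foldP``, ``joint_flag``; rows sorted by descending
    ``logP``, ties by ascending ``foldP``, then pathway id.
    """
    pb = _p_column(records_bias, use_adjusted)
    pe = _p_column(records_efficacy, use_adjusted)
    common = pb.index.intersection(pe.index)
    dropped = sorted(set(pb.index).symmetric_difference(pe.index))
    if dropped:
        warnings.warn(f"pathways present on one side only were dropped: {dropped}", stacklevel=2)
    if len(common) == 0:
        raise ValidationError("no pathway present in both record sets")
    pb, pe = pb.loc[common], pe.loc[common]
    for name, p in (("bias", pb), ("efficacy", pe)):
        bad = p[(p <= 0) | (p > 1)]
        if len(bad):
            raise ValidationError(
                f"{name} p-values outside (0, 1] for pathways {bad.index.tolist()[:5]}"
            )
    out = pd.DataFrame(
        {
            "p_bias": pb,
            "p_efficacy": pe,
            "logP": -np.log10(pb) + 0.0,  # +0.0 turns -0.0 into 0.0 at p = 1
            "foldP": pe / pb,
            "joint_flag": (pb <= alpha) & (pe <= alpha),
        }
    )
    out.index.name = "pathway"
    out = out.reset_index()
    out = out.sort_values(
        ["logP", "foldP", "pathway"], ascending=[False, True, True], kind="mergesort"
    ).set_index("pathway")
    return out


def rank_jointly(results: pd.DataFrame) -> pd.DataFrame:
    """Order pathways by joint enrichment first, then logP, then id."""
    out = results.reset_index()
    out = out.sort_values(
        ["joint_flag", "logP", "pathway"], ascending=[False, False, True], kind="mergesort"
    ).set_index("pathway")
    return out


def log10_foldP(results: pd.DataFrame) -> pd.Series:
    """Display transform of foldP for symmetric plotting around 0."""
    return np.log10(results["foldP"])


def plot_dual_axis(results: pd.DataFrame, path, alpha: float = 0.05, highlight=None):
    """Scatter of logP vs foldP (log scale), joint pathways emphasized."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    joint = results["joint_flag"]
    ax.scatter(results.loc[~joint, "logP"], results.loc[~joint, "foldP"],
               c="grey", label="other")
    ax.scatter(results.loc[joint, "logP"], results.loc[joint, "foldP"],
               c="crimson", label=f"joint (alpha={alpha})")
    if highlight is not None and highlight in results.index:
        row = results.loc[highlight]
        ax.scatter([row["logP"]], [row["foldP"]], facecolors="none",
                   edgecolors="red", s=200, linewidths=2)
        ax.annotate(highlight, (row["logP"], row["foldP"]))
    ax.set_yscale("log")
    ax.axhline(1.0, ls="--", c="k", lw=0.5)
    ax.set_xlabel("logP  (-log10 p, bias axis)")
    ax.set_ylabel("foldP  (p_efficacy / p_bias)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
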