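"""Differential testing and the efficacy/bias metabolite classification.

The rule decomposes a drug's action in a four-arm design (control,
challenge, challenge+drug = treated, drug alone):

* **efficacy**: the treated-group mean falls back *between* the control
  and challenge means — the drug restores a challenge-perturbed
  metabolite toward baseline.  Requires a VIP-gated metabolite with a
  significant control-vs-challenge contrast (otherwise "restoration" is
  undefined).
* **bias_up / bias_down**: the treated mean lies *outside* the
  control–challenge interval — a drug-intrinsic shift independent of
  restoration.  Requires a VIP-gated metabolite with a significant
  treated-vs-control contrast, which scopes the rule to differentially
  expressed metabolites.

All means are taken on the analysis (log, imputed) scale; the drug-alone
mean is recorded as evidence but plays no part in the rule itself.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import FeatureTable

CLASSES = ("efficacy", "bias_up", "bias_down", "unclassified")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    """Shapiro–Wilk gate; constant samples count as non-normal."""
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def differential_test(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed per-metabolite comparison of two groups with BH adjustment.

    ``method`` is ``"t"`` (Student's, equal-variance), ``"mannwhitney"``,
    or ``"auto"`` — Student's t when Shapiro–Wilk passes in both groups
    at ``normality_alpha``, Mann–Whitney otherwise.  Missing cells are
    dropped per metabolite; a group left with fewer than 3 observations
    is an error.  Metabolites identical across both groups get p = 1
    with ``degenerate=True``.

    Returns a frame indexed by metabolite with columns ``statistic``,
    ``p``, ``p_adj``, ``method``, ``degenerate``.
    """
    if method not in ("t", "mannwhitney", "auto"):
        raise ValidationError(f"unknown test method {method!r}")
    for g in (group_a, group_b):
        if (table.groups == g).sum() < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 samples")
    A = table.values[table.groups == group_a].to_numpy()
    B = table.values[table.groups == group_b].to_numpy()
    mets = table.metabolite_ids
    n_met = len(mets)

    stat = np.zeros(n_met)
    pval = np.ones(n_met)
    used = np.empty(n_met, dtype=object)
    degen = np.zeros(n_met, dtype=bool)

    cols: dict[str, list[int]] = {"t": [], "mannwhitney": []}
    for j in range(n_met):
        a, b = A[:, j], B[:, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 3 or len(b) < 3:
            raise ValidationError(
                f"metabolite {mets[j]!r} has fewer than 3 observed values in a group"
            )
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            used[j] = "degenerate"
            degen[j] = True
            continue
        use_t = method == "t" or (
            method == "auto"
            and _is_normalish(a, normality_alpha)
            and _is_normalish(b, normality_alpha)
        )
        used[j] = "t" if use_t else "mannwhitney"
        complete = len(a) == A.shape[0] and len(b) == B.shape[0]
        if complete:  # equal-length columns run as one vectorized batch
            cols[used[j]].append(j)
        elif use_t:
            res = stats.ttest_ind(a, b, equal_var=True)
            stat[j], pval[j] = float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat[j], pval[j] = float(res.statistic), float(res.pvalue)

    if cols["t"]:
        jt = np.array(cols["t"])
        res = stats.ttest_ind(A[:, jt], B[:, jt], axis=0, equal_var=True)
        stat[jt], pval[jt] = res.statistic, res.pvalue
    if cols["mannwhitney"]:
        jm = np.array(cols["mannwhitney"])
        res = stats.mannwhitneyu(A[:, jm], B[:, jm], axis=0, alternative="two-sided")
        stat[jm], pval[jm] = res.statistic, res.pvalue

    out = pd.DataFrame(
        {"statistic": stat, "p": pval, "method": used, "degenerate": degen},
        index=pd.Index(mets, name="metabolite"),
    )
    out["p_adj"] = bh_adjust(out["p"])
    return out[["statistic", "p", "p_adj", "method", "degenerate"]]


def classify_metabolite(
    m_control: float,
    m_challenge: float,
    m_treated: float,
    challenge_significant: bool,
    epsilon: float = 0.0,
) -> str:
    """Class of one metabolite from its three relevant group means.

    Symmetric in control/challenge.  ``epsilon`` shrinks the "between"
    interval and pads the "outside" thresholds to guard against ties;
    the default 0 treats boundaries as between.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    for v in (m_control, m_challenge, m_treated):
        if not np.isfinite(v):
            raise ValidationError("group means must be finite")
    lo, hi = min(m_control, m_challenge), max(m_control, m_challenge)
    if m_treated > hi + epsilon:
        return "bias_up"
    if m_treated < lo - epsilon:
        return "bias_down"
    if challenge_significant and lo + epsilon <= m_treated <= hi - epsilon:
        return "efficacy"
    return "unclassified"


def classify_all(
    table: FeatureTable,
    vip: pd.DataFrame,
    diff_challenge: pd.DataFrame,
    diff_treated: pd.DataFrame,
    vip_threshold: float = 1.0,
    epsilon: float = 0.0,
    alpha: float = 0.05,
    vip_column: str = "vip",
) -> pd.DataFrame:
    """Per-metabolite verdicts over a whole (analysis-scale) table.

    ``diff_challenge`` is the control-vs-challenge test (gates efficacy),
    ``diff_treated`` the treated-vs-control test (gates bias); both
    BH-adjusted at ``alpha``.  Only metabolites with VIP strictly above
    ``vip_threshold`` can receive a non-unclassified label.

    Returns one row per metabolite: ``class``, the four group means,
    ``vip``, ``challenge_p_adj``, ``treated_p_adj``.
    """
    mets = pd.Index(table.metabolite_ids)
    for name, frame in (("vip", vip), ("diff_challenge", diff_challenge),
                        ("diff_treated", diff_treated)):
        missing = mets.difference(frame.index).tolist()
        if missing:
            raise ValidationError(f"{name} table is missing metabolites: {missing[:5]}")

    means = table.group_means()
    for g in ("control", "challenge", "treated"):
        if g not in means.columns:
            raise ValidationError(f"table has no samples in required group {g!r}")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    vip_s = vip.loc[mets, vip_column] if isinstance(vip, pd.DataFrame) else vip.loc[mets]
    chal_p = diff_challenge.loc[mets, "p_adj"].to_numpy()
    treat_p = diff_treated.loc[mets, "p_adj"].to_numpy()

    m_c = means.loc[mets, "control"].to_numpy()
    m_a = means.loc[mets, "challenge"].to_numpy()
    m_t = means.loc[mets, "treated"].to_numpy()
    if not np.isfinite(np.concatenate([m_c, m_a, m_t])).all():
        raise ValidationError("group means must be finite")
    lo, hi = np.minimum(m_c, m_a), np.maximum(m_c, m_a)

    # vectorized form of classify_metabolite + the significance gates
    gated = vip_s.to_numpy() > vip_threshold
    geo_up = m_t > hi + epsilon
    geo_down = m_t < lo - epsilon
    between = ~geo_up & ~geo_down & (m_t >= lo + epsilon) & (m_t <= hi - epsilon)
    cls = np.full(len(mets), "unclassified", dtype=object)
    cls[gated & geo_up & (treat_p < alpha)] = "bias_up"
    cls[gated & geo_down & (treat_p < alpha)] = "bias_down"
    cls[gated & between & (chal_p < alpha)] = "efficacy"

    return pd.DataFrame(
        {
            "class": cls,
            "m_control": m_c,
            "m_challenge": m_a,
            "m_treated": m_t,
            "m_drug_alone": means.loc[mets, "drug_alone"].to_numpy()
            if "drug_alone" in means.columns
            else np.nan,
            "vip": vip_s.to_numpy(),
            "challenge_p_adj": chal_p,
            "treated_p_adj": treat_p,
        },
        index=pd.Index(mets, name="metabolite"),
    )
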