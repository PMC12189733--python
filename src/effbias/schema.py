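"""Column documentation for every numeric table a run emits.

Written verbatim as ``schema.json`` into each run directory.
"""

TABLE_SCHEMAS = {
    "preprocessed_matrix.tsv": {
        "sample": "sample id (row index)",
        "<metabolite>": "fully preprocessed abundance (imputed, transformed, scaled)",
    },
    "vip.tsv": {
        "metabolite": "metabolite id (row index)",
        "vip": "cumulative variable importance in projection over all components",
        "vip_comp<a>": "single-component VIP for component a",
    },
    "differential_challenge.tsv": {
        "metabolite": "metabolite id (row index)",
        "statistic": "test statistic (t or Mann-Whitney U)",
        "p": "two-tailed p-value, control vs challenge",
        "p_adj": "Benjamini-Hochberg adjusted p across metabolites",
        "method": "test used: t, mannwhitney, or degenerate",
        "degenerate": "True when both groups were identical constants (p=1 by convention)",
    },
    "differential_treated.tsv": {
        "metabolite": "metabolite id (row index)",
        "statistic": "test statistic (t or Mann-Whitney U)",
        "p": "two-tailed p-value, control vs treated",
        "p_adj": "Benjamini-Hochberg adjusted p across metabolites",
        "method": "test used: t, mannwhitney, or degenerate",
        "degenerate": "True when both groups were identical constants (p=1 by convention)",
    },
    "verdicts.tsv": {
        "metabolite": "metabolite id (row index)",
        "class": "efficacy | bias_up | bias_down | unclassified",
        "m_control": "group mean on the analysis (log, imputed) scale",
        "m_challenge": "group mean on the analysis scale",
        "m_treated": "group mean on the analysis scale",
        "m_drug_alone": "group mean on the analysis scale (evidence only, not used by the rule)",
        "vip": "cumulative VIP used for gating",
        "challenge_p_adj": "BH-adjusted control-vs-challenge p (gates efficacy)",
        "treated_p_adj": "BH-adjusted control-vs-treated p (gates bias)",
    },
    "selection_efficacy.txt": {"<line>": "gene id mapped from an efficacy-class metabolite"},
    "selection_bias.txt": {"<line>": "gene id mapped from a bias-class metabolite"},
    "msea.tsv": {
        "pathway": "metabolite set id",
        "selection": "which selection was tested: differential | efficacy | bias",
        "N": "universe size (analyzed metabolites)",
        "K": "set size within the universe",
        "n": "selection size",
        "k": "overlap",
        "score": "unused for plain ORA (NaN)",
        "p": "hypergeometric upper-tail p (overlap >= k)",
        "p_adj": "BH-adjusted p across sets, within the selection",
    },
    "cepa.tsv": {
        "pathway": "pathway id",
        "selection": "gene selection tested: efficacy | bias",
        "N": "gene universe size (all genes in the mapping)",
        "K": "pathway node count",
        "n": "selection size",
        "k": "overlap (pathway nodes in the selection)",
        "score": "observed centrality-weighted score",
        "p": "permutation p with plus-one correction",
        "p_adj": "BH-adjusted p across pathways, within the selection",
    },
    "dual_axis.tsv": {
        "pathway": "pathway id (row index)",
        "p_bias": "bias-side enrichment p (adjusted by default)",
        "p_efficacy": "efficacy-side enrichment p (adjusted by default)",
        "logP": "-log10(p_bias)",
        "foldP": "p_efficacy / p_bias",
        "joint_flag": "True when both sides pass alpha",
    },
    "dual_axis_ranked.tsv": {
        "pathway": "pathway id, ordered by joint_flag desc, logP desc, id",
        "...": "same columns as dual_axis.tsv",
    },
}
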