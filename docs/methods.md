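# Methods

`effbias` infers, from a four-arm metabolomics cohort, which of a drug's
metabolic effects are *restorative* (efficacy: the drug pushes a
challenge-perturbed metabolite back toward baseline) and which are
*drug-intrinsic* (bias: the drug moves a metabolite away from both the
control and challenge levels), and then asks which biological pathways
carry each kind of effect. This note documents the model, the
procedure, the defaults, and the limits of what the simulations can
show.

## Study design and data model

The design has four groups: **control**, **challenge** (a toxic or
disease-inducing insult), **treated** (challenge + drug) and
**drug_alone**. The data are a samples × metabolites abundance table
from LC-MS feature extraction: non-negative intensities with missing
cells, analyzed throughout on the natural-log scale, where LC-MS noise
is approximately additive and effect sizes can be standardized
(Cohen's *d* in units of the log-scale standard deviation σ).

## Preprocessing

Fixed order: presence filter → imputation → transform → scaling.

| step | default | alternatives | notes |
|---|---|---|---|
| `min_presence` | 0.5 | any fraction | metabolite kept if observed in ≥ this fraction of samples |
| `impute` | `half_min` | `none` | each metabolite's missing cells ← half its observed minimum |
| `transform` | `log` | `none` | natural log, after imputation |
| `scale` | `autoscale` | `pareto`, `none` | autoscale: mean 0, sd 1 (n−1 denominator); pareto: centered / √sd |

The defaults are the common untargeted-metabolomics convention, chosen
here as a convention and exposed as configuration — nothing downstream
assumes a particular scaling beyond requiring a centered matrix for the
latent-variable model. Fitted parameters (kept ids, imputation values,
centers, scales) are stored so held-out samples are projected through
the identical transform. Zero-variance columns are an error under
autoscale/pareto rather than being silently dropped.

## PLS-DA by NIPALS, and VIP

Group membership is encoded as a column-centered one-hot matrix **Y**
(samples × 4). Components are extracted by the classical NIPALS
alternation (w ∝ X′u normalized, t = Xw, q ∝ Y′t, u = Yq) iterated to a
relative score change < `tol`, then X is deflated by t p′ (p = X′t/t′t)
and Y by t q′. The Y sum of squares captured by component *a*
(SSY_a = drop of ‖Y‖² at deflation, always ≥ 0) weights the variable
importance in projection:

VIP_j = √( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ),  unit-norm weight columns,

so mean_j VIP_j² = 1 identically and VIP > 1 means "above-average
contribution to the explained class variance". Both the cumulative VIP
and per-component VIPs are computed; the classification gate uses the
cumulative form by default (the per-axis reading is available but the
published gating convention does not disambiguate, so the inclusive
form is the default).

Numerical choices:

* `tol = 1e-10` on relative score change; `max_iter = 20 000`. The
  iteration is a power method on X′YY′X; on data with little class
  structure its top eigenvalues nearly tie and several thousand
  iterations can be needed to reach 1e-10. Iterations cost O(np), so a
  large cap is cheaper and more robust than loosening the tolerance;
  null-cohort fits were observed to need up to ≈ 6 000 iterations.
* Sign convention: each weight column is flipped so its
  largest-magnitude entry is positive; scores/loadings flip with it.
  Fits are then reproducible across platforms.
* NIPALS starts from the Y column with the largest residual variance
  (first column on ties) — deterministic.
* n_components defaults to 2, matching the two interpreted axes of the
  score plot; the efficacy/bias meaning is **not** attached to a
  particular component — classification works from group means, not
  from score geometry (the score plot is visualization).

## Differential testing

Two-tailed two-sample comparison per metabolite, Benjamini–Hochberg
adjusted across metabolites. `auto` (default) uses Student's t when
Shapiro–Wilk passes at α = 0.05 in both groups, Mann–Whitney otherwise;
constant samples count as non-normal. Metabolites identical across both
groups get p = 1 by convention and a `degenerate` flag. Missing cells
are dropped per metabolite; fewer than 3 observations in a group is an
error.

## The efficacy/bias rule

For each metabolite with cumulative VIP > 1, with group means m_C
(control), m_A (challenge), m_T (treated) on the log/imputed scale and
interval [lo, hi] = [min(m_C, m_A), max(m_C, m_A)]:

* **efficacy** — lo + ε ≤ m_T ≤ hi − ε, *and* the control-vs-challenge
  contrast is BH-significant (α = 0.05). Without a challenge effect
  "restoration" is undefined.
* **bias_up / bias_down** — m_T > hi + ε (resp. < lo − ε), *and* the
  treated-vs-control contrast is BH-significant. The significance gate
  scopes the rule to differentially expressed metabolites; without it,
  a pure-noise metabolite that clears the VIP gate would land outside
  the interval two-thirds of the time and the false-positive rate would
  be unacceptable.
* otherwise **unclassified**.

ε defaults to 0 (boundaries count as "between"); it exists because ties
are measure-zero in theory but real in rounded data. The rule is
symmetric in control/challenge. The drug-alone mean is recorded as
evidence in every verdict but is not consulted by the rule; whether the
treated-vs-challenge contrast should additionally be required for
efficacy calls is left open in the source methodology and is not
required here (it would cost sensitivity at half restoration, where the
treated mean sits 1.5 σ from the challenge mean).

## Enrichment

**Metabolite level (MSEA).** Upper-tail hypergeometric ORA of a
selection against each GMT set, universe = all analyzed metabolites,
tail inclusive (overlap ≥ k). BH adjustment across sets within each
selection. The pipeline tests three selections: all
challenge-differential metabolites, the efficacy class, and the bias
class.

**Gene level (centrality-weighted).** Each selection of metabolites is
mapped to genes through a two-column metabolite→gene table (the union
over selected metabolites; unmapped metabolites are counted and
warned). Each pathway is an undirected graph of genes; the observed
score is Σ of node-centrality weights over selection genes in the
pathway, and the null redraws |selection| genes uniformly without
replacement from the gene universe (all genes in the mapping — stated
in the output because it changes p). The permutation p carries the
plus-one correction (1 + #{null ≥ s})/(1 + n_perm), so p ∈ (0, 1]
always. Centrality kinds: `equal` (default — the most conservative,
reducing to overlap counting and converging to the hypergeometric
tail), `degree`, unnormalized shortest-path `betweenness`. Defaults:
n_perm = 10 000, BH across pathways within each selection class. Which
centrality and which null the original analysis used is not documented
anywhere; all choices here are explicit configuration, none is claimed
to reproduce an authors' setting.

## Dual-axis ranking

Per pathway, with p_bias and p_efficacy the (by default BH-adjusted)
enrichment p's of the bias and efficacy selections:

* `logP = −log10(p_bias)`;
* `foldP = p_efficacy / p_bias` (stored as the raw ratio; a log10
  display transform is provided for plotting);
* `joint_flag = (p_bias ≤ α) ∧ (p_efficacy ≤ α)`, α = 0.05.

Output rows are sorted by descending logP, ties by ascending foldP,
then pathway id — a total order, so shuffled input reproduces the same
ranking. `rank_jointly` orders by joint_flag first, then logP: the
pathway a drug touches through both routes tops that list. Whether
foldP should be built from raw or adjusted p's is a config flag
(`use_adjusted`, default true).

## Synthetic cohorts and the knowledge base

`generate_cohort` draws abundances exp(Normal(μ_gj, σ)) with a shared
log-scale σ per metabolite:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | 7 | samples per arm |
| `n_metabolites` | 400 | features |
| `n_efficacy` / `n_bias` | 40 / 40 | planted metabolites per class |
| `challenge_effect` | 3.0 | challenge shift in σ units (efficacy metabolites; direction ±, 50/50) |
| `restoration_fraction` | 0.5 | fraction of the challenge shift reversed in the treated arm |
| `bias_effect` | 3.0 | treated and drug-alone shift in σ units (bias metabolites; same side, ± 50/50) |
| `baseline_log_mean` / `baseline_log_sd` | 10 / 0.3 | log-intensity scale and noise |
| `missing_rate` | 0 | MCAR cell masking |

Efficacy metabolites: μ_challenge = μ_0 ± dσ, μ_treated halfway back,
μ_drug_alone = μ_0 (the drug has no effect absent challenge — the
simplest structure consistent with the class definitions). Bias
metabolites: no challenge effect, treated *and* drug-alone shifted by
±(bias d)σ on the same recorded side. Unplanted metabolites are
exchangeable noise. The generator is byte-deterministic under its seed.

`generate_knowledge` gives every metabolite two private genes and
builds: one pathway from efficacy-metabolite genes, one from
bias-metabolite genes, one "double" pathway drawing 80 % of its genes
from both plants (the analogue of a pathway hit by both routes), and
size-matched decoy pathways from unplanted genes; per-pathway graphs
are random connected (spanning tree + extra edges). Matching
metabolite-level GMT sets mirror the same structure for MSEA.

What the generator does **not** emulate: metabolite–metabolite
correlation, batch/drift effects, informative (intensity-dependent)
missingness, heavy-tailed or zero-inflated intensity distributions,
many-to-many promiscuous gene mappings, and overlapping pathways.
Passing recovery simulations therefore shows the inference chain is
correct and calibrated under its own assumptions — not that real
cohorts of this size will yield the same sensitivity.

## Simulation studies and problem sizes

The shipped studies (test suite and `scripts/acceptance.py`) use: 100–
200 planted and null cohorts at the reference conditions for the
classification recovery and false-positive control; 40–100 full-chain
cohorts with 8 pathways and n_perm = 2 000 for the dual-axis study
(the plus-one p floor 1/2001 sits far below the BH-adjusted 0.05 gate
at 8 pathways, so the reduced permutation count does not bind);
n_perm = 50 000 against the exact hypergeometric tail on an 8-gene
universe for the permutation-null calibration; and an exhaustive
enumeration sweep of every ORA configuration on universes up to 12.

## Reproducibility

All randomness descends from one root seed: stage seeds are derived as
SHA-256 of `"{seed}:{label}"` reduced below 2³¹, so adding a pathway or
reordering stages does not shift any other stage's stream. Identical
configuration ⇒ byte-identical numeric outputs (tables are written with
fixed float formatting); the run manifest records the config hash,
seed, and library versions.

## Known limitations

* Balanced groups are assumed by the PLS-DA encoding (no class
  weighting); the four-arm design is balanced by construction.
* The classifier uses group means only; a metabolite whose treated
  *distribution* straddles the interval is summarized by its mean.
* CePa-style enrichment uses node centrality only; edge semantics in
  SIF inputs (activation/inhibition) are parsed and ignored.
* MSEA and the gene-level stage treat sets as given; no correction for
  overlapping pathway membership.
* Cross-validated choice of the number of PLS components and
  permutation tests of class separation are out of scope.
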