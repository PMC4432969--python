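# Methods

This note documents the models, parameter choices and numerical decisions
behind emtkit, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Differential-expression model and the synthetic generator

Inputs to the transcriptomic arm are per-comparison tables of (gene,
log2 fold-change, p, q, detected).  Seven comparisons mirror the
two-cell-line EMT design: stimulated-vs-unstimulated contrasts for
PMC42-ET (+EGF), PMC42-LA (+EGF), MDA-MB-468 (+EGF and +hypoxia), plus
three inter-model contrasts.  Gene identity is the uppercased HGNC-style
symbol; tables must be pre-collapsed to one row per gene (how isoforms
were collapsed upstream is outside this package's knowledge).  Undetected
transcripts are retained with a flag and excluded from every
p-value-based computation.

The generator draws each gene's p-value from the beta-uniform mixture
f(p) = λ + (1−λ)·a·p^(a−1): null genes uniform, signal genes Beta(a, 1).
Defaults: signal fraction `de_fraction = 0.10` (so λ = 0.90) and
`bum_a = 0.2`.  The shape 0.2 makes the signal component heavy enough near
zero that a planted network module is detectable at the default network
FDR (see §3) — with a flatter signal (a ≳ 0.3) the score threshold
τ ≈ 10⁻⁵–10⁻⁶ would sit below essentially all signal p-values and no
generator truth would be recoverable, which would defeat the generator's
purpose.  Planted pathway enrichment multiplies the per-gene signal odds
inside chosen pathways.  Q-values are Benjamini–Hochberg over the detected
genes of each table (statsmodels implementation; an independent
brute-force step-up oracle lives in the tests).

## 2. Pathway over-representation analysis

For each pathway the 2×2 contingency (in-pathway vs not) × (DE vs not) is
evaluated over the universe of *detected* genes with the 1-df Pearson χ²
without continuity correction.  A goodness-of-fit variant (observed vs
expected in-pathway counts only) is available behind
`variant="goodness_of_fit"`; the 2×2 form is the default because the
analysis compares expected and observed counts against the complement.
Two thresholds deliberately coexist: DE *counting* at q < 0.05 and ORA DE
*status* at q < 0.01, both explicit config keys.  Bonferroni correction
multiplies raw p-values by the size of the signalling-map family (22 maps
in the emulated design; the family is whatever the GMT flags via the
`[signalling]` description tag).  Pathways with expected DE counts below
5 are flagged `low_count`, not dropped.

Type-I calibration is checked on pure-null tables (`de_fraction = 0`).
Under a pure null, BH q-values are ≈ 1 and a q-based DE call yields empty
contingency tables, so the calibration suite marks DE by raw p < 0.05 —
the only reading under which a 5% nominal rate is defined — and uses
pathways of ≥ 100 measured genes so the χ² asymptotics hold.

## 3. BUM network scoring and subnetwork search

`fit_bum` maximizes the mixture likelihood over (λ, a) ∈ (0,1)² by
L-BFGS-B from a fixed 12-point start grid (deterministic); p = 0 is
clamped to 10⁻³⁰⁰ before logs because differential-expression tools emit
exact zeros.  Given a target FDR φ (default 0.001, a mandatory config
key), τ is the largest t with
(λ̂+(1−λ̂)â)·t / (λ̂t+(1−λ̂)t^â) ≤ φ (solved by bisection), and genes score
s(p) = (â−1)(ln p − ln τ).

The maximum-score connected subgraph problem is NP-hard in general; the
implementation uses:

* an **exact linear-time dynamic program** when the scored graph is a
  forest (root each tree; dp[v] = w(v) + Σ_children max(0, dp[c]));
* otherwise a **deterministic greedy heuristic**: contract maximal
  positive-score components into super-nodes, connect them through
  minimum-penalty paths (Dijkstra with node penalty max(0, −s)) while the
  net gain is positive, then prune negative-score leaves.  Components are
  processed in (score desc, node asc) order and all ties break
  lexicographically, so results are reproducible.

`exhaustive_max_subnetwork` (bitmask enumeration of connected subsets,
≤ 15 nodes) is the test oracle; the suite requires the heuristic to reach
≥ 95% of the exhaustive optimum on random graphs and exactly the optimum
on trees.  Subnetworks for the two stimuli are merged on their node union
with parent-induced edges; *degree* in the druggable ranking is the
neighbour count in this merged graph (an alternative — degree in the full
network restricted to scored nodes — would be a one-line change but is
not exposed, as the merged-graph reading matches the ranking's purpose:
counting interaction partners that themselves changed).

The planted module in the synthetic network is the connected set grown
from the preferential-attachment seed hub, labelled with the *most
strongly dysregulated* signal genes (smallest p-values) of the configured
comparison.  This emulates a coherent perturbed core; a module of
randomly chosen signal genes would by construction be invisible at the
default FDR and could not serve as recoverable ground truth.

## 4. High-content screen quantification

**Classifier.**  A depth-≤2 axis-aligned decision tree on (mean, total)
vimentin intensity separates cells of positive-control wells (full-effect
reference, epithelial-like) from negative-control wells (stimulated
vehicle).  Candidate thresholds are midpoints of consecutive sorted unique
feature values, evenly subsampled to ≤ 512 per feature; the search is
exhaustive over the root and each child's best refinement, minimizing
class-balanced misclassification of well provenance.  Two regularizers
control overfitting, which otherwise isolates noise slivers between the
control populations and visibly inflates the vimentin⁺ call rate:
each leaf must hold ≥ 0.15 of the balanced weight (of 2.0 total), and a
child split must beat the plain leaf by > 0.02.  Ties prefer fewer nodes,
then the lower first threshold, then the feature name.  The rule
serializes to JSON and reloads with identical predictions.

**Percent inhibition** is exactly
100·(1 − (x − mean(x_pos))/(mean(x_neg) − mean(x_pos))) over well-level
control means, unclipped.  **Dose–response** is a least-squares 4PL of
inhibition vs log₁₀(dose) with deterministic multi-start initialization
(plateaus from response extremes, midpoint from the half-range crossing
and the median dose, hill ∈ {0.5, 1, 2}); the hill sign is canonicalized
so the top plateau is high inhibition.  Constant responses return an
unconverged flag, never a spurious curve.  The reported **IC50 is the
absolute 50%-inhibition crossing** (not the 4PL inflection, which is also
reported), censored to the plate's actual tested dose range with
">MAX"/"<MIN" tokens.

**Plate generator.**  384 wells (16×24): 16 positive controls, 16 negative
controls, 11 doses × 4 replicates (1:2 serial dilution from 10 µM), rest
empty.  Per well, the cell count is negative-binomial (dispersion 50,
i.e. CV ≈ 16% at the default 220 cells/well — typical plate-to-plate
variation for an imaging screen) around a 4PL of dose; per cell, vimentin
mean intensity is a two-component log-normal mixture (modes 50 and 1000,
σ = 0.45 on the log scale) whose vim⁺ weight follows a 4PL of dose
between the stimulated fraction (0.60) and the cell line's baseline
(PMC42-LA 0.10, MDA-MB-468 0.05); vim_total = vim_mean × a log-normal
area; pERK has its own dose-dependent log-normal mean.  The intensity
model is a stand-in: the source experiments report no per-cell intensity
distributions, and a log-normal mixture is the conventional choice for
immunofluorescence intensities (strictly positive, right-skewed, with a
well-defined Bayes threshold for classifier tests).

**Hypoxia plates.**  The oxygen condition is metadata only.  On HPX
plates the stimulus-free (normoxic vehicle) wells serve as the
full-reversion reference — they occupy the positive-control *role*, with
their provenance recorded in the compound column — and hypoxic vehicle
wells are the uninhibited negative controls.  Mapping normoxic wells to
the negative-control role instead would make the percent-inhibition
denominator degenerate (both control means at baseline) or invert the
0%/100% anchors, so the role assignment follows the formula's semantics
rather than the protocol's labelling.

## 5. Combination analysis

Single agents: OLS of log₁₀(fa/(1−fa)) on log₁₀(D); points with fa
outside (0.01, 0.99) are excluded and counted.  CI uses the mutually
exclusive form dA/DxA + dB/DxB (the mutually nonexclusive variant, with
its extra cross-term, is available behind a switch but deprecated by the
method's originators).  Classification thresholds (0.9, 1.1) follow
common practice and are configurable.  Negative inhibition values are
clamped to ε for fa purposes with a warning; points with fa at 0 or 1
are skipped and logged.  Both constant-ratio and checkerboard input
layouts are accepted (the analysis is per-point).

The generator produces single-agent series exactly from the median-effect
equation and combination points whose affected fraction solves the
CI-scaled Loewe sum dA/DxA(fa) + dB/DxB(fa) = CI*, so the planted CI* is
recoverable exactly at zero noise.  The default combination grid runs
both drugs at their Dm ratio over scales 0.25–4 (≈ ED20–ED80): outside
that window small fa noise dominates the index.  Default fa noise
σ = 0.005 represents replicate-averaged well precision.

## 6. Determinism and problem sizes

Every generator draws from a dedicated stream derived from
(master seed, generator index, context tag), so identical (seed, config)
gives byte-identical serialized outputs and adding a generator does not
perturb the others.  Pipeline artifacts are written with fixed float
formatting and JSON sidecars (stage, config hash, seed, row count); the
config hash excludes the output directory.

Default problem sizes are chosen for desk-scale runs: 4 000 genes,
30 pathways (22 signalling), a 400-node network, single plates of
~10⁴ cells.  The test suite and acceptance script complete in a few
minutes on one CPU; all sizes scale up through `SimulationConfig`.

## 7. What passing tests do and do not show

The generator plants clean, parametric truth: BUM-distributed p-values,
exactly logistic dose–response, log-normal intensities, no spatial plate
effects (edge/row gradients), no batch effects, no correlated noise
between wells, and gene labels free of the identifier ambiguity of real
annotation pipelines.  Recovery of planted truth therefore validates the
*estimators and their implementation*, not robustness to the failure
modes of real screens (segmentation errors, focus drift, evaporation
gradients) or real RNA-seq (isoform collapsing, length biases).  The
classifier calibration figures recomputed by `scripts/acceptance.py`
check that the trained rule reproduces the known baseline vimentin⁺
fractions of unstimulated cells; they say nothing about classifier
behaviour under staining batch variation.

## 8. Known limitations

* The greedy subnetwork search carries no approximation guarantee on
  cyclic graphs; the 95%-of-optimum property is verified empirically on
  small random graphs only.
* The ORA χ² is asymptotic; for small pathways the `low_count` flag must
  be heeded (no exact test is provided).
* IC50 censoring reflects the tested dose range of the plate at hand;
  cross-plate harmonization of censor bounds is the caller's concern.
* The CuffDiff dialect reader consumes the documented `gene_exp.diff`
  column layout; other upstream DE tools need the generic dialect.
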