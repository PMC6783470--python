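# Methods

This note documents the models and procedures implemented in `thermoasr`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data validation does and does not demonstrate.

## CvP bias and the OGT calibration

The CvP bias of a protein is `100·(n_charged − n_polar)/n_counted`, with
charged = {R, K, D, E}, polar = {Q, N, S, T}, and `n_counted` the number of
canonical residues. Gaps and the ambiguity codes X/B/Z are excluded from
both numerator and denominator — they are unclassifiable, and excluding them
from the denominator avoids diluting the bias. Selenocysteine (U) and
pyrrolysine (O) are rejected outright rather than remapped, for the same
reason. CvP is reported in percentage points (0–100 scale): with the shipped
calibration coefficients, only a percentage-scale predictor maps realistic
CvP values (≈3–13 pp for this marker) onto the biologically calibrated
37–100 °C range.

Calibration is ordinary least squares of OGT on CvP (via
`scipy.stats.linregress`), with R² reported as the squared Pearson
correlation and the slope's two-sided t-test p-value as a diagnostic only.
Two corrections precede the fit, in this order:

1. **Psychrophile exclusion** (default on). Cold-adapted lineages evolve
   composition under different constraints and sit off the line; flagged
   records are dropped.
2. **Mesophile collapse** (default temperature 37.0 °C). OGT surveys
   over-represent host-associated isolates reported at exactly 37 °C;
   the whole group is replaced by one point at (mean CvP, 37 °C) rather
   than reweighted — the most direct reading of averaging the group — with
   a `collapse_duplicates` switch that instead collapses every duplicated
   OGT value, for sensitivity analysis.

Species with multiple gene copies contribute one point per copy at the same
OGT (`copy_id` distinguishes them; how copies are labeled in any particular
alignment is this package's convention, `taxon|copy`). The published McrABG
calibration ships as `hua2019` = (6.7548, 13.858, R² 0.7288); its panel is
not distributed, so `n_points` is recorded as 0.

## Substitution model and likelihood

The CTMC is built from a symmetric exchangeability matrix (LG shipped, WAG
optional; packaged as conventional lower-triangle text tables) and
equilibrium frequencies π — the model's own, or alignment-empirical "+F"
with add-one smoothing (default in the pipeline). `Q_ij = R_ij·π_j`, rows
zeroed, scaled so −Σ πᵢQᵢᵢ = 1; branch lengths therefore read as expected
substitutions per site. Transition matrices come from the symmetrized
eigendecomposition (Q is similar to a symmetric matrix under the π^½
transform), cached per model; P(0) is returned as the exact identity so
that impossible data (conflicting states across a zero-length path) yields
a true zero likelihood rather than eigendecomposition round-off.

Among-site rate variation uses k equal-probability discrete-gamma
categories (mean rate of each Gamma(α, α) quantile slice, closed form via
regularized incomplete gamma functions, normalized to mean 1). The default
k = 10 follows the convention of running empirical-Bayes reconstruction
with 10 rate categories under LG; the recovery suite uses k = 4, the usual
accuracy/cost compromise. α is either fixed or estimated by bounded Brent
search on [0.02, 100] (tolerance 1e-4); an estimate at a search bound is
flagged, not silently accepted.

The tree likelihood is the pruning recursion with per-node, per-column
scaling (accumulated log scalers), columns mixed over categories with equal
priors. Gaps/ambiguity at leaves are missing data (all-ones partials), so
every column is reconstructed at every node. Columns with zero likelihood
are floored at −10¹⁰ with a warning instead of propagating −∞.

Branch lengths are taken as **fixed inputs by default**; coordinate-wise
Brent re-estimation (sweeps until the gain drops below 1e-3, cap 20) is
available by flag. Fixed-by-default is the reproducible and cheaper choice;
note that under a reversible model the two root-adjacent branch lengths are
identifiable only through their sum (pulley principle), so re-estimated
values for those two edges are reported as an arbitrary split of that sum.

## Marginal ancestral reconstruction

For every internal node the marginal posterior over the 20 residues is
computed by the standard two-pass (inside partials, outside vectors)
algorithm; per-column category weights are proportional to each category's
column likelihood. MAP residues break ties alphabetically for determinism.
Both the MAP-sequence CvP and the posterior-expected CvP
(`100·mean_cols(P(charged) − P(polar))`) are always reported: a
codeml-style workflow could have used either, so the pipeline shows them
side by side, with MAP as the headline column. Ancestral CvP uses all
alignment columns by default; a mask restricting to columns with ≥50%
residues is available (`mask_gappy_columns`).

## MAD rooting

For a candidate root at distance x from endpoint i on branch (i, j):
pairs (b, c) spanning the branch have the root as putative ancestor, with
relative deviation |2(d(i,b)+x)/d(b,c) − 1|; same-side pairs keep their
fixed divergence node, giving |d(i,b) − d(i,c)|/d(b,c). The per-branch x
minimizing the spanning pairs' squared deviations has the closed form
x = Σ(D−2d)/D² / (2 Σ 1/D²), clamped to the branch; the branch score is the
RMS deviation over *all* leaf pairs, and the best branch/position wins,
with ties broken by smallest branch id. Zero-length branches are evaluated
at x = 0 rather than skipped (they are common in real ML trees). Scores are
ratios of path lengths, hence invariant to uniform rescaling; on an
ultrametric tree the MAD root is the midpoint root. The ambiguity index is
best/second-best score in (0, 1] — near 1 means the placement is ambiguous.
Coincident leaves (pairwise distance 0) make relative deviations undefined
and are rejected by name. Correctness is anchored to a dense grid-search
oracle in the test suite, since the criterion itself has no printed
reference trees to compare against.

## Pipeline

`run_pipeline` chains: MAD rooting (or pass-through for pre-rooted trees) →
calibration (fitted from an OGT table, or a named built-in) → optional α
estimation and branch-length re-estimation → marginal reconstruction →
per-node CvP (both variants) → OGT prediction for every node. Leaves report
their observed alignment-row CvP and predicted OGT next to the tabled OGT,
making calibration residuals inspectable. Outputs (annotations TSV,
annotated Newick with `ogt=` node comments, calibration TSV, root-candidate
report, JSON manifest with input digests and the seed, run log) are
byte-deterministic for identical inputs, config and seed.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Calibration panels** — OGTs with an inflated 37 °C group and flagged
  psychrophiles (placed off the line by +3 pp, emulating their distinct
  composition evolution); per-species target CvP = line value + Gaussian
  noise; sequences realize targets by integer residue counts. A finite
  sequence quantizes CvP to multiples of 100/L (L default 20000, so ≤0.005
  pp), which is why exact targets are also recorded in the truth object:
  noise-free recovery tests fit on the targets and separately check the
  sequences against the quantization bound.
* **Tree datasets** — Yule topologies (uniform leaf splitting, i.i.d.
  exponential branch lengths), Brownian OGT trajectories
  (child = parent + N(0, σ²·branch), clamped to [5, 110] °C), node
  compositions from the inverted calibration line (mass shifted between
  the charged and polar sets only, proportionally within each — isolating
  the CvP signal from other composition change), and non-stationary
  simulation in which each branch uses its child's equilibrium frequencies
  with shared LG exchangeabilities. Rate categories are drawn once per
  column and inherited, matching the discrete-gamma likelihood. No indels.

Defaults for the recovery suite: 32 leaves, 3000 columns, root OGT 95 °C,
σ = 8 °C per √(subs/site), α = 0.8, k = 4, mean branch length 0.15
substitutions/site (tree height ≈ 0.75).

What passing tests show: the full chain — rooting, model fitting,
reconstruction, calibration, prediction — recovers the simulated **root**
OGT with small error (mean absolute error ≈ 2.5 °C across 10 seeds), and
every algorithmic component matches an independent oracle. What they do not
show: real alignments have indels, site-heterogeneous composition, model
misspecification and uncertain OGT metadata, none of which the generator
emulates.

A known, quantified limitation: **node-level** OGT estimates are strongly
attenuated. Under a stationary substitution model the posterior composition
at an internal node is pulled toward the global average; at the default
tree height the regression slope of estimated on true node CvP is ≈0.17,
and the residual estimator noise (≈0.56 pp at 3000 columns) is comparable
to the entire true internal-node CvP spread (≈0.62 pp). Consequently the
Pearson correlation between true and estimated internal-node OGTs is low
(≈0.1–0.7 across seeds) even though the root estimate — an average over the
deepest shared signal — is accurate, and directional contrasts (hot root
vs. cooler tips) are recovered reliably. Deeper trees (root-to-tip ≳1.5
subs/site), longer alignments, or smoother OGT trajectories all raise the
node-level correlation; users should treat individual shallow-node OGTs
with caution and rely on root/clade-level summaries.

## Numerical choices

* Likelihood scaling: per-node, per-column max normalization with log
  scalers; zero-likelihood columns floored at −10¹⁰ with a warning.
* MAP ties: alphabetical; candidate ties in MAD: smallest branch id.
* Newick output: 10-significant-digit branch lengths; rootedness is
  encoded by root degree (bifurcation = rooted, multifurcation = unrooted).
* OGT sanity range [−5, 130] °C at the I/O boundary; trajectory clamp
  [5, 110] °C inside it.
* Matching of alignment ids, leaf labels and OGT taxa is exact string
  equality after whitespace trimming — silent fuzzy matches would corrupt
  the calibration.
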