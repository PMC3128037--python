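# Methods

## Model

The package scores a *known* bipartite transcription network against
expression data. The top layer holds regulators — transcription-factor
*activities*, which are never observed directly because activity is set by
post-translational state, localization and partner binding, not by the
factor's own mRNA level. The bottom layer holds target genes, observed as
discretized expression. The activity of factor "A" and the expression of
gene "A" are distinct variables, so a factor may regulate its own gene
without creating a cycle.

Every variable is discrete with three states (low / medium / high).
Genes are multinomial conditioned on the joint state of their regulator
parents; regulators are parentless multinomials. With Dirichlet priors on
all parameters, the marginal likelihood of a completed dataset is
closed-form. For a family with parent-configuration counts `q` and child
arity `r`, writing `N_ijk` for the number of observations with parent
configuration `j` and child state `k`, and `α_ijk` for the pseudocounts:

    log P(child | parents) = Σ_j [ lnΓ(α_ij) − lnΓ(α_ij + N_ij) ]
                           + Σ_jk [ lnΓ(α_ijk + N_ijk) − lnΓ(α_ijk) ]

The network score is the sum of these local terms over all variables. It is
kept in natural log throughout; with hundreds of variables and a hundred
observations the linear-scale product underflows immediately.

A conditional-table model sees arbitrary interactions among parents, not
just additive effects — an XOR-like gene that responds only to "exactly one
parent active" has almost no marginal correlation structure a pairwise or
linear method could use, but fills its parent-configuration table
informatively.

## Hidden-activity sampling

Regulator columns are missing data. They are completed by Gibbs sampling:
cells are visited in a fixed scan order (regulators in declaration order,
observations in sample order) and each cell is redrawn from its full
conditional given everything else. Because the score decomposes over
families, that conditional involves only the regulator's own family and the
families of its target genes, and reduces to a product of one-step
Dirichlet–multinomial predictive probabilities with the cell's own
contribution removed from the counts. The sweep engine maintains count
tables incrementally; its conditional is exactly (atol 1e-12) the
normalized exponentiated full-network rescoring, which is how the tests pin
it down.

A run performs `burn_in` discarded sweeps (default 10) from a uniform
random initialization, then retains `n_samples` states (default 50) spaced
`thinning` sweeps apart (default 1). One RNG stream seeded once drives
initialization and all sweeps, so the retained list is a pure function of
(inputs, seed).

The exact posterior has a 3!-fold label symmetry per regulator. Edge scores
are invariant to relabeling (they depend on counts only), so label switching
does not affect the ranking; state-identity questions (e.g. comparing
sampled activities to a ground truth) are resolved at evaluation time by
taking the best of the six relabelings per regulator.

## Edge scoring and selection

An edge's importance is the change in the average network score, over
retained samples, when the edge is removed versus present
(`raw_delta = mean_s score(net, s) − mean_s score(net − e, s)`; positive =
edge helps). Only the target gene's local term changes, so the
implementation computes the local difference, with exact equality to
full-network rescoring asserted in tests. Scores are min–max normalized to
[0, 1]; selection supports a fixed top-k, a score threshold, and a
largest-gap cut within the top half of the ranking.

Two empirical significance procedures:

* **Random-activity null** — regulator activities drawn iid uniform (no
  Gibbs), edges rescored and re-ranked identically; an edge's p-value at K
  is the add-one fraction of replicates in which it lands in the null top
  K. The observed ranking is held fixed; only the null is randomized.
  Defaults: 5,000 replicates, K ∈ {10, 50, 100, 250}.
* **Disconnection test** — for each edge, the per-sample deltas across ≥20
  retained Gibbs samples enter a one-sided sign-flip permutation test
  (10,000 flips, shared flip matrix, add-one estimator) of "removal does
  not hurt the score".

Note the membership p-value is a property of the null ensemble: it
estimates the edge's null probability of ranking in the top K. At large K
(say half the edge count) those probabilities concentrate near K/E and
split by gene parent count (each extra parent multiplies table rows by
three, and the marginal likelihood penalizes unfilled rows), so the
p-values are *not* uniform under no-signal data and small p-values are
structurally rare. At small K the test behaves as intended: an edge that
never enters the null top-K over 5,000 replicates gets p ≈ 2·10⁻⁴.

## Preprocessing

Genes are filtered to those that can be scored meaningfully: the top N by
sample standard deviation (default 500, ddof 1, ties by ascending symbol),
present in the network, and with at most 10 regulator parents — a
multinomial family's parameter count grows as 3^parents, so a densely
parented gene cannot score well on ~100 observations regardless of biology.
The induced subnetwork drops regulators left without targets.

Discretization is per-gene rank tertiles: samples ranked ascending (stable
ties by sample order), state = floor(3·rank/n). Bin occupancies differ by
at most one and the binning is invariant under any strictly increasing
transform. Three bins keep the hidden configuration space manageable: 100
observations × 2 regulators already span 3^200 ≈ 10^95 configurations, and
each extra bin adds ~25 orders of magnitude.

## Synthetic data

The generator emulates the real problem's shape: random bipartite networks
(each gene draws 1–3 distinct parents by default), hidden activities iid
uniform over three states, and expression assembled as
`Σ_e w_e (a_r − 1) + N(0, noise_sd)` so medium activity is neutral. Effect
magnitudes are uniform on ±[0.8, 1.5] — strong enough that tertile binning
retains the signal at the default noise SD 0.5, comparable to a clearly
differentially expressed gene. A configurable fraction of edges (default
30% in the recovery setting) are decoys with weight 0, giving labeled
negatives; optional nonlinear genes take value +2 when exactly one of their
two parents is high and −2 otherwise.

What it does not emulate: probe-level artifacts, batch structure, cohort
composition (e.g. normal/adjacent/tumor groups), correlated regulator
activities, or realistic scale-free degree distributions. Passing the
recovery gates shows the scoring machinery separates signal from placebo
edges under the model's own assumptions; it does not certify performance on
microarray cohorts.

## Numerical and design choices

* Default prior: uniform pseudocount α = 1 per table cell (parameter-free
  K2 flavor); BDeu (α_ijk = ess/(q·r)) available for sensitivity checks.
* Zero-observation families score exactly 0; empty parent-configuration
  rows are skipped (they contribute 0).
* All tie-breaks are deterministic: gene-symbol order in the SD filter,
  sample order in tertile ranking, (raw delta, edge name) in edge ranking.
* Add-one estimators everywhere a permutation p-value is reported, so no
  p-value is ever 0 at finite replicates.
* Problem sizes in the test-suite gates (20 regulators × 60 genes × 100
  observations; 2 regulators × 8 observations for the exact-posterior
  comparison) are chosen so exact oracles remain enumerable and full runs
  complete in seconds while leaving each statistic well away from its
  small-sample floor.

## Known limitations

* **Retained-sample noise in rankings.** With the default 50 retained
  samples (lag-1 autocorrelation ≈ 0.3), per-edge deltas carry a standard
  error of roughly a nat — larger than the typical score spacing near an
  arbitrary rank cutoff — so membership of a fixed-size top list can churn
  by a few edges between runs with different seeds. Averages stabilize with
  more retained samples (config-exposed); runs at 500 samples agree on 96%
  of their top-50 edges in the reference synthetic setting.
* **Weakly anchored regulators overfit.** A hidden regulator whose
  children carry no signal can co-adapt its sampled activities to the noise,
  inflating its edges' deltas. Regulators with several informative targets
  are well pinned; interpret single-target regulators with care.
* **Interaction edges rank below strong linear edges.** The exactly-one-high
  response is bimodal (±2) and tertile binning splits one mode across two
  bins, so interaction edges score clearly above decoys but typically below
  strong linear edges — detection, not dominance.
* The network is taken as given; no structure search, no edge direction
  inference, no multiple-testing correction across edges.
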